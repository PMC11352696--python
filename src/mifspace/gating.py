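"""Marker-threshold phenotyping.

Each cell gets exactly one exclusive lineage phenotype via an ordered rule
list (first matching positivity pattern wins; nothing matches ⇒ "Other")
plus any number of non-exclusive functional flags. Positivity is closed:
``intensity >= threshold`` is positive, so boundary cells count as
positive.

The default rule order encodes the usual lineage precedence for this
panel: CTL (CD3+CD8+) before Th (CD3+CD4+CD8−) before generic T (CD3+),
then B, macrophage, myeloid, endothelial, fibroblast, smooth muscle. CD3+
CD4+CD8+ double-positives therefore gate as CTL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cells import CellTable, flag_column
from .scene import IntensityModel

#: (phenotype, required-positive markers, required-negative markers)
DEFAULT_EXCLUSIVE_RULES: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("CTL", ("CD3", "CD8"), ()),
    ("Th", ("CD3", "CD4"), ("CD8",)),
    ("T_other", ("CD3",), ()),
    ("B", ("CD20",), ("CD3",)),
    ("Mac", ("CD68",), ("CD3", "CD20")),
    ("Myeloid", ("CD14",), ("CD68", "CD3", "CD20")),
    ("Endothelial", ("CD31",), ()),
    ("Fibroblast", ("FAP",), ()),
    ("SmoothMuscle", ("aSMA",), ()),
)

DEFAULT_FUNCTIONAL_RULES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("PD1", ("PD1",)),
    ("PDL1", ("PDL1",)),
    ("Ki67", ("Ki67",)),
    ("GZMB", ("GZMB",)),
)

FALLBACK_PHENOTYPE = "Other"


@dataclass(frozen=True)
class GatingConfig:
    """Ordered threshold-gating rules.

    ``thresholds`` maps each referenced marker to its positivity cutoff
    (same arbitrary units as the intensity columns). ``exclusive_rules``
    is an ordered precedence list; ``functional_rules`` are evaluated
    independently of lineage.
    """

    thresholds: dict[str, float]
    exclusive_rules: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
        DEFAULT_EXCLUSIVE_RULES
    )
    functional_rules: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_FUNCTIONAL_RULES

    def __post_init__(self) -> None:
        referenced: set[str] = set()
        for _, pos, neg in self.exclusive_rules:
            referenced.update(pos); referenced.update(neg)
        for _, pos in self.functional_rules:
            referenced.update(pos)
        missing = sorted(referenced - set(self.thresholds))
        if missing:
            raise ValueError(f"no threshold for rule markers: {missing}")

    @classmethod
    def from_intensity_model(cls, model: IntensityModel | None = None) -> "GatingConfig":
        """Thresholds at the log-space midpoint of the intensity model."""
        model = model or IntensityModel.default()
        return cls(thresholds=model.midpoint_thresholds())

    # -- structured-text round trip -------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "thresholds": {k: float(v) for k, v in self.thresholds.items()},
            "exclusive_rules": [
                {"phenotype": p, "positive": list(pos), "negative": list(neg)}
                for p, pos, neg in self.exclusive_rules
            ],
            "functional_rules": [
                {"flag": f, "positive": list(pos)} for f, pos in self.functional_rules
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GatingConfig":
        doc = yaml.safe_load(text)
        return cls(
            thresholds=dict(doc["thresholds"]),
            exclusive_rules=tuple(
                (r["phenotype"], tuple(r["positive"]), tuple(r.get("negative", ())))
                for r in doc["exclusive_rules"]
            ),
            functional_rules=tuple(
                (r["flag"], tuple(r["positive"])) for r in doc["functional_rules"]
            ),
        )


def gate_cells(table: CellTable, config: GatingConfig) -> CellTable:
    """Assign one exclusive phenotype and the functional flags per cell.

    Returns a new table with a ``phenotype`` column and one 0/1
    ``<flag>_pos`` column per functional rule.
    """
    referenced: set[str] = set()
    for _, pos, neg in config.exclusive_rules:
        referenced.update(pos); referenced.update(neg)
    for _, pos in config.functional_rules:
        referenced.update(pos)
    missing = sorted(referenced - set(table.markers))
    if missing:
        raise ValueError(f"gating rules reference markers absent from table: {missing}")

    positive = {
        m: table.data[m].to_numpy(dtype=float) >= config.thresholds[m] for m in referenced
    }
    n = table.n_cells
    phenotype = np.full(n, FALLBACK_PHENOTYPE, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for name, pos, neg in config.exclusive_rules:
        match = unassigned.copy()
        for m in pos:
            match &= positive[m]
        for m in neg:
            match &= ~positive[m]
        phenotype[match] = name
        unassigned &= ~match

    data = table.data.copy()
    data["phenotype"] = phenotype
    for flag, pos in config.functional_rules:
        hit = np.ones(n, dtype=bool)
        for m in pos:
            hit &= positive[m]
        data[flag_column(flag)] = hit.astype(int)
    return table.with_data(data)


def proliferation_composition(table: CellTable) -> pd.Series:
    """Phenotype composition of the proliferating (Ki67+) compartment.

    Returns the fraction of Ki67+ cells carried by each phenotype
    (summing to 1 over phenotypes present among Ki67+ cells). An empty
    Ki67+ compartment yields an empty Series with a warning.
    """
    if not table.is_gated:
        raise ValueError("table must be gated before computing proliferation composition")
    ki67 = table.data[table.data[flag_column("Ki67")].astype(bool)]
    if len(ki67) == 0:
        warnings.warn(f"case {table.case_id!r}: no Ki67+ cells")
        return pd.Series(dtype=float, name="fraction")
    frac = ki67["phenotype"].value_counts(normalize=True).sort_index()
    frac.name = "fraction"
    return frac
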