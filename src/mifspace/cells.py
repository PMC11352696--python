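"""Canonical per-cell table shared by every stage of the pipeline.

A :class:`CellTable` wraps a pandas DataFrame with one row per segmented
cell: a unique ``cell_id``, centroid coordinates in micrometres (image
convention: origin top-left, y increasing downward), one nonnegative mean
intensity column per marker, and — once gating has run — a ``phenotype``
column plus 0/1 functional-flag columns (``<flag>_pos``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: mIF panel: lineage markers, checkpoints, vessel/stroma markers, function.
MARKERS: tuple[str, ...] = (
    "CD3", "CD4", "CD8", "CD14", "CD20", "CD68",
    "PD1", "PDL1", "CD31", "aSMA", "FAP", "Ki67", "GZMB",
)

#: Exclusive lineage phenotypes, in canonical reporting order.
PHENOTYPES: tuple[str, ...] = (
    "CTL", "Th", "T_other", "B", "Mac", "Myeloid",
    "Endothelial", "Fibroblast", "SmoothMuscle", "Other",
)

#: Non-exclusive functional states; stored as ``<flag>_pos`` 0/1 columns.
FUNCTIONAL_FLAGS: tuple[str, ...] = ("PD1", "PDL1", "Ki67", "GZMB")

#: Markers whose positive component defines each phenotype when simulating.
PHENOTYPE_POSITIVE_MARKERS: dict[str, tuple[str, ...]] = {
    "CTL": ("CD3", "CD8"),
    "Th": ("CD3", "CD4"),
    "T_other": ("CD3",),
    "B": ("CD20",),
    "Mac": ("CD68",),
    "Myeloid": ("CD14",),
    "Endothelial": ("CD31",),
    "Fibroblast": ("FAP",),
    "SmoothMuscle": ("aSMA",),
    "Other": (),
}


def flag_column(flag: str) -> str:
    return f"{flag}_pos"


@dataclass
class CellTable:
    """Segmented-cell table for a single case.

    Parameters
    ----------
    data
        One row per cell. Required columns: ``cell_id``, ``x``, ``y`` (μm)
        and one column per entry of ``markers``. Optional: ``phenotype``,
        ``<flag>_pos`` flags, ``true_phenotype`` / ``true_niche`` ground
        truth, and arbitrary passthrough metadata columns.
    markers
        Marker intensity columns present in ``data``.
    case_id
        Case (slide/patient) identifier shared by all rows.
    group
        Clinical group label, e.g. ``"LG-ESS"``, ``"HG-ESS"``, ``"SDUS"``.
    """

    data: pd.DataFrame
    markers: tuple[str, ...] = MARKERS
    case_id: str = "case"
    group: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = tuple(self.markers)
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        required = ["cell_id", "x", "y", *self.markers]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"CellTable missing required columns: {missing}")
        if self.data["cell_id"].duplicated().any():
            dup = self.data["cell_id"][self.data["cell_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate cell_id within case {self.case_id!r}: {dup!r}")
        xy = self.data[["x", "y"]].to_numpy(dtype=float)
        if xy.size and not np.isfinite(xy).all():
            raise ValueError("non-finite cell coordinates")
        for m in self.markers:
            col = self.data[m].to_numpy(dtype=float)
            if col.size and (not np.isfinite(col).all() or (col < 0).any()):
                raise ValueError(f"marker {m!r} has negative or non-finite intensities")

    # -- convenience accessors ------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) float array of centroids in μm."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def intensities(self) -> pd.DataFrame:
        return self.data[list(self.markers)]

    @property
    def phenotypes(self) -> pd.Series:
        if "phenotype" not in self.data.columns:
            raise ValueError("table is not gated: no 'phenotype' column")
        return self.data["phenotype"]

    @property
    def is_gated(self) -> bool:
        return "phenotype" in self.data.columns

    def flags(self, flag: str) -> np.ndarray:
        col = flag_column(flag)
        if col not in self.data.columns:
            raise ValueError(f"table has no functional flag column {col!r}")
        return self.data[col].to_numpy(dtype=bool)

    def with_data(self, data: pd.DataFrame) -> "CellTable":
        return replace(self, data=data)

    def copy(self) -> "CellTable":
        return replace(self, data=self.data.copy())

    def __len__(self) -> int:
        return len(self.data)
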