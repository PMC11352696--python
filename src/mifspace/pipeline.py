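"""Config-driven end-to-end runner.

One :class:`RunConfig` describes a whole multi-case study: the cases
(synthetic scene specs and/or cell-table files), gating thresholds, and
the hotspot / interaction / niche parameters. :func:`run_pipeline`
executes simulate → gate → hotspot densities → proximity interactions →
niche clustering → group comparison and writes a per-case and study-level
bundle to the output directory, fully determined by the global seed.

Per-stage seeds are derived as ``sha256(global_seed:stage:case)`` so that
adding or removing one case never perturbs another case's results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cells import CellTable
from .gating import GatingConfig, gate_cells, proliferation_composition
from .hotspots import DensityReport, Window, find_hotspot, group_stats, hotspot_densities
from .interactions import build_proximity_graph, interaction_counts, interaction_enrichment
from .io import read_cell_table, write_cell_table
from .niches import cluster_niches, neighborhood_profiles, niche_report, pool_profiles
from .scene import SceneSpec, generate_scene, make_paper_like_suite

log = logging.getLogger("mifspace.pipeline")


def derive_seed(global_seed: int, stage: str, case_id: str = "") -> int:
    """Stable per-stage, per-case sub-seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}:{case_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class CaseInput:
    """One case: either a synthetic profile/spec or an input file."""

    case_id: str
    group: str = ""
    profile: str | None = None  # "ESS-like" | "SDUS-like"
    spec: SceneSpec | None = None
    path: str | None = None
    dialect: str = "generic"


@dataclass
class RunConfig:
    cases: list[CaseInput]
    gating: GatingConfig | None = None  # None → intensity-model midpoints
    window_side: float = 500.0
    stride: float = 250.0
    reference: str = "all"
    radius: float = 15.0
    n_perm: int = 1000
    niche_mode: str = "knn"
    niche_k_nn: int = 20
    niche_k: int = 6
    niche_n_init: int = 10
    seed: int = 0
    outdir: str = "results"
    extra: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        doc = {
            "seed": self.seed, "outdir": self.outdir,
            "window_side": self.window_side, "stride": self.stride,
            "reference": self.reference, "radius": self.radius,
            "n_perm": self.n_perm,
            "niche": {"mode": self.niche_mode, "k_nn": self.niche_k_nn,
                      "k": self.niche_k, "n_init": self.niche_n_init},
            "cases": [
                {k: v for k, v in {
                    "case_id": c.case_id, "group": c.group, "profile": c.profile,
                    "path": c.path, "dialect": c.dialect,
                }.items() if v not in (None, "")}
                for c in self.cases
            ],
        }
        if self.gating is not None:
            doc["gating"] = yaml.safe_load(self.gating.to_yaml())
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text)
        niche = doc.get("niche", {})
        gating = None
        if "gating" in doc:
            gating = GatingConfig.from_yaml(yaml.safe_dump(doc["gating"]))
        cases = [CaseInput(**c) for c in doc.get("cases", [])]
        return cls(
            cases=cases, gating=gating,
            window_side=doc.get("window_side", 500.0),
            stride=doc.get("stride", 250.0),
            reference=doc.get("reference", "all"),
            radius=doc.get("radius", 15.0),
            n_perm=doc.get("n_perm", 1000),
            niche_mode=niche.get("mode", "knn"),
            niche_k_nn=niche.get("k_nn", 20),
            niche_k=niche.get("k", 6),
            niche_n_init=niche.get("n_init", 10),
            seed=doc.get("seed", 0),
            outdir=doc.get("outdir", "results"),
        )


@dataclass
class PipelineResult:
    """In-memory bundle mirroring what lands in the output directory."""

    tables: dict[str, CellTable]
    density_reports: dict[str, DensityReport]
    interactions: dict[str, object]
    niche_model: object
    niche_report: object
    group_comparison: object | None
    proliferation: dict[str, pd.Series]
    summary: dict
    outdir: Path


def _load_case(case: CaseInput, seed: int) -> CellTable:
    if case.spec is not None:
        spec = case.spec
        return generate_scene(spec)
    if case.profile is not None:
        spec = make_paper_like_suite(case.profile, derive_seed(seed, "simulate", case.case_id),
                                     case_id=case.case_id)
        return generate_scene(spec)
    if case.path is not None:
        return read_cell_table(case.path, dialect=case.dialect,
                               case_id=case.case_id, group=case.group)
    raise ValueError(f"case {case.case_id!r}: no spec, profile or path given")


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full study described by ``config``.

    Writes, under ``config.outdir``: the echoed config, per-case gated
    tables and per-case density / interaction CSVs, pooled niche outputs
    and a ``summary.json``. Identical configs produce byte-identical
    numeric outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())
    gating = config.gating or GatingConfig.from_intensity_model()

    tables: dict[str, CellTable] = {}
    reports: dict[str, DensityReport] = {}
    inter: dict[str, object] = {}
    prolif: dict[str, pd.Series] = {}
    profiles_by_case: dict[str, pd.DataFrame] = {}
    groups: dict[str, str] = {}

    for case in config.cases:
        cdir = outdir / "cases" / case.case_id
        cdir.mkdir(parents=True, exist_ok=True)
        stage = "load"
        try:
            table = _load_case(case, config.seed)
            if case.group:
                table.group = case.group
            groups[case.case_id] = table.group

            stage = "gate"
            table = gate_cells(table, gating)
            tables[case.case_id] = table
            write_cell_table(table, cdir / "cells.csv")
            prolif[case.case_id] = proliferation_composition(table)

            stage = "density"
            window = find_hotspot(table, config.window_side, config.stride, config.reference)
            rep = hotspot_densities(table, window)
            reports[case.case_id] = rep
            pd.Series(rep.densities, name="density_per_mm2").rename_axis("phenotype") \
                .to_csv(cdir / "hotspot_density.csv")

            stage = "interactions"
            graph = build_proximity_graph(table, config.radius)
            graph.edge_frame().to_csv(cdir / "edges.csv", index=False)
            enr = interaction_enrichment(
                graph, table, n_perm=config.n_perm,
                seed=derive_seed(config.seed, "interactions", case.case_id),
            )
            inter[case.case_id] = enr
            enr.counts.to_csv(cdir / "interaction_counts.csv")
            enr.z.round(6).to_csv(cdir / "interaction_z.csv")
            enr.p_perm.round(6).to_csv(cdir / "interaction_p.csv")

            stage = "niche-profiles"
            profiles_by_case[case.case_id] = neighborhood_profiles(
                table, mode=config.niche_mode, k_nn=config.niche_k_nn,
            )
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed for case {case.case_id!r}: {exc}"
            ) from exc
        log.info("case %s done (%d cells)", case.case_id, table.n_cells)

    pooled = pool_profiles(profiles_by_case)
    model = cluster_niches(
        pooled, k=config.niche_k, seed=derive_seed(config.seed, "niche"),
        n_init=config.niche_n_init,
    )
    nreport = niche_report(model)
    model.labels.rename("niche").reset_index().to_csv(outdir / "niche_labels.csv", index=False)
    nreport.composition.round(6).to_csv(outdir / "niche_composition.csv")
    nreport.case_proportions.round(6).to_csv(outdir / "niche_proportions.csv")

    comparison = None
    if len(set(groups.values())) >= 2:
        comparison = group_stats(list(reports.values()), groups)
        comparison.comparisons.round(6).to_csv(outdir / "group_comparisons.csv")

    dens_matrix = pd.DataFrame({c: r.densities for c, r in reports.items()}).T
    dens_matrix.rename_axis("case_id").round(6).to_csv(outdir / "hotspot_densities.csv")

    summary = {
        "seed": config.seed,
        "n_cases": len(config.cases),
        "groups": groups,
        "cells_per_case": {c: t.n_cells for c, t in tables.items()},
        "hotspot": {
            c: {"window": [r.window.x0, r.window.y0, r.window.side_x, r.window.side_y],
                "area_mm2": r.window_area_mm2,
                "densities_per_mm2": r.densities}
            for c, r in reports.items()
        },
        "proliferation_composition": {c: s.to_dict() for c, s in prolif.items()},
        "interaction_top_pairs": {
            c: _top_pairs(e.z) for c, e in inter.items()
        },
        "niche": {
            "k": model.k,
            "inertia": model.inertia,
            "case_proportions": {
                str(c): {int(n): float(v) for n, v in row.items()}
                for c, row in nreport.case_proportions.iterrows()
            },
            "predominant": nreport.predominant,
        },
        "group_comparison": (
            comparison.comparisons.reset_index().to_dict(orient="records")
            if comparison is not None else None
        ),
        "method": (comparison.method if comparison is not None else None),
    }
    summary = _round_floats(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return PipelineResult(
        tables=tables, density_reports=reports, interactions=inter,
        niche_model=model, niche_report=nreport, group_comparison=comparison,
        proliferation=prolif, summary=summary, outdir=outdir,
    )


def _top_pairs(z: pd.DataFrame, n: int = 5) -> list[dict]:
    pairs = []
    cats = list(z.index)
    for i, a in enumerate(cats):
        for b in cats[i:]:
            pairs.append({"pair": f"{a}-{b}", "z": float(z.loc[a, b])})
    pairs.sort(key=lambda d: -d["z"])
    return pairs[:n]


# ---------------------------------------------------------------------------
# QC plots
# ---------------------------------------------------------------------------

def qc_plots(result: PipelineResult, outdir: str | Path | None = None) -> list[Path]:
    """Basic QC figures: phenotype scatter, interaction-z heatmap and
    niche map per case. Plot failures warn and never corrupt numeric
    outputs."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    outdir = Path(outdir or result.outdir) / "figures"
    outdir.mkdir(parents=True, exist_ok=True)
    made: list[Path] = []

    labels = result.niche_model.labels
    niche_cmap = plt.get_cmap("tab10")
    for case_id, table in result.tables.items():
        try:
            fig, axes = plt.subplots(1, 3, figsize=(16, 5))
            if table.n_cells == 0:
                axes[0].text(0.5, 0.5, "empty case", ha="center")
                warnings.warn(f"case {case_id!r} is empty; placeholder figure written")
            else:
                for pheno, sub in table.data.groupby("phenotype"):
                    axes[0].scatter(sub["x"], sub["y"], s=2, label=str(pheno))
                axes[0].legend(fontsize=6, markerscale=3, ncol=2)
                axes[0].invert_yaxis()
                axes[0].set_title(f"{case_id}: phenotypes")

                z = result.interactions[case_id].z
                im = axes[1].imshow(z.to_numpy(), cmap="coolwarm", vmin=-5, vmax=5)
                axes[1].set_xticks(range(len(z)), z.columns, rotation=90, fontsize=6)
                axes[1].set_yticks(range(len(z)), z.index, fontsize=6)
                fig.colorbar(im, ax=axes[1], label="permutation z")
                axes[1].set_title("interaction enrichment")

                case_labels = labels.xs(case_id, level="case_id")
                order = table.data["cell_id"]
                niche = case_labels.reindex(order).to_numpy()
                axes[2].scatter(table.data["x"], table.data["y"], s=2,
                                c=[niche_cmap((int(n) - 1) % 10) for n in niche])
                axes[2].invert_yaxis()
                axes[2].set_title(f"niches (1..{result.niche_model.k})")
            fig.tight_layout()
            p = outdir / f"{case_id}_qc.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            made.append(p)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"QC plot for case {case_id!r} failed: {exc}")
    return made
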