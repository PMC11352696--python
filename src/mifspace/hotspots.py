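"""Maximum-density window selection and per-phenotype density statistics.

Immune infiltration is spatially heterogeneous across a slide, so per-case
densities are quantified inside the single maximum-cell-density window
("hotspot") rather than slide-wide: a square window of fixed side slides
over the ROI bounding box on a stride grid and the anchor maximizing the
reference-cell count wins (ties: smallest y, then smallest x anchor).
Window membership is half-open, [x0, x0+w) × [y0, y0+w), so tiling never
double-counts a cell.

Group comparison follows the common two-factor (group × phenotype)
analysis-of-variance layout on per-case hotspot densities, with
per-phenotype group contrasts on the pooled residual variance and a
Šidák family correction across phenotypes, plus a rank-based fallback
(Mann-Whitney / Kruskal-Wallis) that is more defensible at the tiny
case counts typical of rare-tumor studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cells import CellTable

UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class Window:
    """Axis-aligned square analysis window, μm; half-open membership."""

    x0: float
    y0: float
    side_x: float
    side_y: float

    @property
    def area_mm2(self) -> float:
        return self.side_x * self.side_y / UM2_PER_MM2

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x0) & (x < self.x0 + self.side_x)
            & (y >= self.y0) & (y < self.y0 + self.side_y)
        )


@dataclass
class DensityReport:
    """Per-case hotspot densities (cells/mm²) by phenotype."""

    case_id: str
    window: Window
    densities: dict[str, float]
    counts: dict[str, int]
    window_area_mm2: float
    group: str = ""

    def to_series(self) -> pd.Series:
        return pd.Series(self.densities, name=self.case_id)


def _anchors(lo: float, hi: float, side: float, stride: float) -> np.ndarray:
    """Stride-grid anchors in [lo, hi - side], always including the last
    position flush with the far edge."""
    n = int(np.floor((hi - lo - side) / stride))
    xs = lo + stride * np.arange(n + 1)
    last = hi - side
    if last - xs[-1] > 1e-9:
        xs = np.append(xs, last)
    return xs


def find_hotspot(
    table: CellTable,
    window_side: float = 500.0,
    stride: float = 250.0,
    reference: str = "all",
) -> Window:
    """Locate the square window maximizing the count of reference cells.

    ``reference`` is ``"all"`` or a phenotype name (requires a gated
    table). If the window does not fit inside the cell bounding box the
    whole bounding box is used, with a warning.
    """
    if table.n_cells == 0:
        raise ValueError("cannot locate a hotspot in an empty table")
    if reference == "all":
        pts = table.coords
    else:
        pts = table.coords[table.phenotypes.to_numpy() == reference]
        if pts.shape[0] == 0:
            raise ValueError(f"no cells of reference phenotype {reference!r}")
    allx, ally = table.coords[:, 0], table.coords[:, 1]
    xmin, xmax = float(allx.min()), float(allx.max())
    ymin, ymax = float(ally.min()), float(ally.max())
    if window_side > (xmax - xmin) or window_side > (ymax - ymin):
        warnings.warn(
            f"window side {window_side} μm exceeds the cell bounding box; "
            "using the whole bounding box"
        )
        eps = 1e-6  # widen so max-coordinate cells stay inside the half-open box
        return Window(xmin, ymin, xmax - xmin + eps, ymax - ymin + eps)

    x, y = pts[:, 0], pts[:, 1]
    order = np.argsort(x, kind="stable")
    xs_sorted, ys_by_x = x[order], y[order]
    ax = _anchors(xmin, xmax, window_side, stride)
    ay = _anchors(ymin, ymax, window_side, stride)

    best_count, best = -1, None
    counts = np.zeros((len(ay), len(ax)), dtype=int)
    for jx, x0 in enumerate(ax):
        lo = np.searchsorted(xs_sorted, x0, side="left")
        hi = np.searchsorted(xs_sorted, x0 + window_side, side="left")
        ys = np.sort(ys_by_x[lo:hi], kind="stable")
        counts[:, jx] = np.searchsorted(ys, ay + window_side, side="left") - np.searchsorted(
            ys, ay, side="left"
        )
    # row-major argmax over (y, x) implements the (smallest y, then x) tie-break
    flat = int(np.argmax(counts))
    jy, jx = divmod(flat, len(ax))
    best = Window(float(ax[jx]), float(ay[jy]), window_side, window_side)
    best_count = int(counts[jy, jx])
    return best


def hotspot_densities(
    table: CellTable, window: Window, phenotypes: tuple[str, ...] | None = None
) -> DensityReport:
    """Per-phenotype densities (cells/mm²) inside a window.

    Counts use the half-open membership convention; density × area equals
    the integer count exactly.
    """
    if window.area_mm2 <= 0:
        raise ValueError("zero-area window")
    labels = table.phenotypes.to_numpy()
    inside = window.contains(table.coords[:, 0], table.coords[:, 1])
    if phenotypes is None:
        phenotypes = tuple(pd.unique(labels))
    counts = {p: int(np.sum(inside & (labels == p))) for p in phenotypes}
    area = window.area_mm2
    densities = {p: c / area for p, c in counts.items()}
    return DensityReport(
        case_id=table.case_id, window=window, densities=densities,
        counts=counts, window_area_mm2=area, group=table.group,
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupStatsResult:
    """Two-factor comparison of per-case hotspot densities.

    ``comparisons`` has one row per phenotype with the group contrast,
    pooled-variance p-value, Šidák-adjusted p-value and the rank-based
    fallback; ``anova`` is the two-factor ANOVA table; ``summary`` holds
    per group × phenotype medians and ranges.
    """

    comparisons: pd.DataFrame
    anova: pd.DataFrame
    summary: pd.DataFrame
    method: str = "two-way ANOVA, pooled-MSE contrasts, Sidak family correction"


def _long_frame(reports: list[DensityReport], groups: dict[str, str]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        grp = groups.get(rep.case_id, rep.group)
        for pheno, dens in rep.densities.items():
            rows.append((rep.case_id, grp, pheno, dens))
    return pd.DataFrame(rows, columns=["case_id", "group", "phenotype", "density"])


def group_stats(
    reports: list[DensityReport],
    groups: dict[str, str] | None = None,
    phenotypes: tuple[str, ...] | None = None,
) -> GroupStatsResult:
    """Compare hotspot densities between clinical groups per phenotype."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    long = _long_frame(reports, groups or {})
    if phenotypes is not None:
        long = long[long["phenotype"].isin(phenotypes)]
    group_names = sorted(long["group"].unique())
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    sizes = long.groupby("group")["case_id"].nunique()
    if (sizes < 1).any():
        raise ValueError("every group needs at least one case")

    fit = smf.ols("density ~ C(group) * C(phenotype)", data=long).fit()
    if fit.df_resid > 0:
        anova = sm.stats.anova_lm(fit, typ=2)
        mse = float(fit.mse_resid)
    else:
        # saturated fit (one case per group): no residual df, contrasts
        # fall back to the rank test / direct differences
        anova = pd.DataFrame(columns=["sum_sq", "df", "F", "PR(>F)"])
        mse = np.nan
    df_resid = float(fit.df_resid)

    phenos = sorted(long["phenotype"].unique())
    m = len(phenos)
    rows = []
    for pheno in phenos:
        sub = long[long["phenotype"] == pheno]
        cell = {g: sub.loc[sub["group"] == g, "density"].to_numpy() for g in group_names}
        if len(group_names) == 2:
            g1, g2 = group_names
            diff = float(cell[g2].mean() - cell[g1].mean())
            se = np.sqrt(mse * (1 / len(cell[g1]) + 1 / len(cell[g2])))
            if not np.isfinite(se) or se == 0:
                p = 1.0 if diff == 0 else (0.0 if np.isfinite(se) else np.nan)
                t = 0.0 if diff == 0 else np.inf
            else:
                t = diff / se
                p = float(2 * stats.t.sf(abs(t), df_resid))
            try:
                p_rank = float(stats.mannwhitneyu(cell[g1], cell[g2]).pvalue)
            except ValueError:
                p_rank = 1.0
        else:
            # per-phenotype F on the pooled residual variance
            grand = sub["density"].mean()
            ss_b = sum(len(v) * (v.mean() - grand) ** 2 for v in cell.values())
            df_b = len(group_names) - 1
            diff = np.nan
            if mse > 0:
                f = (ss_b / df_b) / mse
                p = float(stats.f.sf(f, df_b, df_resid))
            else:
                p = 1.0 if ss_b == 0 else 0.0
            try:
                p_rank = float(stats.kruskal(*cell.values()).pvalue)
            except ValueError:
                p_rank = 1.0
        rows.append((pheno, diff, p, p_rank))

    comp = pd.DataFrame(rows, columns=["phenotype", "mean_diff", "p", "p_rank"])
    comp["p_adj"] = _sidak(comp["p"].to_numpy(), m)
    comp["p_rank_adj"] = _sidak(comp["p_rank"].to_numpy(), m)
    comp = comp.set_index("phenotype")

    summary = (
        long.groupby(["group", "phenotype"])["density"]
        .agg(median="median", min="min", max="max", n="size")
        .reset_index()
    )
    return GroupStatsResult(comparisons=comp, anova=anova, summary=summary)


def _sidak(p: np.ndarray, m: int) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return 1.0 - (1.0 - np.clip(p, 0.0, 1.0)) ** m
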