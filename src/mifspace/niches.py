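"""Cellular-niche discovery from neighborhood composition profiles.

For each reference cell, its neighborhood profile is the phenotype
composition (fractions) of its spatial neighbors — by default the 20
nearest neighbors (the CODEX-style convention), optionally all cells
within a radius. K-means over the pooled profiles partitions cells into
"C-niches": recurring local microenvironments such as lymphoid
aggregates or vascular-rich zones. Niches are re-indexed 1..k by
descending cell count so reports are stable across runs; note that this
canonical numbering is a property of the fitted model, not comparable
across different datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .cells import PHENOTYPES, CellTable


def _categories(labels: np.ndarray) -> list[str]:
    present = set(labels)
    cats = [p for p in PHENOTYPES if p in present]
    cats += sorted(present - set(cats))
    return cats


def neighborhood_profiles(
    table: CellTable,
    mode: str = "knn",
    k_nn: int = 20,
    radius: float = 50.0,
    categories: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-cell phenotype composition of the spatial neighborhood.

    Rows index cells (by cell_id), columns are phenotypes, entries are
    neighbor fractions (reference cell excluded). In knn mode ties at the
    k-th neighbor distance are broken by row order; in radius mode
    isolated cells get an all-zero row.
    """
    labels = table.phenotypes.to_numpy()
    cats = list(categories) if categories is not None else _categories(labels)
    codes = np.array([cats.index(l) for l in labels])
    coords = table.coords
    n = len(coords)
    counts = np.zeros((n, len(cats)))

    if mode == "knn":
        if n < k_nn + 1:
            raise ValueError(f"knn mode needs at least {k_nn + 1} cells, got {n}")
        tree = cKDTree(coords)
        # query one extra neighbor to detect ties crossing the k-th boundary
        kq = min(k_nn + 2, n)
        dist, idx = tree.query(coords, k=kq)
        for i in range(n):
            di, ii = dist[i], idx[i]
            self_pos = np.flatnonzero(ii == i)
            keep = np.delete(np.arange(kq), self_pos[0] if self_pos.size else 0)
            di, ii = di[keep], ii[keep]
            if len(di) > k_nn and di[k_nn - 1] == di[k_nn]:
                # tie at the neighborhood boundary: resolve by (distance, row)
                d_all = np.linalg.norm(coords - coords[i], axis=1)
                order = np.lexsort((np.arange(n), d_all))
                order = order[order != i][:k_nn]
                nb = order
            else:
                nb = ii[:k_nn]
            counts[i] = np.bincount(codes[nb], minlength=len(cats))
    elif mode == "radius":
        tree = cKDTree(coords)
        for i, nbrs in enumerate(tree.query_ball_point(coords, radius)):
            nb = [j for j in nbrs if j != i]
            if nb:
                counts[i] = np.bincount(codes[nb], minlength=len(cats))
    else:
        raise ValueError(f"unknown neighborhood mode {mode!r}")

    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        profiles = np.where(totals > 0, counts / totals, 0.0)
    return pd.DataFrame(profiles, index=pd.Index(table.data["cell_id"], name="cell_id"),
                        columns=cats)


def pool_profiles(per_case: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-case profile matrices with a (case_id, cell_id) index,
    aligning phenotype columns (absent phenotypes fill with 0)."""
    frames = []
    cols: list[str] = []
    for df in per_case.values():
        cols += [c for c in df.columns if c not in cols]
    for case, df in per_case.items():
        out = df.reindex(columns=cols, fill_value=0.0)
        out.index = pd.MultiIndex.from_product(
            [[case], df.index], names=["case_id", "cell_id"]
        )
        frames.append(out)
    return pd.concat(frames)


@dataclass
class NicheModel:
    """Fitted niche clustering over pooled neighborhood profiles."""

    profiles: pd.DataFrame
    k: int
    centroids: pd.DataFrame  # niche × phenotype
    labels: pd.Series  # per cell, values 1..k
    inertia: float
    seed: int
    params: dict


def cluster_niches(
    profiles: pd.DataFrame, k: int = 6, seed: int = 0, n_init: int = 10
) -> NicheModel:
    """K-means (k-means++, ``n_init`` restarts) over profile rows.

    Niche ids are re-indexed by descending cell count, so niche 1 is
    always the most populous. Deterministic given ``seed``.
    """
    x = profiles.to_numpy(dtype=float)
    if k > len(x):
        raise ValueError(f"k={k} exceeds number of cells {len(x)}")
    if k > len(np.unique(x, axis=0)):
        raise ValueError(f"k={k} exceeds number of distinct profile rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(x)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")  # ties by original label
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    labels = pd.Series(remap[raw], index=profiles.index, name="niche")
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=pd.RangeIndex(1, k + 1, name="niche"),
        columns=profiles.columns,
    )
    return NicheModel(
        profiles=profiles, k=k, centroids=centroids, labels=labels,
        inertia=float(km.inertia_), seed=seed,
        params={"n_init": n_init, "algorithm": "k-means++"},
    )


@dataclass
class NicheReport:
    """Niche composition and per-case prevalence."""

    composition: pd.DataFrame  # niche × phenotype mean profile
    case_proportions: pd.DataFrame  # case × niche fractions
    predominant: dict[str, int]  # case → niche id


def niche_report(model: NicheModel, case_ids: pd.Series | None = None) -> NicheReport:
    """Summarize a fitted model: mean profile per niche, per-case niche
    proportions (each row sums to 1) and the predominant niche per case
    (ties go to the lower niche id)."""
    if case_ids is None:
        if isinstance(model.profiles.index, pd.MultiIndex):
            case_ids = model.profiles.index.get_level_values("case_id").to_series(
                index=model.profiles.index
            )
        else:
            case_ids = pd.Series("case", index=model.profiles.index)
    composition = model.profiles.groupby(model.labels).mean()
    composition.index.name = "niche"
    composition = composition.reindex(range(1, model.k + 1), fill_value=np.nan)

    tab = pd.crosstab(np.asarray(case_ids), model.labels.to_numpy())
    tab = tab.reindex(columns=range(1, model.k + 1), fill_value=0)
    proportions = tab.div(tab.sum(axis=1), axis=0)
    proportions.index.name = "case_id"
    proportions.columns.name = "niche"
    # idxmax returns the first (lowest) niche id on ties
    predominant = {str(c): int(proportions.loc[c].idxmax()) for c in proportions.index}
    return NicheReport(
        composition=composition, case_proportions=proportions, predominant=predominant
    )


def k_scan(
    profiles: pd.DataFrame,
    ks: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    seed: int = 0,
    n_init: int = 5,
    max_silhouette_n: int = 2000,
) -> pd.DataFrame:
    """Elbow/silhouette scan over candidate k, for choosing the niche
    count transparently. Silhouette uses a seeded subsample for speed."""
    x = profiles.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        if k >= len(x):
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
        if len(x) > max_silhouette_n:
            sub = rng.choice(len(x), max_silhouette_n, replace=False)
            sil = silhouette_score(x[sub], km.labels_[sub])
        else:
            sil = silhouette_score(x, km.labels_)
        rows.append((k, float(km.inertia_), float(sil)))
    return pd.DataFrame(rows, columns=["k", "inertia", "silhouette"])
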