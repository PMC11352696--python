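"""Radius proximity graph and permutation interaction enrichment.

Cells whose centroids lie within a fixed radius (15 μm by default,
inclusive) are treated as potential interacting partners. Interaction
structure between phenotypes is summarized as the symmetric matrix of
observed A–B edge counts and scored against a label-permutation null:
phenotype labels are shuffled uniformly over cells while positions (and
hence the edge set) stay fixed, giving per-pair z-scores and one-sided
enrichment p-values — the standard construction in neighborhood-analysis
practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cells import CellTable, flag_column


@dataclass
class ProximityGraph:
    """Undirected radius graph over one case's cells.

    ``edges`` holds row indices into the originating table (each unordered
    pair once, i < j); ``cell_ids`` maps row index → cell id.
    """

    cell_ids: np.ndarray
    coords: np.ndarray
    edges: np.ndarray  # (E, 2) int
    distances: np.ndarray  # (E,) μm
    radius: float

    @property
    def n_nodes(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id_a": self.cell_ids[self.edges[:, 0]],
            "id_b": self.cell_ids[self.edges[:, 1]],
            "distance_um": self.distances,
        })


@dataclass
class InteractionResult:
    """Observed counts plus permutation-null enrichment scores."""

    counts: pd.DataFrame  # phenotype × phenotype, symmetric ints
    z: pd.DataFrame
    p_perm: pd.DataFrame  # one-sided enrichment
    null_mean: pd.DataFrame
    n_perm: int
    seed: int


def build_proximity_graph(table: CellTable, radius: float = 15.0) -> ProximityGraph:
    """All unordered cell pairs with centroid distance ≤ radius (closed
    boundary; coincident distinct cells are connected; no self-edges)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = table.coords
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size == 0:
        pairs = np.empty((0, 2), dtype=int)
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    dist = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return ProximityGraph(
        cell_ids=table.data["cell_id"].to_numpy(),
        coords=coords, edges=pairs, distances=dist, radius=radius,
    )


def composite_labels(table: CellTable, flags: tuple[str, ...] = ("Ki67",)) -> pd.Series:
    """Expand phenotype labels with functional flags, e.g. ``Ki67+ CTL``.

    Cells positive for several listed flags get all prefixes in order.
    """
    labels = table.phenotypes.astype(str).copy()
    for fl in flags:
        col = flag_column(fl)
        if col not in table.data.columns:
            raise ValueError(f"flag column {col!r} missing; gate the table first")
        pos = table.data[col].astype(bool).to_numpy()
        labels[pos] = f"{fl}+ " + labels[pos]
    return labels


def _label_codes(
    graph: ProximityGraph, table: CellTable, labels: pd.Series | None
) -> tuple[np.ndarray, list[str]]:
    if labels is None:
        labels = table.phenotypes
    lab = np.asarray(labels, dtype=object)
    if len(lab) != graph.n_nodes:
        raise ValueError("labels length does not match graph nodes")
    if pd.isna(lab).any():
        raise ValueError("a graph node lacks a phenotype label")
    cats = sorted(set(lab))
    codes = np.searchsorted(np.array(cats, dtype=object), lab)
    return codes.astype(np.intp), cats


def _count_matrix(codes: np.ndarray, edges: np.ndarray, k: int) -> np.ndarray:
    a, b = codes[edges[:, 0]], codes[edges[:, 1]]
    flat = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    m = flat + flat.T
    np.fill_diagonal(m, np.diag(flat))
    return m


def interaction_counts(
    graph: ProximityGraph, table: CellTable, labels: pd.Series | None = None
) -> pd.DataFrame:
    """Symmetric phenotype × phenotype matrix of observed edge counts
    (diagonal counts same-phenotype edges once each)."""
    codes, cats = _label_codes(graph, table, labels)
    m = _count_matrix(codes, graph.edges, len(cats))
    return pd.DataFrame(m, index=cats, columns=cats)


def interaction_enrichment(
    graph: ProximityGraph,
    table: CellTable,
    n_perm: int = 1000,
    seed: int = 0,
    labels: pd.Series | None = None,
) -> InteractionResult:
    """Score observed pair counts against the label-permutation null.

    z = (observed − null mean) / null sd (0 where the null sd is 0);
    p = (1 + #{null ≥ observed}) / (1 + n_perm), one-sided for enrichment.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    codes, cats = _label_codes(graph, table, labels)
    # a single label degenerates gracefully: permutation leaves counts
    # fixed, the null sd is 0 and every z is 0
    k = len(cats)
    obs = _count_matrix(codes, graph.edges, k).astype(float)

    rng = np.random.default_rng(seed)
    total = np.zeros((k, k))
    total_sq = np.zeros((k, k))
    geq = np.zeros((k, k))
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        m = _count_matrix(perm, graph.edges, k)
        total += m
        total_sq += m.astype(float) ** 2
        geq += m >= obs
    mean = total / n_perm
    var = total_sq / n_perm - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, 0.0)
    p = (1.0 + geq) / (1.0 + n_perm)
    as_df = lambda a: pd.DataFrame(a, index=cats, columns=cats)  # noqa: E731
    return InteractionResult(
        counts=as_df(obs.astype(int)), z=as_df(z), p_perm=as_df(p),
        null_mean=as_df(mean), n_perm=n_perm, seed=seed,
    )
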