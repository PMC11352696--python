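"""Hotspot window selection, density reports and group statistics."""

import numpy as np
import pandas as pd
import pytest

from mifspace import (
    CellTable,
    DensityReport,
    Window,
    find_hotspot,
    gate_cells,
    generate_scene,
    group_stats,
    hotspot_densities,
)

from conftest import random_cell_table, uniform_scene_spec


def brute_force_best_window(table, side, stride, tol=1e-9):
    """Independent exhaustive scan over the same anchor grid."""
    pts = table.coords
    xmin, xmax = pts[:, 0].min(), pts[:, 0].max()
    ymin, ymax = pts[:, 1].min(), pts[:, 1].max()

    def anchors(lo, hi):
        out = [lo]
        while out[-1] + stride <= hi - side + tol:
            out.append(out[-1] + stride)
        if hi - side - out[-1] > tol:
            out.append(hi - side)
        return out

    best = (-1, None)
    for y0 in anchors(ymin, ymax):
        for x0 in anchors(xmin, xmax):
            c = int(np.sum((pts[:, 0] >= x0) & (pts[:, 0] < x0 + side)
                           & (pts[:, 1] >= y0) & (pts[:, 1] < y0 + side)))
            if c > best[0]:
                best = (c, (x0, y0))
    return best


def window_count(table, w: Window) -> int:
    return int(w.contains(table.coords[:, 0], table.coords[:, 1]).sum())


def test_uniform_grid_tie_breaks_top_left():
    """All windows tie on a regular grid; the top-left anchor wins."""
    xs, ys = np.meshgrid(np.arange(0, 1000, 50), np.arange(0, 1000, 50))
    data = pd.DataFrame({"cell_id": range(xs.size), "x": xs.ravel() + 0.5,
                         "y": ys.ravel() + 0.5})
    t = CellTable(data=data, markers=())
    w = find_hotspot(t, window_side=500, stride=250)
    assert (w.x0, w.y0) == (t.coords[:, 0].min(), t.coords[:, 1].min())


def test_dense_cluster_is_found():
    rng = np.random.default_rng(5)
    sparse = rng.uniform(0, 2000, (300, 2))
    cluster = rng.uniform(1200, 1600, (400, 2))
    pts = np.vstack([sparse, cluster])
    t = CellTable(data=pd.DataFrame({"cell_id": range(len(pts)),
                                     "x": pts[:, 0], "y": pts[:, 1]}), markers=())
    w = find_hotspot(t, window_side=500, stride=250)
    cx, cy = cluster.mean(axis=0)
    assert w.contains(np.array([cx]), np.array([cy]))[0]


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_hotspot_matches_exhaustive_anchor_scan(seed):
    t = random_cell_table(n=1500, seed=seed, side=1500.0)
    w = find_hotspot(t, window_side=400, stride=200)
    best_count, _ = brute_force_best_window(t, 400, 200)
    assert window_count(t, w) == best_count


def test_coarse_stride_near_fine_stride_optimum():
    """A stride of half the window side loses at most a bounded fraction
    of the 1 μm-stride optimum on a clustered scene."""
    rng = np.random.default_rng(9)
    pts = np.vstack([rng.uniform(0, 600, (1200, 2)),
                     rng.normal(300, 60, (800, 2))])
    t = CellTable(data=pd.DataFrame({"cell_id": range(len(pts)),
                                     "x": pts[:, 0], "y": pts[:, 1]}), markers=())
    w = find_hotspot(t, window_side=200, stride=100)
    fine, _ = brute_force_best_window(t, 200, 1.0)
    assert window_count(t, w) >= 0.9 * fine


def test_window_larger_than_bbox_warns_and_covers_all():
    t = random_cell_table(n=100, seed=1, side=300.0)
    with pytest.warns(UserWarning, match="bounding box"):
        w = find_hotspot(t, window_side=500)
    assert window_count(t, w) == t.n_cells


def test_empty_table_errors():
    t = CellTable(data=pd.DataFrame({"cell_id": [], "x": [], "y": []}), markers=())
    with pytest.raises(ValueError, match="empty"):
        find_hotspot(t)


class TestDensities:
    def test_definition(self):
        t = random_cell_table(n=100, seed=3, side=1000.0, labels=("CTL",))
        rep = hotspot_densities(t, Window(0, 0, 1000, 1000))
        assert rep.densities["CTL"] == pytest.approx(100.0)

    def test_half_open_right_bottom_edge_excluded(self):
        data = pd.DataFrame({"cell_id": [0, 1, 2], "x": [0.0, 500.0, 250.0],
                             "y": [0.0, 250.0, 500.0],
                             "phenotype": ["CTL", "CTL", "CTL"]})
        t = CellTable(data=data, markers=())
        rep = hotspot_densities(t, Window(0, 0, 500, 500))
        assert rep.counts["CTL"] == 1  # only the origin cell is inside

    def test_conservation_density_times_area_is_count(self, gated_mixed_scene):
        w = find_hotspot(gated_mixed_scene, window_side=400, stride=200)
        rep = hotspot_densities(gated_mixed_scene, w)
        total = sum(rep.densities.values()) * rep.window_area_mm2
        assert total == pytest.approx(window_count(gated_mixed_scene, w), abs=1e-9)

    def test_planted_density_recovered(self, default_gating):
        """A region planted at the immune-high CTL density is estimated
        within the 4-sigma Poisson sampling bound."""
        planted = 782.2
        spec = uniform_scene_spec(density=planted, mixture={"CTL": 1.0},
                                  side=1500.0, seed=13)
        t = gate_cells(generate_scene(spec), default_gating)
        w = Window(250, 250, 1000, 1000)
        rep = hotspot_densities(t, w)
        area = w.area_mm2
        assert abs(rep.densities["CTL"] - planted) <= 4 * np.sqrt(planted * area) / area

    def test_zero_area_window_errors(self, gated_mixed_scene):
        with pytest.raises(ValueError, match="zero-area"):
            hotspot_densities(gated_mixed_scene, Window(0, 0, 0, 100))


def make_report(case, group, dens):
    return DensityReport(case_id=case, window=Window(0, 0, 500, 500),
                         densities=dens, counts={k: int(v * 0.25) for k, v in dens.items()},
                         window_area_mm2=0.25, group=group)


class TestGroupStats:
    def test_identical_groups_null(self):
        dens = {"CTL": 10.0, "Th": 5.0}
        reports = [make_report(f"a{i}", "G1", dict(dens)) for i in range(3)]
        reports += [make_report(f"b{i}", "G2", dict(dens)) for i in range(3)]
        res = group_stats(reports)
        assert (res.comparisons["mean_diff"] == 0).all()
        assert (res.comparisons["p_adj"] >= 1 - 1e-9).all()

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        reports = [make_report(f"e{i}", "ESS", {"CTL": float(10 + rng.normal(0, 2)),
                                                "Th": float(8 + rng.normal(0, 2))})
                   for i in range(7)]
        reports += [make_report(f"s{i}", "SDUS", {"CTL": float(700 + rng.normal(0, 50)),
                                                  "Th": float(9 + rng.normal(0, 2))})
                    for i in range(2)]
        res = group_stats(reports)
        assert res.comparisons.loc["CTL", "p_adj"] < 0.05
        assert res.comparisons.loc["CTL", "mean_diff"] > 0

    def test_single_value_median(self):
        reports = [make_report("a", "G1", {"Th": 10.4}),
                   make_report("b", "G2", {"Th": 20.0})]
        res = group_stats(reports)
        row = res.summary[(res.summary["group"] == "G1") & (res.summary["phenotype"] == "Th")]
        assert row["median"].iloc[0] == 10.4

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="two groups"):
            group_stats([make_report("a", "G1", {"CTL": 1.0})])

    def test_null_calibration_small_n(self):
        """With 2 vs 7 cases drawn from one distribution, the rate of
        per-phenotype (unadjusted) false positives stays near alpha and
        the family-adjusted rate stays below it. 500 seeded simulations."""
        alpha, n_sim = 0.05, 500
        rng = np.random.default_rng(2024)
        phenos = ["CTL", "Th", "B", "Mac"]
        hits = 0
        fam_hits = 0
        for _ in range(n_sim):
            reports = [make_report(f"a{i}", "G1",
                                   {p: float(rng.normal(20, 5)) for p in phenos})
                       for i in range(7)]
            reports += [make_report(f"b{i}", "G2",
                                    {p: float(rng.normal(20, 5)) for p in phenos})
                        for i in range(2)]
            res = group_stats(reports)
            hits += int((res.comparisons["p"] < alpha).sum())
            fam_hits += int((res.comparisons["p_adj"] < alpha).any())
        per_test_rate = hits / (n_sim * len(phenos))
        se = np.sqrt(alpha * (1 - alpha) / (n_sim * len(phenos)))
        assert abs(per_test_rate - alpha) <= 2 * se + 0.01
        fam_se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert fam_hits / n_sim <= alpha + 2 * fam_se
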