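"""Synthetic scene generator: planted structure must be recoverable."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from mifspace import (
    AttractionPair,
    Disc,
    GatingConfig,
    IntensityModel,
    MarginSpec,
    Rect,
    RegionSpec,
    SceneSpec,
    gate_cells,
    generate_scene,
    make_paper_like_suite,
    make_planted_niche_scene,
)
from mifspace.scene import ESS_DENSITY_RANGES

from conftest import uniform_scene_spec


def test_zero_density_region_yields_empty_table():
    spec = uniform_scene_spec(density=0.0)
    table = generate_scene(spec)
    assert table.n_cells == 0


def test_pure_ctl_region_count_and_labels():
    """Poisson(1000) count within 4 sqrt(1000) and 100% CTL ground truth,
    with CD3/CD8 intensities from the positive log-normal component."""
    spec = uniform_scene_spec(density=1000.0, mixture={"CTL": 1.0}, seed=7)
    table = generate_scene(spec)
    assert abs(table.n_cells - 1000) <= 4 * np.sqrt(1000)
    assert (table.data["true_phenotype"] == "CTL").all()
    # positive component: log-intensity within 6 sd of the positive mean
    for marker in ("CD3", "CD8"):
        logs = np.log(table.data[marker])
        assert np.all(np.abs(logs - 2.0) < 6 * 0.25)
    # a negative marker stays in the negative component
    logs = np.log(table.data["CD20"])
    assert np.all(np.abs(logs - 0.0) < 6 * 0.25)


def test_determinism_same_spec_same_table():
    spec = uniform_scene_spec(density=500.0, mixture={"CTL": 0.5, "Mac": 0.5}, seed=11)
    t1, t2 = generate_scene(spec), generate_scene(spec)
    pd.testing.assert_frame_equal(t1.data, t2.data)


def test_attraction_relocates_within_radius():
    """With attracted fraction 1.0 every CTL must have a Mac within the
    attraction radius — verified by brute-force pair scan."""
    spec = uniform_scene_spec(
        density=800.0, mixture={"Mac": 0.5, "CTL": 0.5}, seed=3,
        attraction_pairs=(AttractionPair("Mac", "CTL", 15.0, 1.0),),
    )
    table = generate_scene(spec)
    mac = table.coords[table.data["true_phenotype"] == "Mac"]
    ctl = table.coords[table.data["true_phenotype"] == "CTL"]
    dmin = cdist(ctl, mac).min(axis=1)
    assert (dmin <= 15.0 + 1e-9).all()


def test_density_recovery_over_replicates():
    """Estimated density is within 4 standard errors of the planted
    density when averaged over 100 seeded replicates."""
    density, area = 500.0, 1.0  # 1 mm² region
    counts = [
        generate_scene(uniform_scene_spec(density=density, seed=s,
                                          intensity_model=IntensityModel.default(("CD3",)))).n_cells
        for s in range(100)
    ]
    se = np.sqrt(density * area) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - density) <= 4 * se


def test_phenotype_recoverability_from_intensities(default_gating):
    """Default midpoint gating recovers >= 99% of planted phenotypes on a
    10^4-cell scene with the separable default intensity model."""
    mixture = {"CTL": 0.12, "Th": 0.12, "T_other": 0.05, "B": 0.08, "Mac": 0.08,
               "Myeloid": 0.05, "Endothelial": 0.05, "Fibroblast": 0.05,
               "SmoothMuscle": 0.05, "Other": 0.35}
    spec = uniform_scene_spec(density=10_000.0, mixture=mixture, seed=5)
    table = gate_cells(generate_scene(spec), default_gating)
    agree = (table.data["phenotype"] == table.data["true_phenotype"]).mean()
    assert table.n_cells > 9000
    assert agree >= 0.99


def test_margin_band_plants_pd1_t_and_pdl1_tumor():
    margin = MarginSpec(band_axis="y", band_center=500.0, band_halfwidth=100.0,
                        pd1_t_density=200.0, pdl1_tumor_density=200.0)
    spec = uniform_scene_spec(density=100.0, mixture={"Other": 1.0}, seed=9,
                              margin_band=margin)
    table = generate_scene(spec)
    t = table.data[table.data["true_PD1_pos"] == 1]
    tum = table.data[table.data["true_PDL1_pos"] == 1]
    assert len(t) > 0 and len(tum) > 0
    assert (t["true_phenotype"] == "T_other").all()
    assert t["y"].between(400, 600).all() and tum["y"].between(400, 600).all()


def test_overlapping_regions_with_conflicting_niches_error():
    r1 = RegionSpec(Rect(0, 0, 500, 500), 100.0, {"CTL": 1.0}, niche_id=1)
    r2 = RegionSpec(Disc(250, 250, 100), 100.0, {"Mac": 1.0}, niche_id=2)
    with pytest.raises(ValueError, match="conflicting niche ids"):
        SceneSpec(roi_width=500, roi_height=500, regions=(r1, r2))


def test_empty_roi_errors():
    with pytest.raises(ValueError, match="ROI"):
        SceneSpec(roi_width=0, roi_height=100, regions=())


def test_mixture_must_sum_to_one():
    with pytest.raises(ValueError, match="sums to"):
        RegionSpec(Rect(0, 0, 100, 100), 10.0, {"CTL": 0.7}, niche_id=1)


def test_intensity_model_requires_separability():
    with pytest.raises(ValueError, match="separable"):
        IntensityModel({"CD3": 0.0}, {"CD3": 0.2}, {"CD3": 1.0}, {"CD3": 0.2})


class TestPaperLikeSuite:
    def test_ess_like_expected_th_density_in_low_range(self):
        spec = make_paper_like_suite("ESS-like", 1)
        assert spec.expected_density("Th") <= ESS_DENSITY_RANGES["Th"][2]
        assert spec.expected_density("CTL") <= ESS_DENSITY_RANGES["CTL"][2]

    def test_sdus_like_ctl_at_least_tenfold_ess(self):
        ess = make_paper_like_suite("ESS-like", 1)
        sdus = make_paper_like_suite("SDUS-like", 1)
        assert sdus.expected_density("CTL") >= 10 * ess.expected_density("CTL")

    def test_same_profile_same_seed_identical_specs(self):
        assert make_paper_like_suite("ESS-like", 4) == make_paper_like_suite("ESS-like", 4)

    def test_unknown_profile_errors(self):
        with pytest.raises(ValueError, match="unknown profile"):
            make_paper_like_suite("HG-ESS", 0)

    def test_sdus_like_has_clusters_margin_and_attraction(self):
        spec = make_paper_like_suite("SDUS-like", 2)
        assert spec.margin_band is not None
        assert len(spec.attraction_pairs) == 2
        assert len({r.niche_id for r in spec.regions}) == 3


def test_planted_niche_scene_share():
    spec = make_planted_niche_scene(0, predominant_share=0.6)
    areas = {r.niche_id: r.geometry.area_um2 / 1e6 for r in spec.regions}
    expected = {nid: r.cell_density * areas[nid] for nid, r in
                zip([r.niche_id for r in spec.regions], spec.regions)}
    share = expected[3] / sum(expected.values())
    assert share == pytest.approx(0.6, abs=1e-9)
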