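"""Synthetic mIF scene generation with known ground truth.

The study's slides are not deposited, so every downstream stage is
exercised on simulated segmented-cell tables whose phenotypes, niches,
attraction structure and invasive-margin band are planted and therefore
recoverable. The generative model:

* per region, cell count ~ Poisson(density × area), positions uniform in
  the region geometry (homogeneous Poisson process);
* per cell, an exclusive phenotype drawn from the region mixture and
  non-exclusive functional flags drawn per-phenotype;
* marker intensities drawn from a two-component log-normal (positive
  component for the phenotype's defining markers and any set flags,
  negative component otherwise);
* phenotype attraction planted by thinning-and-displacement: a fraction
  of B-phenotype cells is relocated uniformly into a disc of the
  attraction radius around a randomly chosen A-phenotype cell;
* an optional invasive-margin band of PD-1+ T cells and PD-L1+ tumor
  cells.

All randomness flows from a single seeded ``numpy.random.Generator``, so
an identical spec (including its seed) reproduces a byte-identical table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from .cells import (
    FUNCTIONAL_FLAGS,
    MARKERS,
    PHENOTYPE_POSITIVE_MARKERS,
    PHENOTYPES,
    CellTable,
    flag_column,
)

UM2_PER_MM2 = 1e6  # μm² in a mm²


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, μm; (x0, y0) is the top-left corner."""

    x0: float
    y0: float
    width: float
    height: float

    @property
    def area_um2(self) -> float:
        return self.width * self.height

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.random((n, 2))
        return np.column_stack(
            [self.x0 + u[:, 0] * self.width, self.y0 + u[:, 1] * self.height]
        )

    def shapely(self):
        return box(self.x0, self.y0, self.x0 + self.width, self.y0 + self.height)


@dataclass(frozen=True)
class Disc:
    """Disc of radius ``r`` (μm) centred at (cx, cy)."""

    cx: float
    cy: float
    r: float

    @property
    def area_um2(self) -> float:
        return np.pi * self.r**2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # polar with sqrt-radius for uniform area density
        rad = self.r * np.sqrt(rng.random(n))
        theta = rng.random(n) * 2 * np.pi
        return np.column_stack(
            [self.cx + rad * np.cos(theta), self.cy + rad * np.sin(theta)]
        )

    def shapely(self):
        return Point(self.cx, self.cy).buffer(self.r, quad_segs=64)


Geometry = Rect | Disc


# ---------------------------------------------------------------------------
# spec dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityModel:
    """Two-component log-normal intensity model, one pair per marker.

    Intensities are in arbitrary units; a marker-positive cell draws
    ``exp(N(positive_log_mean, positive_log_sd))`` and a negative cell the
    negative component. Separability (positive log-mean strictly above the
    negative) is required so that midpoint thresholds gate cleanly.
    """

    positive_log_mean: dict[str, float]
    positive_log_sd: dict[str, float]
    negative_log_mean: dict[str, float]
    negative_log_sd: dict[str, float]

    def __post_init__(self) -> None:
        for m in self.positive_log_mean:
            if self.positive_log_mean[m] <= self.negative_log_mean[m]:
                raise ValueError(f"intensity model not separable for marker {m!r}")

    @classmethod
    def default(
        cls,
        markers: tuple[str, ...] = MARKERS,
        positive_log_mean: float = 2.0,
        positive_log_sd: float = 0.25,
        negative_log_mean: float = 0.0,
        negative_log_sd: float = 0.25,
    ) -> "IntensityModel":
        return cls(
            {m: positive_log_mean for m in markers},
            {m: positive_log_sd for m in markers},
            {m: negative_log_mean for m in markers},
            {m: negative_log_sd for m in markers},
        )

    def midpoint_thresholds(self) -> dict[str, float]:
        """Per-marker threshold midway between components in log space."""
        return {
            m: float(np.exp(0.5 * (self.positive_log_mean[m] + self.negative_log_mean[m])))
            for m in self.positive_log_mean
        }


@dataclass(frozen=True)
class RegionSpec:
    """A spatial region with its own density, mixture and true niche id."""

    geometry: Geometry
    cell_density: float  # cells per mm²
    phenotype_mixture: dict[str, float]
    niche_id: int

    def __post_init__(self) -> None:
        if self.cell_density < 0:
            raise ValueError("cell_density must be >= 0")
        total = sum(self.phenotype_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phenotype mixture sums to {total}, not 1")
        unknown = set(self.phenotype_mixture) - set(PHENOTYPES)
        if unknown:
            raise ValueError(f"unknown phenotypes in mixture: {sorted(unknown)}")


@dataclass(frozen=True)
class MarginSpec:
    """Invasive-margin band of PD-1+ T cells facing PD-L1+ tumor cells.

    The band is the strip where the ``band_axis`` coordinate lies within
    ``band_halfwidth`` of ``band_center``, clipped to the ROI.
    """

    band_axis: Literal["x", "y"]
    band_center: float
    band_halfwidth: float
    pd1_t_density: float  # per mm²
    pdl1_tumor_density: float  # per mm²


@dataclass(frozen=True)
class AttractionPair:
    """Planted spatial attraction: a fraction of B cells is displaced to
    within ``radius`` μm of a uniformly chosen A cell."""

    phenotype_a: str
    phenotype_b: str
    radius: float  # μm
    fraction: float  # of B cells relocated, in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("attracted fraction must lie in [0, 1]")
        if self.radius <= 0:
            raise ValueError("attraction radius must be > 0")


@dataclass(frozen=True)
class SceneSpec:
    """Full generative description of one synthetic case."""

    roi_width: float  # μm
    roi_height: float  # μm
    regions: tuple[RegionSpec, ...]
    attraction_pairs: tuple[AttractionPair, ...] = ()
    margin_band: MarginSpec | None = None
    intensity_model: IntensityModel = field(default_factory=IntensityModel.default)
    functional_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0
    case_id: str = "case"
    group: str = ""

    def __post_init__(self) -> None:
        if self.roi_width <= 0 or self.roi_height <= 0:
            raise ValueError("empty ROI: dimensions must be positive")
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "attraction_pairs", tuple(self.attraction_pairs))
        self._check_overlap()
        if self.margin_band is not None:
            mb = self.margin_band
            lo, hi = (0.0, self.roi_width) if mb.band_axis == "x" else (0.0, self.roi_height)
            if not (lo <= mb.band_center - mb.band_halfwidth and mb.band_center + mb.band_halfwidth <= hi):
                raise ValueError("margin band must lie within the ROI")

    def _check_overlap(self) -> None:
        geoms = [(r.geometry.shapely(), r.niche_id) for r in self.regions]
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                gi, ni = geoms[i]
                gj, nj = geoms[j]
                if ni != nj and gi.intersection(gj).area > 1e-6:
                    raise ValueError(
                        f"regions {i} and {j} overlap with conflicting niche ids {ni} vs {nj}"
                    )

    @property
    def roi_area_mm2(self) -> float:
        return self.roi_width * self.roi_height / UM2_PER_MM2

    def expected_density(self, phenotype: str) -> float:
        """Expected ROI-wide density (cells/mm²) of a phenotype: the sum of
        region contributions plus the margin band, divided by ROI area."""
        expected = sum(
            r.cell_density
            * r.phenotype_mixture.get(phenotype, 0.0)
            * (r.geometry.area_um2 / UM2_PER_MM2)
            for r in self.regions
        )
        if self.margin_band is not None:
            area = _band_area_mm2(self)
            if phenotype == "T_other":
                expected += self.margin_band.pd1_t_density * area
            elif phenotype == "Other":
                expected += self.margin_band.pdl1_tumor_density * area
        return expected / self.roi_area_mm2


def _band_area_mm2(spec: SceneSpec) -> float:
    mb = spec.margin_band
    length = spec.roi_height if mb.band_axis == "x" else spec.roi_width
    return 2 * mb.band_halfwidth * length / UM2_PER_MM2


def _band_rect(spec: SceneSpec) -> Rect:
    mb = spec.margin_band
    if mb.band_axis == "x":
        return Rect(mb.band_center - mb.band_halfwidth, 0.0, 2 * mb.band_halfwidth, spec.roi_height)
    return Rect(0.0, mb.band_center - mb.band_halfwidth, spec.roi_width, 2 * mb.band_halfwidth)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_scene(spec: SceneSpec) -> CellTable:
    """Draw one synthetic segmented-cell table from a :class:`SceneSpec`.

    Returns a :class:`CellTable` whose data carries ``true_phenotype`` and
    ``true_niche`` ground-truth columns alongside coordinates and marker
    intensities. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    xs, ys, phenos, niches, forced_flags = [], [], [], [], []

    for region in spec.regions:
        area_mm2 = region.geometry.area_um2 / UM2_PER_MM2
        n = int(rng.poisson(region.cell_density * area_mm2))
        pts = region.geometry.sample(n, rng)
        names = list(region.phenotype_mixture)
        probs = np.array([region.phenotype_mixture[p] for p in names])
        labels = rng.choice(names, size=n, p=probs / probs.sum())
        xs.append(pts[:, 0]); ys.append(pts[:, 1])
        phenos.append(labels)
        niches.append(np.full(n, region.niche_id))
        forced_flags.append(np.zeros((n, len(FUNCTIONAL_FLAGS)), dtype=bool))

    if spec.margin_band is not None:
        band = _band_rect(spec)
        area = _band_area_mm2(spec)
        n_t = int(rng.poisson(spec.margin_band.pd1_t_density * area))
        n_tum = int(rng.poisson(spec.margin_band.pdl1_tumor_density * area))
        pts = band.sample(n_t + n_tum, rng)
        xs.append(pts[:, 0]); ys.append(pts[:, 1])
        phenos.append(np.array(["T_other"] * n_t + ["Other"] * n_tum, dtype=object))
        niches.append(np.zeros(n_t + n_tum, dtype=int))
        forced = np.zeros((n_t + n_tum, len(FUNCTIONAL_FLAGS)), dtype=bool)
        forced[:n_t, FUNCTIONAL_FLAGS.index("PD1")] = True
        forced[n_t:, FUNCTIONAL_FLAGS.index("PDL1")] = True
        forced_flags.append(forced)

    if xs:
        x = np.concatenate(xs); y = np.concatenate(ys)
        pheno = np.concatenate(phenos).astype(object)
        niche = np.concatenate(niches).astype(int)
        forced = np.concatenate(forced_flags, axis=0)
    else:
        x = y = np.empty(0)
        pheno = np.empty(0, dtype=object)
        niche = np.empty(0, dtype=int)
        forced = np.zeros((0, len(FUNCTIONAL_FLAGS)), dtype=bool)
    n_total = len(x)

    # functional flags: forced (margin) OR drawn per phenotype
    flags = forced.copy()
    for j, fl in enumerate(FUNCTIONAL_FLAGS):
        p = np.array(
            [spec.functional_probs.get(ph, {}).get(fl, 0.0) for ph in pheno], dtype=float
        )
        flags[:, j] |= rng.random(n_total) < p

    # attraction by thinning-and-displacement
    region_lookup = [(r.geometry.shapely(), r.niche_id) for r in spec.regions]
    for pair in spec.attraction_pairs:
        a_idx = np.flatnonzero(pheno == pair.phenotype_a)
        b_idx = np.flatnonzero(pheno == pair.phenotype_b)
        if a_idx.size == 0:
            warnings.warn(
                f"attraction pair {pair.phenotype_a}-{pair.phenotype_b}: "
                "no A cells in scene, skipping"
            )
            continue
        move = b_idx[rng.random(b_idx.size) < pair.fraction]
        anchors = a_idx[rng.integers(0, a_idx.size, size=move.size)]
        for b, a in zip(move, anchors):
            x[b], y[b] = _sample_near(x[a], y[a], pair.radius, spec, rng)
            niche[b] = _containing_niche(x[b], y[b], region_lookup)

    intensities = _draw_intensities(spec, pheno, flags, rng)

    data = pd.DataFrame({"cell_id": np.arange(n_total, dtype=int), "x": x, "y": y})
    for m in spec.intensity_model.positive_log_mean:
        data[m] = intensities[m]
    data["true_phenotype"] = pheno
    data["true_niche"] = niche
    for j, fl in enumerate(FUNCTIONAL_FLAGS):
        data[f"true_{flag_column(fl)}"] = flags[:, j].astype(int)
    return CellTable(
        data=data,
        markers=tuple(spec.intensity_model.positive_log_mean),
        case_id=spec.case_id,
        group=spec.group,
    )


def _sample_near(
    ax: float, ay: float, radius: float, spec: SceneSpec, rng: np.random.Generator
) -> tuple[float, float]:
    """Uniform point in the disc of ``radius`` around (ax, ay) ∩ ROI."""
    for _ in range(256):
        r = radius * np.sqrt(rng.random())
        t = rng.random() * 2 * np.pi
        px, py = ax + r * np.cos(t), ay + r * np.sin(t)
        if 0 <= px <= spec.roi_width and 0 <= py <= spec.roi_height:
            return px, py
    return ax, ay  # anchor itself is always inside the ROI


def _containing_niche(px: float, py: float, region_lookup) -> int:
    pt = Point(px, py)
    for geom, niche_id in region_lookup:
        if geom.covers(pt):
            return niche_id
    return 0


def _draw_intensities(
    spec: SceneSpec, pheno: np.ndarray, flags: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    im = spec.intensity_model
    markers = list(im.positive_log_mean)
    n = len(pheno)
    out: dict[str, np.ndarray] = {}
    flag_idx = {fl: j for j, fl in enumerate(FUNCTIONAL_FLAGS)}
    pos_sets = {p: set(PHENOTYPE_POSITIVE_MARKERS.get(p, ())) for p in PHENOTYPES}
    for m in markers:
        positive = np.fromiter((m in pos_sets.get(p, set()) for p in pheno), bool, n)
        if m in flag_idx:
            positive |= flags[:, flag_idx[m]]
        mu = np.where(positive, im.positive_log_mean[m], im.negative_log_mean[m])
        sd = np.where(positive, im.positive_log_sd[m], im.negative_log_sd[m])
        out[m] = np.exp(rng.normal(mu, sd))
    return out


# ---------------------------------------------------------------------------
# paper-shaped case suites
# ---------------------------------------------------------------------------

# ROI-wide medians and ranges (cells/mm²) of the immune-low endometrial
# stromal sarcoma profile, and the immune-high hotspot targets for the
# SMARCA4-deficient profile.
ESS_DENSITY_RANGES = {
    "Th": (10.4, 0.0, 64.5),
    "CTL": (9.8, 2.0, 22.2),
    "B": (1.2, 0.4, 21.6),
    "Mac": (6.6, 2.4, 35.5),
}
SDUS_HOTSPOT_TARGETS = {"CTL": 782.2, "Th": 382.0, "B": 147.9, "Mac": 140.0}

_ROI_SIDE = 2000.0  # μm; 4 mm² scenes
_TILE = 500.0


def make_paper_like_suite(profile: str, seed: int, case_id: str | None = None) -> SceneSpec:
    """Build a SceneSpec emulating one study case.

    ``"ESS-like"`` is an immune-low scene: a single uniform region whose
    immune densities are drawn per seed around the reported medians and
    clipped to the reported ranges. ``"SDUS-like"`` is an immune-high scene:
    a 4×4 grid of 500 μm tiles typed background / lymphoid-aggregate /
    vascular (the planted niches), a PD-1/PD-L1 invasive-margin band,
    Th–B and CTL–Th attraction, and a planted Ki67 composition in which
    CTLs are 20% and Th + B cells 14% of proliferating cells.
    """
    rng = np.random.default_rng(seed)
    if profile == "ESS-like":
        return _ess_like(rng, seed, case_id or f"ESS_{seed}")
    if profile == "SDUS-like":
        return _sdus_like(rng, seed, case_id or f"SDUS_{seed}")
    raise ValueError(f"unknown profile {profile!r}; expected 'ESS-like' or 'SDUS-like'")


def _ess_like(rng: np.random.Generator, seed: int, case_id: str) -> SceneSpec:
    dens = {}
    for pheno, (median, lo, hi) in ESS_DENSITY_RANGES.items():
        d = median * float(np.exp(rng.normal(0.0, 0.5)))
        dens[pheno] = float(np.clip(d, max(lo, 0.05 * median + 1e-3), hi))
    total = 1500.0  # cells/mm²: tumor-cell-dominated field
    extra = {"T_other": 4.0, "Myeloid": 5.0, "Endothelial": 30.0,
             "Fibroblast": 80.0, "SmoothMuscle": 150.0}
    mixture = {p: d / total for p, d in {**dens, **extra}.items()}
    mixture["Other"] = 1.0 - sum(mixture.values())
    region = RegionSpec(
        geometry=Rect(0.0, 0.0, _ROI_SIDE, _ROI_SIDE),
        cell_density=total,
        phenotype_mixture=mixture,
        niche_id=1,
    )
    functional = {p: {"Ki67": 0.02} for p in mixture}
    functional["CTL"] = {"Ki67": 0.02, "GZMB": 0.10, "PD1": 0.05}
    return SceneSpec(
        roi_width=_ROI_SIDE, roi_height=_ROI_SIDE, regions=(region,),
        functional_probs=functional, seed=seed, case_id=case_id, group="ESS",
    )


def _tile_mixture(base: dict[str, float]) -> dict[str, float]:
    mix = dict(base)
    mix["Other"] = 1.0 - sum(mix.values())
    assert mix["Other"] >= 0
    return mix


def _sdus_like(rng: np.random.Generator, seed: int, case_id: str) -> SceneSpec:
    jit = lambda v, s=0.08: float(v * np.exp(rng.normal(0.0, s)))  # noqa: E731

    # lymphoid-aggregate tiles: planted so the densest (hotspot) tile carries
    # the reported immune-high densities
    lymph_total = 3000.0
    lymph_mix = _tile_mixture({
        "CTL": jit(SDUS_HOTSPOT_TARGETS["CTL"]) / lymph_total,
        "Th": jit(SDUS_HOTSPOT_TARGETS["Th"]) / lymph_total,
        "B": jit(SDUS_HOTSPOT_TARGETS["B"]) / lymph_total,
        "Mac": jit(SDUS_HOTSPOT_TARGETS["Mac"]) / lymph_total,
        "T_other": 0.02, "Endothelial": 0.03,
    })
    vasc_total = 2000.0
    vasc_mix = _tile_mixture({
        "Endothelial": 0.20, "Mac": 0.10, "CTL": 0.08,
        "SmoothMuscle": 0.12, "Th": 0.03,
    })
    bg_total = 1200.0
    bg_mix = _tile_mixture({
        "CTL": 0.02, "Th": 0.01, "Mac": 0.02, "Myeloid": 0.02,
        "Endothelial": 0.02, "Fibroblast": 0.03, "SmoothMuscle": 0.03,
    })

    n_side = int(_ROI_SIDE / _TILE)
    order = rng.permutation(n_side * n_side)
    tile_type = np.full(n_side * n_side, 1)  # background niche
    tile_type[order[:4]] = 3   # lymphoid-aggregate niche
    tile_type[order[4:7]] = 2  # vascular niche
    params = {1: (bg_total, bg_mix), 2: (vasc_total, vasc_mix), 3: (lymph_total, lymph_mix)}
    regions = []
    for t in range(n_side * n_side):
        i, j = divmod(t, n_side)
        density, mix = params[int(tile_type[t])]
        regions.append(RegionSpec(
            geometry=Rect(j * _TILE, i * _TILE, _TILE, _TILE),
            cell_density=density, phenotype_mixture=mix, niche_id=int(tile_type[t]),
        ))

    margin = MarginSpec(
        band_axis="y", band_center=jit(1000.0, 0.05), band_halfwidth=100.0,
        pd1_t_density=150.0, pdl1_tumor_density=300.0,
    )
    attraction = (
        AttractionPair("Th", "B", 15.0, 0.4),
        AttractionPair("CTL", "Th", 15.0, 0.4),
    )
    spec = SceneSpec(
        roi_width=_ROI_SIDE, roi_height=_ROI_SIDE, regions=tuple(regions),
        attraction_pairs=attraction, margin_band=margin,
        seed=seed, case_id=case_id, group="SDUS",
    )
    functional = _ki67_plan(spec, rng)
    functional.setdefault("CTL", {})["GZMB"] = 0.30
    functional.setdefault("CTL", {})["PD1"] = 0.10
    functional.setdefault("Th", {})["PD1"] = 0.10
    functional.setdefault("Other", {})["PDL1"] = 0.05
    functional.setdefault("Mac", {})["PDL1"] = 0.10
    return SceneSpec(
        roi_width=spec.roi_width, roi_height=spec.roi_height, regions=spec.regions,
        attraction_pairs=spec.attraction_pairs, margin_band=spec.margin_band,
        intensity_model=spec.intensity_model, functional_probs=functional,
        seed=seed, case_id=case_id, group="SDUS",
    )


def make_planted_niche_scene(
    seed: int,
    predominant_share: float = 0.6,
    base_density: float = 400.0,
    dominant_fraction: float = 0.75,
) -> SceneSpec:
    """A six-niche benchmark scene for clustering recovery.

    Six square regions on a 3×2 grid, separated by 300 μm gaps (wider
    than any default neighborhood), each dominated by a different
    phenotype so neighborhood profiles are well separated. Region with
    niche id 3 is made dense enough to hold ``predominant_share`` of all
    cells, giving a known predominant niche.
    """
    dominants = ("CTL", "Th", "B", "Mac", "Endothelial", "Other")
    minor = ("Myeloid", "Fibroblast")
    side, cell = 700.0, 1000.0
    pad = (cell - side) / 2
    n_regions = len(dominants)
    # density of region 3 so that its Poisson mean is the target share
    d3 = base_density * (n_regions - 1) * predominant_share / (1 - predominant_share)
    regions = []
    for idx, dom in enumerate(dominants):
        i, j = divmod(idx, 3)
        mix = {dom: dominant_fraction}
        rest = (1.0 - dominant_fraction) / len(minor)
        for m in minor:
            mix[m] = rest
        niche_id = idx + 1
        regions.append(RegionSpec(
            geometry=Rect(j * cell + pad, i * cell + pad, side, side),
            cell_density=d3 if niche_id == 3 else base_density,
            phenotype_mixture=mix,
            niche_id=niche_id,
        ))
    return SceneSpec(
        roi_width=3 * cell, roi_height=2 * cell, regions=tuple(regions),
        seed=seed, case_id=f"planted6_{seed}",
    )


#: Planted composition of the proliferating (Ki67+) compartment: CTLs 20%,
#: Th and B cells 7% each (14% combined).
KI67_COMPOSITION = {
    "CTL": 0.20, "Th": 0.07, "B": 0.07, "Mac": 0.14,
    "Endothelial": 0.05, "Other": 0.47,
}
KI67_OVERALL_RATE = 0.05  # fraction of all cells that proliferate


def _ki67_plan(spec: SceneSpec, rng: np.random.Generator) -> dict[str, dict[str, float]]:
    """Per-phenotype Ki67 probabilities realizing KI67_COMPOSITION."""
    area = spec.roi_area_mm2
    expected = {p: spec.expected_density(p) * area for p in PHENOTYPES}
    n_total = sum(expected.values())
    target_ki67 = KI67_OVERALL_RATE * n_total
    out: dict[str, dict[str, float]] = {}
    for pheno, frac in KI67_COMPOSITION.items():
        if expected.get(pheno, 0.0) > 0:
            out[pheno] = {"Ki67": float(np.clip(target_ki67 * frac / expected[pheno], 0.0, 1.0))}
    return out
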