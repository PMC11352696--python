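# Methods

This note documents the models, conventions and design choices behind
`mifspace`, and what the synthetic benchmarks do and do not demonstrate
about real tissue data.

## Coordinate and unit conventions

All coordinates are centroid positions in micrometres, origin at the
top-left, y increasing downward (image convention). Densities are cells
per mm² (1 mm² = 10⁶ μm²). Marker intensities are arbitrary units, as in
QuPath mean-intensity exports; a `scale` factor at read time converts
pixel-based coordinate exports when the pixel size is known.

## Phenotyping model

Positivity is a per-marker threshold with a **closed** boundary
(intensity ≥ threshold is positive), so a cell exactly at threshold is
positive — a documented convention, tested at the boundary. Exclusive
lineage labels come from an ordered rule list; the first rule whose
positive/negative pattern matches wins, and unmatched cells are "Other".
The default precedence (CTL ≻ Th ≻ T_other ≻ B ≻ Mac ≻ Myeloid ≻
Endothelial ≻ Fibroblast ≻ SmoothMuscle) resolves colocalised markers in
favour of the more specific T-cell identity; in particular
CD3⁺CD4⁺CD8⁺ cells gate as CTL by precedence, an explicit choice since
intensity data alone cannot arbitrate such doublets. PD-1, PD-L1, Ki67
and Granzyme B are non-exclusive functional flags on top of lineage,
because biological readouts of interest combine them ("PD-1⁺ T cell",
"Ki67⁺ CTL").

Default thresholds are the log-space midpoints of the synthetic
intensity model's negative/positive components. Real-data use requires
explicit per-marker thresholds in the gating config; no automatic
thresholding (e.g. Otsu) is attempted, keeping every gate auditable.

## Hotspot selection

Immune infiltration is strongly heterogeneous across a slide, so
per-case statistics are computed in the maximum-density window rather
than slide-wide. The window is a 500 μm square (0.25 mm²) by default —
large enough for stable counts of phenotypes at ≥ ~10 cells/mm², small
enough to isolate an infiltrated focus — slid on a 250 μm stride grid
over the cell bounding box, with a final anchor flush against each far
edge. Ties are broken toward the smallest y, then x anchor, making the
choice deterministic. Membership is half-open, [x0, x0+w) × [y0, y0+w),
so tiling a region never double-counts a cell and density × area is an
integer count exactly. One consequence of the 0.25 mm² window: densities
are quantised in steps of 4 cells/mm², so phenotypes at ~1 cell/mm²
(e.g. B cells in immune-low cases) often report 0 in a single window.

## Group statistics

Per-case hotspot densities enter a two-factor (group × phenotype)
ordinary-least-squares ANOVA. Per-phenotype group contrasts use the
pooled residual mean square with Šidák family correction across
phenotypes (p_adj = 1 − (1 − p)^m) — the default family correction of
common two-way-ANOVA multiple-comparison workflows. Because case counts
in rare-tumor studies are tiny (here 7 vs 2), a rank-based fallback
(Mann–Whitney for two groups, Kruskal–Wallis otherwise, same correction)
is always reported alongside; with n = 2 in a group the rank test cannot
reach p < 0.05, which is the honest statement of what ranks alone
support at that sample size. A 500-replicate null simulation in the test
suite confirms the parametric contrast holds its nominal size at these
case counts. When the design is saturated (one case per group) the
pooled variance does not exist and only medians, ranges and rank
statistics are meaningful; the ANOVA table is then empty.

## Interaction enrichment

The proximity graph joins all cell pairs with centroid distance ≤ 15 μm
(inclusive, so "within 15 μm" keeps its plain meaning; coincident
centroids with distinct ids are connected; no self-edges). Construction
uses a k-d tree but is tested to equal O(n²) enumeration exactly.

Observed phenotype-pair edge counts are scored against the standard
label-permutation null of neighborhood analysis: labels are permuted
uniformly over cells, positions and hence the edge set stay fixed, and

    z = (obs − mean_null) / sd_null        (z = 0 when sd_null = 0)
    p = (1 + #{null ≥ obs}) / (1 + n_perm)  (one-sided enrichment)

with n_perm = 1000 by default and the seed recorded in the result. This
null conditions on the spatial arrangement and the label composition,
so it tests label–position association, not clustering of cells per se.
Permutations shuffle exclusive phenotypes only; functional flags ride
with their cell, and composite labels ("Ki67⁺ CTL") are available via
label expansion for flag-stratified interaction questions. Both raw
counts and z/p matrices are emitted, since either may be the quantity of
interest. The one-sided p is slightly conservative under ties, which
matters only for sparse graphs (few edges per pair).

## Cellular niches

Each cell's neighborhood profile is the phenotype composition of its 20
nearest neighbors (reference excluded) — the k-NN convention of
CODEX-style neighborhood analysis; a radius mode exists for workflows
that prefer a fixed interaction range, in which isolated cells yield
all-zero rows and are left unclustered context. k-NN ties at the
boundary are broken by row order, making profiles deterministic.

Profiles are pooled across cases — required for comparing niche
proportions between cases — and clustered by k-means (k-means++, 10
restarts, best inertia kept, seeded). k defaults to 6, matching the
niche count observed in the motivating analyses of this tumor setting;
because the choice of k is not derivable from first principles, a
`k_scan` utility emits inertia and silhouette across candidate k for
transparency. Fitted niches are re-indexed 1..k by descending cell count
so that reports are stable; this canonical numbering is internal to a
fitted model and will not match any external numbering. A per-case
clustering mode is available by simply fitting per case, but joint
fitting is the default since cross-case niche comparison is the point.

## Synthetic scenes

The generator emulates the statistical structure of segmented mIF data:

- **Placement** — per region, cell count ~ Poisson(density × area) with
  uniform positions (homogeneous Poisson process); regions are
  rectangles or discs and may not overlap with conflicting niche ids.
- **Intensities** — two-component log-normal per marker
  (negative: log-mean 0.0, log-sd 0.25; positive: log-mean 2.0, log-sd
  0.25, arbitrary units). The ~8 log-sd separation makes midpoint gating
  ≥ 99% accurate, which is what the gating-recovery benchmark measures.
- **Attraction** — a planted fraction of B-phenotype cells is relocated
  uniformly into the attraction disc of a randomly chosen A cell
  (thinning-and-displacement): simple, and directly verifiable by a
  brute-force pair scan.
- **Margin band** — a strip of PD-1⁺ T cells and PD-L1⁺ tumor cells,
  emulating checkpoint engagement at an invasive margin.
- **Determinism** — one `numpy` generator seeded per scene drives every
  draw; identical specs give byte-identical tables.

Two profile factories define the study conditions. "ESS-like" draws
immune densities per case around the reported immune-low medians,
clipped to the reported ranges (Th 10.4 (0–64.5), CTL 9.8 (2.0–22.2),
B 1.2 (0.4–21.6), Mac 6.6 (2.4–35.5) per mm²), in a uniform
tumor-dominated 4 mm² field at 1500 cells/mm². "SDUS-like" is a 4×4
grid of 500 μm tiles typed background / lymphoid-aggregate / vascular
(the planted niches), with the lymphoid tiles planted so the hotspot
carries the immune-high densities (CTL 782, Th 382, B 148, Mac 140 per
mm², jittered ~8% per seed), Th–B and CTL–Th attraction, a PD-1/PD-L1
margin band, and a Ki67 assignment in which CTLs are 20% and Th + B
cells 14% of proliferating cells. The degree of lymphocyte aggregation
in the immune-high profile is a stated assumption, not an estimate — no
quantitative aggregation measurement exists to fit it to.

A separate six-niche benchmark (`make_planted_niche_scene`) places six
regions with disjoint dominant phenotypes, separated by 300 μm gaps so
no 20-NN neighborhood crosses regions, one region holding ~60% of all
cells. This is deliberately an easy, well-posed recovery problem: it
verifies the profile/clustering machinery, not the hardness of niche
discovery in continuous tissue, where niche boundaries blend and ARI
against any "truth" would be ill-defined.

What the synthetic scenes do **not** model: segmentation errors and
doublets, spatially varying staining/autofluorescence background,
intensity spillover between channels, cell-size variation, anisotropic
tissue architecture, and holes/folds. Passing the benchmarks therefore
demonstrates correctness of the computations under the stated generative
model, not robustness to those artifacts; on real exports, gating
thresholds and the intensity statistic must be set per panel.

## Problem sizes and numerical choices

Synthetic study cases are 4 mm² at 1200–3000 cells/mm² (~6–7.5 k cells
per case), within the realistic range for mIF regions of interest and
comfortable for exhaustive-oracle cross-checks. The calibration study
uses 500 simulations of 2000-cell scenes with 200 permutations each;
the detection study 50 replicates of ~5000-cell scenes. Float outputs
are rounded to 6 decimals in CSV/JSON bundles purely for byte-stable
serialization; all statistics are computed in double precision.
Degenerate inputs are handled explicitly: empty scenes (valid, empty
tables), header-only files (warned), zero-variance contrasts (p = 1 when
the difference is 0), single-label enrichment (z = 0), isolated cells
(zero profiles), and saturated ANOVA designs (rank statistics only).
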