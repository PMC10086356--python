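# Methods

This note documents the models and procedures implemented in `aortamihc`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic validation does and does not show.

## The analysis problem

Whole-slide multiplex IHC of the aortic wall yields, after cell
segmentation, a table of cells with µm positions, per-marker intensities
and a tile (field-of-view) id, together with a tissue segmentation into
intima, media and adventitia and excluded regions (background, surgical
hematoma/blood). The package turns such tables — real or simulated — into
layer-stratified composition summaries, TLS calls, nearest-neighbor
distances, and group-level statistics for a three-group cohort design
(8 non-dilated, 15 dilated, 4 hyperacute-dissection slides).

## Slide geometry

v1 geometry is a rectangular strip with horizontal layer bands — intima at
the bottom, media, adventitia on top — in continuous µm coordinates,
origin bottom-left. Real sections are curved, but every computation here
(point-in-layer tests, band areas, boundary distances) depends only on the
layer topology, so curvature adds nothing. Defaults: 8 000 µm wide;
intima 150 µm, media 1 200 µm, adventitia 800 µm thick
(≈ 17 mm² of tissue, ~2×10⁴ cells per slide at the default densities —
within the plausible range for multi-centimeter aortic sections, whose
physical area is not standardized). A point exactly on a layer boundary
belongs to the inner (lower) layer; this tie-break is arbitrary but fixed
and measure-zero for continuous coordinates. Excluded regions are
polygons; cells inside them are dropped from every count and their overlap
is subtracted from analyzed layer areas, so densities refer to analyzed
tissue.

## Synthetic slide generator

The generator emulates the *post-segmentation* data a trained imaging
pipeline would emit, with known ground truth. It does **not** model
pixels, spectral unmixing, segmentation errors (beyond optional doublet
labels), autofluorescence structure (a log-normal nuisance floor stands in
for it), or staining batch effects.

- **Placement.** Cells are a homogeneous Poisson process per layer and
  phenotype: counts `Poisson(fraction x layer density x analyzed area)`,
  positions uniform in the band outside excluded polygons. Endothelium is
  the exception: vasa-vasorum microvessels are emulated as a Matérn-style
  cluster process (clusters of mean size 7 within 20 µm disks) so
  nearest-neighbor analyses have realistic, spatially aggregated targets.
  Blood polygons are filled with a dense leukocyte mix (2 500 cells/mm²)
  to exercise the exclusion path.
- **Intensities.** Log-normal per marker per population. Bimodal markers:
  negative `LN(log 1.5, 0.4)`, positive `LN(log 30, 0.4)` — separated by
  ~7.5 SD in log space, so fixed thresholds gate at ≈ 100 % accuracy, as
  reproducible manual gates would. Gradual markers (CD45RO, MMP9):
  negative `LN(0.69, 0.5)`, positive shifted by +1.8 in log — genuinely
  overlapping distributions with no separated positive mode, which is the
  regime the negative-control thresholding rule exists for. At the default
  0.995 quantile, ≤ 0.5 % of true negatives are called positive by
  construction, at the price of imperfect sensitivity (~85 %) for true
  CD45RO+/MMP9+ cells; this trade-off is intrinsic to one-sided
  thresholding of overlapping distributions.
- **Planted TLS.** A TLS template is a compact B-cell core (rings spaced
  4.5 µm; the germinal-center proxy) separated by an 11 µm gap from a
  T-cell rim (rings spaced 10 µm), jittered ≤ 0.4 µm. Worst-case
  neighbor spacing stays below the 12 µm contact radius, so each planted
  structure is guaranteed to form a single contact-connected component.
  Defaults: 40 B + 110 T members; centers offset from the
  media/adventitia boundary by `N(242, 60)` µm (truncated to fit);
  prevalence 0.5 per dilated/dissection slide; count per positive slide
  `1 + Poisson(1.6)` (mean 2.6).
- **TLS members are relocated, not added.** Members are drawn from the
  slide's already-generated background B and helper-T pool and moved into
  the template positions. Planting therefore changes only the spatial
  arrangement, never the per-layer composition — which keeps the
  fraction-based calibration exact regardless of how many TLS a slide
  receives. If a slide's realized pool is smaller than the demand (rare
  at defaults), the shortfall is synthesized and recorded in ground truth.
- **Cohort defaults.** Per-layer compositions per group are constructed
  once so that the group medians recover the calibration targets: a 4×
  adventitial lymphocyte and 25× B-cell excess (dilated over non-dilated),
  helper T at 12.42 % of adventitial cells with CD4/CD8 2.52 (dilated)
  vs 1.82 (non-dilated), a 1.6× CD68+ excess, TLS prevalence 50 % at 2.6
  per positive slide and 242 µm mean offset, and a pooled intima of 8.1 %
  immune cells with 4.6 % M1-like macrophages. FoxP3 is masked in the
  non-dilated group (post-mortem material); dissection adventitia is
  flagged non-quantifiable and excluded from adventitial group statistics
  while still being generated and analyzed.
- **Determinism.** Per-slide generators are spawned from the master seed
  via `SeedSequence`, so a cohort is bit-identical across runs for a fixed
  configuration.

## Gating

Thresholding is strictly `intensity > threshold`; equality is negative — a
deterministic tie-break that only matters for degenerate (zero-variance)
inputs. The gradual-marker threshold is the nearest-rank 0.995 quantile of
the negative-control population (all lineage markers of the panel
negative); below 50 control cells the fixed fallback threshold from the
configuration is used. The published rule table is not mutually
exclusive as printed (e.g. CD31+ MMP9+); rules are applied
most-specific-first with explicit required-negatives, which is its
disjoint closure, and a cell matching no rule is `other`. When a cell is
positive for both markers of an exclusive lineage pair (CD3/CD20,
CD68/CD15) it is a segmentation-doublet artifact: labeled `ambiguous`,
excluded from every phenotype count but kept in denominators. Cells
carrying FoxP3-dependent labels cannot be called when FoxP3 is masked;
those labels are reported as missing, not zero, and the cells fall
through to the next rule (helper T), mirroring how a masked stain reads.
"Lymphocyte" in the fold-change reporting means CD3+ or CD20+; the term
is otherwise left undefined in the source workflow.

## Layer quantification

Fold changes are computed on per-slide *fractions of all cells* (the
"% of all cells" basis), as the ratio of group medians — whether published
fold changes are ratios of medians or medians of ratios is unstated;
ratio of medians was chosen (and documented here) because it is defined
even when individual denominator slides are zero. Densities are also
emitted. Group aggregation is by medians throughout, matching the
median-(IQR) reporting convention for small non-Gaussian samples.

## TLS detection

- `contact_radius_um = 12`: lymphocyte diameters are ≈ 8–10 µm, so
  physically touching cells have center distances of about one diameter.
- `min_infiltrate_cells = 20`: a "dense conglomerate" threshold; random
  background contact components at the default densities have ≪ 20 cells
  (the contact graph is deep in the subcritical percolation regime).
- Zones: per class, the mean over members of the fraction of their
  k = 5 nearest within-component neighbors of the same class; both class
  scores ≥ 0.7 ⇒ separate zones. A perfectly mixed lattice scores far
  below 0.5, the planted core/rim template ≥ 0.9.
- Germinal center: some member-centered disk of radius 15 µm whose B-cell
  density is ≥ 2× the component's median local member density with a T
  fraction ≤ 0.2. The probe radius must be smaller than the B core for
  the density contrast to exist; 15 µm (probe) vs ≈ 15–20 µm (core
  radius at defaults) achieves that. None of these constants are
  published; all are exposed in `AnalysisParams`.
- Venules, an alternative organized-structure criterion in the source
  workflow, are not modeled: the lymphocyte panel carries no endothelial
  marker, so the criterion is restricted to zones/germinal centers. This
  is a deliberate narrowing.
- The mean TLS count is reported per TLS-*positive* slide (primary; the
  per-slide basis of the published average is ambiguous) with the
  per-all-slides alternative also emitted.

## Nearest neighbors

Distances are Euclidean on merged whole-slide coordinates — tiles are
never a boundary. The `min_count = 150` exclusion applies to *either*
phenotype. The KD-tree is used only as an index; distances are recomputed
at the matched pairs so results are bit-identical to an O(n²) scan (the
suite asserts exact equality). Direction is source→target
(macrophage→endothelium); the reverse is available but not the default.

## Statistics

Kruskal–Wallis uses the tie-corrected H; an all-identical input returns
p = 1 rather than an error. Pairwise tests are Bonferroni-multiplied by
the number of pairs and capped at 1. The Kendall CI uses a seeded
percentile bootstrap (2 000 resamples) because no analytic CI convention
is implied by the source workflow; degenerate resamples are redrawn. ICC
defaults to ICC(2,1) — two-way random effects, absolute agreement, single
measures — with ICC(3,1) behind a flag, since the ANOVA model actually
used by the original SPSS analysis is unknowable; identical ratings return
ICC = 1 by convention. KS uses the exact small-sample method where scipy's
`auto` switch selects it.

## What the validation shows — and does not

Calibration recovery (20 master seeds, medians within ±15 % / ±5
percentage points), planted-TLS recovery (sensitivity and precision
≥ 0.95), brute-force oracle equality, and type-I-error calibration of the
tests at n = 8/15/4 demonstrate that the *pipeline* is correct and that
the generator hits its configured regime. They do not validate the
biology of real slides: the generator's cells are (except for TLS and
vasa vasorum) spatially unstructured, intensities are clean log-normals
without spatial gradients or batch effects, helper-T and B counts are
independent (so the positive helper-T/B correlation seen in real dilated
aortas is *not* reproduced — the tau machinery is instead verified
against enumeration oracles), and segmentation is error-free apart from
optional doublets. Results on real inForm-style exports will inherit all
the artifacts the generator omits.

## Known limitations

- Geometry v1 is banded; strongly curved or fragmented sections would
  need polygon layer masks (the `LayerGeometry` interface is the seam).
- The germinal-center criterion is density-based; it cannot distinguish a
  germinal center from any equally dense, equally pure B focus.
- Dissection slides are generated with an intact (if flagged) adventitia;
  the morphological destruction of real dissections is represented only
  by the non-quantifiable flag, not by the point pattern.
- FCS export covers list-mode float32 only — sufficient for round-trip
  use by flow software, not a general FCS implementation.
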