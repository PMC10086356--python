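# aortamihc

Whole-slide multiplex immunohistochemistry (mIHC) resolves every segmented
cell of a tissue section into a position, a set of marker intensities and a
phenotype — and therefore lets inflammation be *quantified* rather than
scored. This package implements that analysis for the ascending aortic wall
in bicuspid-aortic-valve (BAV) aortopathy: starting from post-segmentation
single-cell tables it gates phenotypes from two eight-color panels,
stratifies counts by tissue layer (intima / media / adventitia), detects
tertiary lymphoid structures (TLS) as contact-connected T/B conglomerates
with organized zones, runs nearest-neighbor distance analyses, and applies
the nonparametric statistical battery for three small patient groups
(non-dilated, dilated, dissection).

Because no raw cohort slides are publicly deposited, the package ships a
synthetic whole-slide generator with known ground truth, calibrated so
that the full pipeline recovers the published cohort summary statistics by
construction. Every stage is validated against brute-force oracles and
that calibration.

## Methods at a glance

- **Gating.** Bimodal markers are thresholded with fixed flow-style gates;
  the gradual markers CD45RO and MMP9 (no separated positive mode) are
  thresholded at the 99.5th percentile of the *negative-control*
  population — cells negative for every lineage marker. A cell is positive
  iff intensity > threshold. Ordered most-specific-first rules assign one
  leaf label per panel, e.g. CD3+CD8− → helper T, CD3+CD8−FoxP3+ →
  regulatory T, CD68+CD206− → M1-like macrophage; CD3+CD20+ doublets are
  `ambiguous` and excluded from counts.
- **Layer quantification.** Per slide and layer: count, fraction of all
  cells and density (cells/mm² of analyzed area, excluded blood regions
  subtracted). Group effects are ratios of group medians of per-slide
  fractions; CD4/CD8 = helper-T / cytotoxic-T counts.
- **TLS detection.** Lymphocytes whose centers lie within 12 µm are
  "touching"; connected components with ≥ 20 members and both lineages are
  lymphoid infiltrates. An infiltrate is a TLS if it has separate B/T
  zones (mean k-NN class segregation ≥ 0.7 for both classes) or a germinal
  center (a ≥ 2×-dense, ≥ 80 % pure B-cell focus). Distances are measured
  from the TLS centroid to the media/adventitia boundary.
- **Nearest neighbors.** Median minimal distance from CD68+CD206−
  macrophages to CD31+CD68− endothelium per slide, computed on merged
  whole-slide coordinates; slides with < 150 cells of either phenotype are
  excluded; groups compared with Kruskal–Wallis.
- **Statistics.** Median (IQR); two-group Kolmogorov–Smirnov; three-group
  Kruskal–Wallis with Bonferroni-adjusted pairwise tests (capped at 1);
  Fisher exact for binary variables; Kendall's tau-b with bootstrap CI;
  ICC(2,1) for two-observer agreement.

## Worked example

Run the numbered analysis scripts from the repository root:

```sh
python analysis/01_simulate_cohort.py --seed 0     # writes results/cohort/
python analysis/02_gate_and_quantify.py
python analysis/03_detect_tls.py
python analysis/04_nearest_neighbors.py
python analysis/05_group_statistics.py
```

With seed 0 this prints (abridged):

```
adventitia lymphocyte: dilated / non-dilated fold change = 3.98
adventitia b_cell: dilated / non-dilated fold change = 22.87
adventitia macrophage: dilated / non-dilated fold change = 1.62
dilated adventitia helper T: 12.47% of all cells
CD4/CD8 dilated: 2.46
CD4/CD8 non-dilated: 1.90
non_dilated: prevalence 0%, ... TLS per positive slide
dilated: prevalence 60%, 2.56 TLS per positive slide, mean distance to media 223 um
ground truth: 30/30 planted TLS recovered
Kruskal-Wallis on per-slide medians: H = 0.092, p = 0.955 (not significant at 0.05)
Fisher TLS presence dilated vs non-dilated: p = 0.0072
```

Reading: the dilated adventitia carries ~4× the lymphocytes and ~25× the
B cells of non-dilated aortas; helper T cells are the dominant subset
(~12 % of all adventitial cells, CD4/CD8 ≈ 2.5); TLS appear only in
dilated/dissected slides (~2.6 per positive slide, ~240 µm from the
media); and macrophage-to-endothelium distances do not differ between
groups. Single-seed values fluctuate (e.g. the 60 % prevalence above is a
15-slide binomial draw around the configured 50 %); the medians over 20
seeds, which is what the acceptance script reports, sit on the calibrated
values.

The same run can also be driven programmatically:

```python
from aortamihc import default_cohort_config, RunManifest, run_pipeline
bundle = run_pipeline(RunManifest(run_id="demo", config=default_cohort_config(), seed=0))
print(bundle.calibration)
```

## Layout

```
src/aortamihc/     library: config, geometry, panels, simulate, gating,
                   quantify, tls, neighbors, stats, io, pipeline
analysis/          numbered narrative drivers writing results/
scripts/           acceptance.py (cohort-level recomputation)
tests/             pytest suite incl. cohort-level acceptance tests
docs/methods.md    model, parameters, design choices, limitations
```
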