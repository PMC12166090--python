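# Methods

This note documents the models and procedures implemented in `crcimmune`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Inputs and conventions

All cell positions are μm in slide space, origin top-left, x right,
y down. A tissue raster pixel (r, c) covers the half-open square
[c·mpp, (c+1)·mpp) × [r·mpp, (r+1)·mpp). Detection tables are
comma-delimited UTF-8 CSV with `.` decimals; coordinates round-trip
bit-exactly through the readers/writers (the CSV reader uses
round-trip float parsing).

Raw nucleus classes are the seven-way H&E classification: epithelial,
lymphocyte, neutrophil, plasma, eosinophil, mitosis, connective.
Neutrophils, plasma cells, mitoses and connective cells are analysed as a
single "other" group. Epithelial nuclei are resolved to tumor vs normal
epithelium by tissue context: the majority tissue class over the pixels
within 25 μm of the centroid (ties go to the nearest tied pixel). The
25 μm radius reuses the nucleus-scale neighborhood used for the
intraepithelial region; nothing in the upstream detection format ties a
nucleus to a tissue class, so some such reconciliation rule is required
and this one is deliberately simple and local. Nuclei beyond the raster
are classed "other" and counted in a warning.

Tissue classes are codes 0–8: background, adipose, muscle, stroma,
lymphoid aggregate, debris, normal epithelium, tumor epithelium, mucin.
Muscle is merged into stroma for analysis, and lymphoid-aggregate pixels
are recoded to stroma rather than masked out: dense lymphocyte structures
are detected (and excluded) at cell level, which keeps a single authority
for exclusions instead of two disagreeing ones. The merge is idempotent.

## Invasive front

The front line is the set of points equidistant from the tumor-epithelium
mask and the muscle∪adipose mask: the zero level set of
f = d_tumor − d_invaded, where both are Euclidean distance transforms in
μm. Implementation: `skimage.measure.find_contours(f, 0)` on the raster,
vertices filtered, polylines simplified with a 1-pixel tolerance.

Front estimation runs on the **unmerged** raster. Merging folds muscle
into stroma, which would erase exactly the mask the midline is defined
against; the merged raster is used for epithelial context only.

Vertex filters, in order:

* tumor and invaded tissue must be within 1000 μm of each other at the
  vertex (d_tumor + d_invaded ≤ 2 × band half-width) — a midline through
  a gap wider than the full band diameter separates nothing;
* the vertex is dropped when its nearest normal-epithelium pixel is
  closer than its nearest muscle/adipose pixel (the "omit anything
  bordering normal mucosa" rule, read literally);
* raster-border vertices are dropped (distance-transform artifacts).

Surviving fragments shorter than 500 μm are discarded (`min_front_length_um`,
an explicit extension to suppress one-pixel spurious fronts). If nothing
survives, the front is undetected — a valid outcome: the slide is flagged
`front_missing`, every tumor cell is labelled center, and region-specific
scores report as missing so such slides drop out of region analyses.

Tumor cells within `front_band_halfwidth_um` = 500 μm of the line are
front, ties inclusive; everything else is center. The band applies to
tumor cells only; immune cells inherit a region through score
attribution (below). Distances use an STR-tree over the polylines and
agree with exhaustive per-segment evaluation to 1e-9 (tested).

## Lymphoid structures and IELs

Lymphocyte pairs at distance ≤ `cluster_link_radius_um` = 20 μm are
linked (KD-tree pair query); connected components of the linkage graph
with **strictly more than** 500 members are lymphoid aggregates and
strictly more than 50 000 are lymph nodes. The thresholds are fixed
constants of the method. Members are excluded from every downstream
count. For lymph nodes, all cells of any class inside the component's
convex hull are excluded as well — an on-slide lymph node is lymphatic
tissue, not tumor microenvironment; this extends the exclusion beyond
lymphocytes and is logged per slide.

The intraepithelial region is the planar union of 25 μm disks around
tumor-epithelial centroids minus 12.5 μm disks around connective
centroids, computed as exact polygonal geometry with 64-segment circle
approximations (area error ≈ 0.16% per disk, verified against closed
forms and Monte-Carlo integration). Non-excluded lymphocytes whose
centroid lies in the region are IELs. The IEL score is
\#\{tumor cells with ≥1 IEL within 25 μm\} / \#\{tumor cells with none\};
"adjacent" is not defined upstream of this package, so the 25 μm
epithelial dilation radius is reused (`adjacency_radius_um`, auditable in
the configuration). The ratio is missing when there are no tumor cells or
when every tumor cell is IEL-adjacent (zero denominator).

## Scoring

Each non-excluded immune cell is assigned to its **nearest** tumor cell.
It contributes to the 10 μm distance-profile bin of that distance (up to
500 μm; profiles are normalized by the whole-slide tumor-cell count) and,
if the distance is ≤ `count_radius_um` = 200 μm (ties inside), to the
region score of the nearest tumor cell's region. Nearest-tumor-cell
attribution is what guarantees an immune cell is never counted twice
across front and center while keeping the fixed 200 μm counting radius;
it is the one attribution rule consistent with both requirements.
Scores are unique counts divided by the region's tumor-cell count, and
missing when that count is zero (or when the front is missing, for
front/center).

Patient scores are weighted means over slides: region scores weighted by
the slide's front/center tumor-cell count, whole-slide scores and the IEL
ratio by the total. Slides missing a value for a score are dropped from
that score's average only.

Normalization is per cohort × score: the 5th and 95th percentiles
(linear-interpolation definition, stated for bit-reproducibility) of the
cohort's **stage II** patients serve as min and max; scaled values below
0 or above 1 pass through unclipped — outliers, typically low-tumor-count
cases, are retained. Fitting requires ≥2 stage II patients with a
non-missing score per cohort and fails naming the cohort otherwise;
a degenerate window (p5 = p95) is an error at application time.

## Survival analysis

The endpoint is time to recurrence with a five-year administrative
cutoff: follow-up is truncated at 60 months and events beyond it are
recoded as censored at 60. Normalized lymphocyte/eosinophil scores enter
regressions as log(1 + max(x, 0)) — normalized values can be ≤ 0, so a
raw log is undefined; log1p is monotone on the retained range and keeps
0 at 0. The IEL ratio enters untransformed.

Rank statistics are Spearman's ρ (continuous pairs), Kendall's τ-B
(ordinal), and two-sided Mann-Whitney U (group comparisons). No
multiple-testing correction is applied anywhere; conclusions are per
comparison. Kaplan-Meier quartile analyses cut the score into quartiles
on the **full** cohort before any subsetting, so a patient keeps its
quartile across subgroup analyses; per-quartile Wald p-values come from
one univariate Cox fit on quartile indicators with the lowest quartile
as baseline.

Cox models use lifelines' partial likelihood with the **Efron** tie
approximation (stated because it changes third-decimal coefficients),
report HR, 95% CI and Wald p per covariate, and AIC = 2k − 2·log L.
Missing covariate values are handled complete-case per model with the
dropped-row count recorded; models with fewer than 10 events warn. AIC
comparisons refuse models fitted on different patient subsets (checked
via a hash of the modeled rows). A proportional-hazards diagnostic
(rank-transform score test) is reported per covariate when requested.

## Synthetic data

`simulate_slide` draws band-layout slides: optional normal-mucosa band,
tumor band, stroma gap, then muscle (optionally adipose) along x, so the
true invasive front is the vertical mid-gap line. Tumor cells are a
homogeneous Poisson process on the tumor band (default 1500 cells/mm²,
a typical epithelial nuclei density at this granularity); immune cells
are an inhomogeneous Poisson process with intensity
base · exp(−d/λ), d the distance to the nearest tumor cell, sampled by
thinning (defaults: lymphocytes 800/mm², λ = 150 μm; eosinophils
120/mm², λ = 120 μm — eosinophils roughly an order of magnitude rarer
than lymphocytes, both concentrated near tumor, mirroring the observed
decay of immune abundance with distance). Lymphocyte intensity inside
the tumor band is additionally multiplied by 0.1: stromal lymphocyte
density far exceeds intraepithelial density in tissue, and the
intraepithelial supply is controlled separately by `iel_rate` (default
0.15: the probability a tumor cell receives a planted lymphocyte 2–8 μm
away). Planted lymphoid structures are isotropic Gaussian clusters
truncated at 1.5σ; at the default dispersion σ = 2√n the linkage-graph
neighbor count stays ≳20 cells even at the truncation edge, so planting
guarantees a single connected component. The generator returns the
analytic front position, per-cell true regions, planted memberships, and
`expected_score` integrates the generating intensity numerically to give
the expectation of the unique-count score for the realized tumor
configuration.

What the slide generator does **not** emulate: nucleus morphology and
classifier errors, tissue-segmentation noise, irregular front geometry,
mucin pools and debris, spatial clustering of immune cells beyond the
distance-decay law, and scanner/staining variation. Passing tests
therefore certify the post-detection computations, not robustness to
upstream model errors.

`simulate_cohort` draws clinicopathological covariates from realistic
CRC marginals (age ≈ N(68, 11²), 42% stage II, 19% MSI, 55% pN0), scores
from a Gaussian copula with log-normal marginals reproducing the
observed correlation structure (LymF–EosF rank correlation 0.64,
front–center 0.63, IEL ≈ independent of eosinophils), and TTR from an
exponential proportional-hazards model on the analysis covariates with
specified true hazard ratios (defaults LymF 0.59, EosF 0.70, IEL 0.34 —
protective effects at the magnitudes reported for such scores) plus
uniform censoring on 6–120 months. The baseline hazard (0.0066/month) is
calibrated so the five-year analysis sees ≈229 events at n = 1122, the
design scale of the statistical stage. Covariate effects are specified
per unit of the analysis covariate (log1p score scale), so parameter
recovery is exact in expectation rather than approximate.

## Numerical choices and degenerate inputs

* Distance ties: ≤ at the 500 μm band, the 200 μm counting radius and
  the 20 μm linkage radius.
* Cluster-size thresholds are strictly exclusive (> 500, > 50 000).
* Percentiles and quantiles: linear interpolation throughout.
* Empty inputs degrade explicitly: no tumor cells → empty profile and
  missing scores with a warning; no front → flagged, not an error;
  constant scores → quartile split raises naming the score.
* Determinism: one `numpy.random.Generator` per simulation, seeded
  explicitly and echoed into output metadata; reruns of `run-all` on the
  same inputs produce byte-identical score CSVs (tested).

## Problem sizes

The test suite and acceptance script size their simulations to be
informative at desk scale: geometry oracles run 100 random instances of
up to 1000 points each; survival recovery runs 200 (tests) / 100
(script) replicates at the full design scale n = 1122; null calibration
uses 2000 (tests) / 1000 (script) replicates of n = 250 cohorts; the
planted-structure check runs one slide with 73 000+ cells including a
60 000-cell lymph node. The end-to-end determinism check uses a
5-slide, 4-patient study, which exercises multi-slide aggregation
without inflating runtime.

## Known limitations

* The 25 μm majority-vote reconciliation of nucleus and tissue calls is
  this package's choice; other rules (point lookup, larger windows) give
  slightly different tumor/normal splits at class boundaries.
* The front midline is raster-derived; its accuracy is bounded by the
  tissue-map resolution (≈1 pixel), not by the detection coordinates.
* Cox survival at very small cohort sizes is skipped by `run-all`
  (below 30 patients / 10 events) rather than fitted unstably; the
  stage-wise `survival` command fits whatever it is given.
* The IEL-ratio definition (positive : negative tumor cells) is
  undefined when every tumor cell is IEL-positive; reported as missing.
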