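# Methods

## The Ki67CL score

The score treats a slide as a marked spatial point pattern: tumor-cell
centroids marked Ki67-positive or Ki67-negative. It is computed in two
stages.

**Spatial clustering.** Tumor cells (both marks; nontumor cells are
excluded first) are clustered by average-linkage (UPGMA) agglomerative
clustering on Euclidean distance, cut at a linkage threshold of 300
pixels at ×40 magnification. Merging proceeds while the smallest average
inter-cluster distance is *strictly below* the threshold; two points
exactly 300 px apart therefore remain separate. ("Average linkage" has
weighted and unweighted variants; this package uses the unweighted
pair-group mean, which is what scikit-learn's `linkage="average"`
computes.) Because hierarchical clustering is quadratic in memory, at
most 10,000 cells enter the agglomeration — a uniform random subset drawn
with a dedicated, logged seed — and every remaining tumor cell then takes
the cluster of its Euclidean-nearest clustered cell, with exact ties
resolved to the lowest cluster id. When a slide has at most 10,000 tumor
cells the result is seed-independent.

**Colocalization.** Each cluster *i* with Ki67-positive fraction
p⁺ᵢ contributes its binary Shannon entropy
H(p⁺ᵢ) = −[p⁺ᵢ log₂ p⁺ᵢ + (1−p⁺ᵢ) log₂(1−p⁺ᵢ)] (convention
0·log₂0 = 0), and the slide score is the unweighted mean of the C cluster
entropies. Clusters are weighted equally regardless of size — that is
what the defining 1/C formula states — even though size weighting would
be a defensible alternative. No minimum cluster size is enforced;
singleton clusters are legal and contribute entropy 0, which biases
slides with many isolated cells toward lower scores. The AutoKi67 ratio
is n(Ki67⁺ tumor) / n(tumor).

**Region settings.** Cells can be filtered against tumor / DCIS / normal
polygons before scoring: WITHOUT_DCIS keeps cells inside TUMOR polygons
and outside DCIS polygons (the invasive region, where conventional Ki67
scoring is defined); WITH_DCIS keeps cells in either. Point-in-polygon
uses the even-odd rule with boundary points counting as inside, a
determinism choice — boundary hits are measure-zero for real centroid
data. When regions are supplied, the AutoKi67 ratio is always computed on
the invasive (WITHOUT_DCIS) cell set regardless of the Ki67CL setting,
mirroring how the manual index is defined; without regions, both scores
use the whole table.

## Survival validation protocol

The marker convention is higher = worse prognosis throughout.

- **Stratification.** Patients split at a cutoff (high = marker >
  cutoff); groups are compared by Kaplan–Meier curves and the two-group
  log-rank chi-square test (1 df). A dataset with no events at all
  returns statistic 0, p = 1 rather than NaN.
- **Cutoff search.** Candidates default to the deciles (10%–90%) of the
  *training* marker distribution; a candidate is feasible only if both
  groups retain at least 10% of patients; the feasible candidate with the
  smallest log-rank p wins, ties to the smaller cutoff. The decile grid
  and the 10% floor are this package's choices — only the resulting
  cutoffs of such a search are ever published, not the grid.
- **Cross-validation.** k = 3 by default. Folds are event-stratified
  (events and censored records dealt round-robin after seeded shuffling)
  so no fold is event-free. Per fold: cutoff selected on the training
  part, log-rank p and Harrell's C evaluated on the held-out part. The
  combined p-value is the conservative min(1, 2 × median of fold
  p-values); the combined C-index is mean ± SD over folds; the cutoff
  reported to users is the median of the per-fold cutoffs (the
  aggregation across folds is this package's choice).
- **Concordance.** Harrell's C over admissible pairs of the *continuous*
  marker (ties contribute 0.5); a binarized-group variant is available
  via `binary_cutoff`. Whether a published C-index of this kind uses the
  continuous score or the binary group is often ambiguous; both are
  provided, continuous is the default.
- **Cox regression.** Partial-likelihood fits via lifelines with Efron
  tie handling and a tightened stopping precision (1e−9; the library
  default leaves ~1e−4 coefficient error, visible against closed-form
  toy solutions). UNIVARIATE fits one single-term model per covariate;
  MULTIVARIATE one joint model. Constant covariates are dropped with
  HR = 1 by convention; non-convergence (e.g. separation) raises a named
  error instead of returning garbage.

## Detection post-processing

- **Tiling**: non-overlapping 252-px half-open windows, edge windows
  clipped.
- **Dot-to-density mapping**: each dot annotation stamps a truncated
  (4σ), *peak-normalized* Gaussian (max 1, not unit mass), so an isolated
  cell center regresses to exactly 1 and the map is comparable to a [0,1]
  target. Overlapping stamps sum, so the raw training target can exceed 1
  for nuclei closer than the kernel support; the synthetic map generator
  clips to [0,1]. σ defaults to 3 px — not a published constant, but it
  must stay well under half the 15-px merge radius for adjacent nuclei to
  remain separable.
- **Local maxima**: a pixel is a candidate if it attains the maximum of
  its Euclidean `min_distance` disk and exceeds `min_probability`
  (defaults 15 px and 0.5 — both artifact choices, configurable);
  candidates are then greedily accepted in order of descending
  probability (ties: lowest row, then column, which also fixes the
  plateau representative) subject to mutual separation ≥ `min_distance`.
- **Cross-channel merge**: detections strictly closer than 15 px
  conflict and only the highest-probability one survives; "less than 15
  pixels" is read as strict, so a pair exactly 15 px apart coexists.
  Ties break by channel order, then (y, x). The operation is idempotent.
- **Matching for evaluation**: predicted and ground-truth centroids
  within 20 px may pair; the matching maximizes the number of pairs and
  then minimizes total distance (optimal bipartite assignment, not greedy
  nearest — greedy is order-dependent and can cross-assign). F1,
  precision and recall score detection regardless of class; Cohen's kappa
  and accuracy score class agreement over matched pairs only; Spearman's
  rho correlates per-patch, per-class count vectors (per-cell vs
  per-patch aggregation for these metrics is rarely stated in
  publications; this package documents its choice rather than claiming
  fidelity). Metrics that are undefined (no matched pairs, no patch ids)
  are returned as NaN, never as 0.

## Synthetic data

**Slides.** Blob centers sit on a jittered square grid (spacing 1,500 px
by default — five times the clustering threshold, so blobs map to
clusters); cells scatter isotropic-Gaussian (σ = 60 px) around centers.
The `mixing` dial interpolates colocalization at fixed expected
positivity: with probability 1 − mixing a blob is single-class (the class
itself drawn with the positivity probability), otherwise each cell's
class is an independent Bernoulli(positivity) draw. mixing = 0 yields
fully segregated slides (score 0), mixing = 1 well-mixed slides (score
near 1 at positivity 0.5); the expected score is monotone in the dial.
Defaults are 9 blobs × 60 cells. Optional extras: uniformly scattered
nontumor cells, an enclosing TUMOR polygon and a disjoint DCIS pocket
with its own cells.

What the generator does *not* emulate: tissue architecture (ducts,
stroma bands), anisotropic or density-varying cell packing, detection
noise (false/missed/misclassified cells), and gradual spatial gradients
of positivity. Passing tests therefore demonstrate the algebraic and
statistical behavior of the pipeline, not the biological validity of the
score on real slides.

**Cohorts.** Event times are exponential with hazard = baseline ×
(HR_high if score > threshold else 1); censoring is an independent
exponential clock plus an administrative follow-up cap, i.e.
non-informative. Defaults emulate a 10-year breast-cancer-specific
survival setting: baseline hazard 0.01 events/month, HR_high = 2,
censoring 0.005/month, cap 120 months, n = 600 — under which the
protocol's 3-fold combined p falls below 0.05 and the Cox HR lands in
[1.6, 2.5] in well over 90% of seeded runs (the test suite checks 50
runs). The single-threshold hazard model matches the binary
stratification being validated; it does not model continuous
dose–response, competing risks or covariate confounding.

**Probability maps** are dot-to-density outputs plus clipped i.i.d.
Gaussian noise, retaining the generating dots for round-trip tests
(dots → density → maxima → 20-px matching recovers F1 = 1 for
well-spaced dots).

## Numerical and scale choices

- Coordinates are 0-based pixels at ×40; no µm conversion anywhere,
  since every operating constant is specified in pixels.
- Entropy uses `scipy.special.xlogy` (exact 0 at the endpoints) with
  hard-coded values at p ∈ {0, 0.5, 1}, and matches a 50-digit
  high-precision evaluation to 1e−12 elsewhere.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; fixed seeds give byte-identical outputs, and every CLI run
  writes a manifest (config, seeds, input hashes) sufficient to reproduce
  it.
- Test-suite and acceptance problem sizes (slides of a few hundred cells,
  cohorts of 600, 50-seed Monte-Carlo sweeps) were chosen so the whole
  suite runs in well under a minute while leaving the Monte-Carlo
  assertions far from their thresholds.

## Known limitations

- Agglomerative clustering is O(n²) in memory; the 10,000-cell subsample
  bounds this, but slides with far more tumor cells lean heavily on the
  nearest-neighbor back-assignment, whose effect on the score is not
  characterized here.
- The score is sensitive to the detector's class-assignment quality;
  this package takes classified centroids as ground truth.
- No proportional-hazards diagnostics are run before Cox fits; users
  should check PH assumptions separately for real cohorts.
- GeoJSON regions are assumed valid simple polygons (optionally with
  holes); self-intersecting rings are not repaired.
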