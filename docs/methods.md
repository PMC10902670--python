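# Methods

## Scope and data model

`cytorisk` analyses cohorts of the following shape: per patient, a
single-cell event table over a 42-marker mass-cytometry panel (26 lineage
markers, 16 metabolic regulators; see `cytorisk.panel`), a five-cytokine
plasma panel (IL-6, IL-8, IL-10, IL-15, TNF-α; pg/mL), and a binary
nosocomial-infection outcome.  All marker analysis happens on the
`asinh(x/5)` scale — the standard ion-count stabilization with cofactor 5.
Upstream instrument processing (bead normalization, debarcoding, batch
alignment) and automated clustering are out of scope; the pipeline consumes
events that are ready to gate.

## Gating and feature assembly

Subsets are resolved by a binary gating tree (marker, threshold,
above/below) whose default encodes the conventional PBMC hierarchy: CD3+
T cells split into γδ, MAIT (TCRVα7.2+), NKT (CD56+), then CD4/CD8 naïve,
central-memory, effector-memory and TEMRA quadrants by CD45RA × CCR7 plus
FoxP3+ Tregs; CD3− events resolve into B cells (CD19+), three NK subsets
(CD56bright; CD56dim CD57±), three monocyte subsets (CD14 × CD16), and
mDC/pDC.  Thresholds live in the tree (YAML-serializable), not in code;
events matching no terminal phenotype are `ungated` and excluded from all
features.

Per-patient features: the abundance of each of the 21 subsets as a
fraction of all gated events (fractions of intermediate parent gates are
available as an optional extra block, since the natural denominator is a
design choice), and for every (subset, regulator) pair the **mean of
per-cell arcsinh values** — means of transformed values, not transforms of
means, so that planted or biological shifts on the analysis scale pass
through linearly.  With 21 subsets and 16 regulators this yields exactly
357 cytometry features; cytokines are appended with the 0 pg/mL
detection floor already applied.  Features are jointly standardized
(Z transformation with sample SD, n−1); constant features are dropped with
a warning.

## Patient embedding

Patients are compared by the squared-rank-difference distance: each
feature is ranked across the cohort (average ranks for ties; missing
values excluded pairwise) and `d_ij = Σ_k (r_k(i) − r_k(j))²`.  Ranking
makes the distance insensitive to feature scale (the preceding Z transform
is retained for workflow fidelity but is a no-op for this distance); an
alternative orientation ranking features within each patient profile is
available as a config option.  The matrix is embedded by least-squares
metric MDS: SMACOF majorization (Guttman transform) from a
classical-scaling start, convergence at a relative stress change below
1e-8 or 1,000 iterations.  The reported loss is the normalized squared
stress `Σ(d−d̂)²/Σd²`, whose minimizer coincides with raw least-squares
stress.  Three numerical conventions matter:

* the stress sequence is non-increasing by construction (majorization);
* the final configuration is reported on its principal axes — stress is
  invariant to rotation, so without this the axis identity would be
  arbitrary run to run; axis signs are aligned so each coordinate
  correlates non-negatively with the outcome;
* the stress-versus-dimension curve is computed with warm starts (each fit
  initialized from the previous dimension's solution padded with a
  jittered column, competing against a cold classical start), which makes
  the curve monotone in dimension.

**Elbow rule.**  The embedding dimensionality is the point of largest
curvature of the stress curve, measured as the discrete second difference
of **log** stress.  The logarithm is deliberate: dropping the smallest
structural axis of a configuration perturbs pairwise distances only at
second order, so raw stress drops decay geometrically along a structured
curve (by a factor ≥ ~3 even for exactly equal latent axes — verified
numerically on exact low-dimensional configurations, squared distances and
cluster geometries), and the raw second difference therefore peaks one
dimension too early regardless of the data.  The log form asks where the
*relative* improvement per added dimension collapses; on curves with one
dominant drop (e.g. stress 0.5, 0.2, 0.19, 0.185) it agrees with the raw
rule (elbow at 2), and on cohorts with a planted three-dimensional
structure it recovers 3 reliably.  A flat or uniformly decaying curve has
no elbow; the smallest dimension is returned with a warning.  The
end-to-end cohort analysis defaults to a three-dimensional embedding (the
reference design) with the elbow available by passing `dims=None`.

## Screening and multiplicity

Coordinate screening uses the rank AUROC (Mann–Whitney identity, ties
half-weighted) with a percentile bootstrap CI, resampling stratified
within outcome classes so every replicate retains both classes and the
cohort prevalence — important at n≈37.  The coordinate with the largest
AUROC is selected (ties break to the lower index).  Feature relevance is
Spearman correlation with the selected coordinate: ρ is the Pearson
correlation of average ranks; p-values are exact (full permutation
enumeration) for n ≤ 9 and t-approximate otherwise.  Multiplicity is
controlled by Storey q-values: π0 estimated on the λ-grid 0.05…0.95 (step
0.05) with a cubic polynomial smoother evaluated at the largest λ (clipped
to (0, 1]; small families fall back to π0 = 1), then the step-up
transformation; with π0 = 1 the procedure is exactly Benjamini–Hochberg.
Features are flagged at q < 0.05 (the threshold is a parameter).
Two-group comparisons use Mann–Whitney (exact for combined n ≤ 20 without
ties, tie-corrected normal approximation otherwise) and Fisher's exact
test; per-feature unadjusted odds ratios come from univariate logistic
fits (IRLS), with perfect separation flagged and reported as an infinite
odds ratio rather than a spurious finite one.

## Elastic-net risk score

The selection model is L1/L2-penalized logistic regression solved by
cyclic coordinate descent on the IRLS quadratic approximation (weights
floored at 1e-5; step-halving guarantees a non-increasing penalized
objective; KKT stationarity holds to < 1e-6 at the solution).  The
intercept is never penalized; features are standardized internally to unit
sample SD and coefficients are reported on both scales.  Defaults: mixing
weight 0.5 (a parameter — the reference analysis does not report its
value); λ from a 50-point geometric path (λ_max down to 1e-3·λ_max) by
leave-one-out binomial deviance — at a few dozen patients k-fold splits
are unstable — with the 1-SE rule, falling back to the deviance-minimizing
λ when the 1-SE choice is the null model.  Candidates default to the
significance-flagged features whose names match the NK/interleukin
pattern, capped at 11; the pattern is configuration, not code.  The
predicted score is the logistic transform of the linear predictor,
computed with a numerically stable sigmoid.  Because the apparent
(in-sample) AUROC of a model selected and fit on the same 37 patients is
optimistic, the acceptance script reports both apparent and leave-one-out
AUROC, labelled as such.

## Gene-signature validation stage

For labeled cell × gene matrices the module score follows the standard
binned-control algorithm: genes are cut into 24 equal-occupancy bins of
the cross-cell average expression; for each signature gene up to 100
control genes are drawn without replacement from its bin; the per-cell
score is the mean over signature genes minus the mean over pooled
controls.  Genes with zero expression in every cell are excluded from both
the signature and the control universe, making scores invariant to
padding the matrix with absent genes.  Group comparison is a tie-corrected
Kruskal–Wallis test with Dunn's pairwise z statistics on pooled average
ranks; the pairwise family is Bonferroni-adjusted by default (Holm by
flag) — the reference procedure names only "Dunn's method", and Bonferroni
is the conservative standard reading.  Gene sets are supplied as plain
one-gene-per-line files; pathway memberships are not fetched at run time
(database versions drift).

## Synthetic cohort generator

The generator produces the study conditions the pipeline assumes, with
every unstated magnitude chosen once on realism grounds:

* **Design:** 37 patients, infection rate 16/37 (rounded to an exact
  count), 5,000 cells per patient — modest relative to real CyTOF
  acquisitions but deep enough that subset-mean sampling noise stays below
  patient-level variation for all but the rarest subsets.
* **Lineage markers** are two-component (negative 0.6 / positive 3.0 on
  the arcsinh scale, SD 0.35; CD56 adds a bright component at 5.0) with
  gating thresholds in the valleys, so the default tree recovers ≥ 99% of
  ground-truth labels.
* **Metabolic regulators** are Gaussian on the arcsinh scale (cell SD
  0.40) — for positive intensities arcsinh ≈ log(2x/5), so this is
  log-normal-type on the ion-count scale while keeping planted shifts
  exactly linear on the analysis scale.  Between-patient variation
  decomposes into a global activation factor (loading 0.18 on every
  non-targeted subset-regulator pair), a lymphoid-vs-myeloid factor
  (±0.10), and idiosyncratic patient noise (0.05).
* **The planted effect** (default: NRF1 −0.5 SD, CPT1a +0.5 SD in all
  three NK subsets of infected patients; directions fixed, magnitudes
  free parameters) lives in features modelled as an independent program —
  no shared-factor loadings — mirroring the empirical situation in which
  the infection-associated NK metabolic axis is orthogonal to the leading
  immune variation and therefore surfaces as the *third* MDS coordinate,
  after the two nuisance factors.
* **Cytokines** are log-normal with a global-factor loading; IL-10
  (+0.8 log) and IL-15 (+0.6 log) are elevated in the infected group; the
  detection limit (1 pg/mL) maps sub-threshold draws to 0 so the floor
  path is always exercised.
* **Composition** varies by patient through logistic-normal jitter of the
  subset proportions plus a lymphoid/myeloid loading on the lineage
  factor.
* **Expression matrices** for the validation stage are negative-binomial
  (dispersion 2) over a log-normal gene-mean universe, with signature-gene
  means multiplied by exp(shift) per group.
* `latent_feature_table` plants an exactly known dimensionality for the
  elbow diagnostic: orthonormalized equal-variance latent axes, an
  orthonormal-row loading map, and Gaussian feature noise (SD 1.0) whose
  floor keeps the post-elbow curve visibly flat.

What the generator does **not** emulate: instrument artifacts (bead
drift, doublets, barcode bleed), batch structure, heavy-tailed or zero-
inflated marker distributions, correlations between composition and
metabolic state beyond the two factors, and the full cellular composition
of public COVID-19 cohorts.  Passing tests therefore demonstrate that the
statistical machinery recovers what it is designed to recover under the
assumed data model — not that the biological findings replicate on any
particular real cohort.

## Degenerate inputs and tie-breaks

Constant features are dropped before standardization; all-missing
features are an error; AUROC requires both classes; bootstrap resampling
is stratified so no replicate is single-class; coordinate-selection ties
break to the lower index; rank ties take average ranks everywhere; a
stress curve without positive curvature returns the smallest dimension
with a warning; perfectly separating features in logistic fits are
flagged rather than reported with a finite odds ratio; elastic-net fits
reject single-class labels and empty λ grids.

## Problem sizes

Default analyses run at the study scale (37 patients × 5,000 cells ×
42 markers; 362 features; 1,000 bootstrap replications; 50-λ LOO paths);
simulation-based checks use 20 seeded cohorts (frequency properties),
500 cohorts × 200 replications (bootstrap coverage), and 200 cells per
group × 300 genes (signature stage).
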