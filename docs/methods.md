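# Methods

This note documents the models and procedures implemented in `mirisk`, the
assumptions behind them, the parameter defaults and why they were chosen,
and what the synthetic-data generator does and does not emulate.

## Study design being modeled

Two cross-sectional tissue cohorts of women without breast cancer — a
discovery set (n = 90; 75 low / 15 high Gail risk) used to build a miRNA
classifier and an independent replication set (n = 71; 48/23) used to
evaluate the locked model — plus a nested case-control serum cohort
(205 cases diagnosed within 18 months of blood draw, 205 matched controls)
profiled on a different platform, used to test whether the tissue panel
carries signal in blood. The generator reproduces this design by default.

## Synthetic-data generator

**Count model.** Probe counts are negative-binomial with
`var = μ + φ·μ²` (default dispersion φ = 0.05, a typical technical+biological
overdispersion for targeted counting assays; φ = 0 gives Poisson). Each
sample carries a library-size factor drawn log-uniformly on
[1/s, s] (default s = 1.5). Endogenous probes split into an expressed
minority (default 25%, matching the observed fraction of probes clearing
background on ~800-probe panels) with latent log2 means uniform on [5, 12],
and a majority fluctuating at the negative-control background floor
(mean 5 counts). Negative controls follow the background distribution only;
positive controls sit on a fixed ladder.

**Planted signal.** `n_informative` probes (default 10) are shifted by
`effect_size` log2 units (default 2, i.e. 4-fold) in the positive class.
Informative baselines are drawn from the lower half of the expressed range
so the planted shift does not perturb the top-quartile normalization
reference — with strongly expressed informative probes the per-group
normalization factors would otherwise differ systematically and leak the
class label into every probe.

**Cohort replication.** The RNG is split: `seed` fixes the probe landscape
(sequences, expressed set, informative set, baselines); `subject_seed`
redraws subjects. A replication cohort is the same landscape with a new
subject draw — the same assay applied to new women. Without this split a
"replication" cohort would measure different biology and no locked model
could transfer.

**Duplicates.** A fraction (default 10%) of samples is re-assayed.
Duplicates are multiplicative lognormal jitters of the original counts with
σ = target_CV·√π, which makes the expected pair CV (SD/mean over the two
measurements, n−1 SD) equal the target (default 4%, in the range reported
for repeat nCounter assays). Independent count redraws cannot hit a 4%
CV — shot noise alone gives CV ≈ 1/√μ — so duplicates are correlated with
their originals by construction. Duplicate CV is meaningful only above
background; the QC summary is computed on the retained probe set.

**Serum platform.** The serum generator carries a tissue panel's sequences
under platform-specific probe ids, makes exactly
⌈detectable_fraction·|panel|⌉ panel probes expressed (the rest stay at the
noise floor), and attenuates the planted effect by `attenuation` (default
4: serum retains a quarter of the tissue log-fold-change, reflecting the
heavy dilution of organ-specific signal in blood; ∞ zeroes it).

**What is not emulated:** FFPE degradation, race- or age-linked expression
structure, matched-pair correlation in the case-control set, batch
effects (the PCA screen is exercised with explicitly planted shifts in
tests), and any dependence between Gail covariates and expression beyond
the risk label itself. Passing tests therefore demonstrate correctness of
the machinery under a clean generative model, not performance on real
tissue.

## Preprocessing

- **Background.** "Below the negative controls" is operationalized per
  sample as the mean of negative-control counts (`mean_neg`, default);
  `max_neg` and `mean_plus_2sd` are selectable for sensitivity analysis.
  A probe is dropped when strictly below threshold in ≥ 50% of samples
  (boundary inclusive).
- **Order.** The default is filter → normalize; both orders are supported.
  Held-out cohorts are normalized on the probe set retained in discovery so
  the locked model sees commensurately scaled data.
- **Top-quartile-mean normalization.** Top quartile = highest ⌈p/4⌉ probe
  values of a sample, ties broken by probe order; reference = geometric
  mean of per-sample top-quartile means (robust to scale outliers; a
  single sample is its own reference). After scaling, every sample's
  top-quartile mean equals the reference to float precision; the operation
  is idempotent.
- **Transform.** Downstream modeling uses log2(normalized + 1).
- **Serum detectability** uses `mean_plus_2sd` by default: with hundreds of
  serum subjects, a probe fluctuating at background exceeds the mean of the
  negative controls in roughly half of them, so the mean rule cannot
  separate noise from signal at the "more than 50 subjects" cutoff; two
  SDs above the mean makes the rule discriminating.
- **SD convention** everywhere: sample SD (n−1).

## Risk engine

Table-driven: log-relative-risk coefficients per covariate category
(optional biopsy×age and first-birth×relatives interaction terms; every
term needs a zero-coefficient reference category) plus age-specific annual
breast-cancer and competing-mortality hazards. Missing/"unknown" covariates
resolve to the reference category. The breast hazard is treated as the
population-average incidence and divided by `average_rr` (the mean
composite RR in the population — the attributable-risk correction), so a
typical woman sits near average risk rather than above it. Absolute risk
integrates in 1-year piecewise-constant steps, matching hazard-table
granularity; with zero competing mortality and constant hazard it reduces
to the closed form 1 − exp(−y·RR·h/R̄), which the tests check. The
high/low boundary ("10% or greater increased risk") is inclusive (≥) by
default and configurable. No published risk-engine constants are shipped;
the bundled `toy_tables()` is synthetic and uncalibrated.

## Sparse PLS-DA

Two-class only. X is centered and unit-variance scaled; y is dummy-coded
into two indicator columns (so "the difference of the two predicted outcome
variables" is well defined) and also centered/scaled. Per component the
leading singular pair of the cross-covariance `M = Xᵀ Y` is computed, the
X-weight is soft-thresholded — keep the `keepX` largest magnitudes, shrink
by the (keepX+1)-th (hard top-k selectable) — renormalized, and both
matrices are deflated in regression mode. Exact-tie blocks at the threshold
fall back to hard selection so the sparsity contract (exactly `keepX`
nonzeros per component) holds; latent scores are mutually orthogonal.

Defaults: 3 components, keepX grid {5, 10, 15, 20, 25}, tuned by
stratified 10-fold CV on mean fold misclassification with ties broken
toward the sparser model. Prediction distances: `max_dist` (default),
`centroid_dist`, `mahalanobis_dist`. With sparsity disabled the fit matches
classical dense PLS-DA to machine precision (checked against an
independent NIPALS implementation and frozen reference values from an
external sPLS-DA implementation).

The risk score is ŷ(positive) − ŷ(negative); under `max_dist` a positive
score and a positive label coincide exactly.

## Permutation test

The model specification is a frozen fit-and-evaluate closure; labels are
permuted in the training cohort and the full procedure rerun (a cheaper
frozen-keepX refit mode is the default; re-tuning inside every replicate is
supported). `p = (1 + #{null ≥ observed}) / (B + 1)` can never be zero.
When a replication cohort is present the scored accuracy is replication
accuracy (the quantity whose significance the design asks about); otherwise
training accuracy. Calibration caveat: accuracy is discrete, so with small
evaluation cohorts ties between null and observed values make the p-value
conservative; the calibration test uses a ~200-subject evaluation cohort,
where the null p distribution is uniform to KS precision.

## Serum transfer

Matching is exact on U/T-harmonized, case-folded mature sequences;
within-platform duplicate sequences collapse to the lexicographically first
probe id (logged). The panel refit on tissue re-tunes keepX on the
restricted panel by default (freezable). Because digital counts and array
intensities are not commensurable, serum data are z-scored per feature
using the serum cohort's own statistics and mapped into the tissue model's
feature scale — by default centered on the *class-balanced* tissue feature
mean, since a matched case-control cohort is balanced by design while the
tissue training set is not (centering on the pooled training mean would
push every serum subject toward the majority training class). This is a
modeling choice, not an estimated calibration, and is the package's own
construction.

Risk-score quartiles are rank-based over all subjects (ties broken by input
order, remainder spread from Q1 up; control-only cutpoints available).
Quartile odds ratios are the 2×2 cross-products against Q1 — identical to
the indicator-coded unadjusted logistic fit, which a test verifies against
statsmodels — with Wald CIs `exp(ln OR ± 1.96·√Σ1/cell)`; zero cells give
unbounded CIs with a warning rather than a continuity fudge.

## Problem sizes and numerical choices

Simulation-based tests use the study's cohort sizes (90/71/410) with the
default 800-probe panel for recovery and transfer checks, and compact
cohorts (~70 probes, 40 training subjects, ~200 evaluation subjects,
B = 99, 200 replicates) for permutation-calibration, which keeps the whole
suite in the low minutes while leaving the statistics well-resolved.
Convergence tolerance of the sparse power iteration is 1e-9 (max 500
iterations); orthogonality is asserted at 1e-8; normalization equality at
1e-9 relative. Constant features are dropped with a warning before
fitting. All pipeline randomness descends from one root seed split per
stage.

## Known limitations

- Two classes only; no AUC-based tuning, ROC analysis, or calibration
  curves.
- The permutation p-value is conservative for small evaluation cohorts
  (discreteness), as noted above.
- The cross-platform z-standardization assumes comparable within-cohort
  orderings between platforms; real array-to-counter transfer may violate
  this in ways the generator does not model.
- The risk engine is a faithful structural implementation, but shipping
  tables are synthetic; results on real covariates require user-supplied
  coefficient/hazard tables.
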