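# Methods

## The mixture model

Bulk PBMC expression from a leukemic CTCL patient is treated as a
two-component mixture.  If a gene's mean abundance is `m_g` in malignant
cells and `base_g` in the normal compartment, a sample with malignant
fraction `f` has noiseless abundance

    x_g(f) = base_g · (1 + (φ_g − 1) · f),     φ_g = m_g / base_g,

linear in `f` on the intensity scale.  Everything downstream — gene
selection by regression on `f`, the calibration-inversion predictor, the
fold-change definitions — follows from this linearity.  The model ignores
within-compartment regulation (a gene changing *inside* malignant cells over
treatment), compositional shifts among normal subsets, and saturation
effects of array intensities.

## Burden trajectory and Gaussian fit

The malignant fraction over a responding patient's visits is modelled as

    f(t) = floor + p0 · exp(−(t − t0)² / (2σ²)),

with the peak constrained at or before the first observation so the fitted
curve decays monotonically over the observation window.  Parameters are
estimated by bounded nonlinear least squares (`scipy.optimize.least_squares`)
from five deterministic method-of-moments starts (floor = min, p0 =
max − min, t0 = first time, σ from the half-decay point scaled by
{¼, ½, 1, 2, 4}); the best converged start wins.  `R² = 1 − SSres/SStot`,
with the convention `R² = 1` when observations are constant and residuals
vanish (degenerate flat fit) and an explicit error otherwise.  Observed
visits always override model predictions in the final trajectory; the model
only fills unobserved visits.  The relapse sample is never extrapolated from
the decay model — its burden must be observed.

Only the functional family is assumed; with four free parameters and nine
observations the noiseless fit recovers the generator's parameters to ~1e−11
and, under 2% multiplicative observation noise, the median peak-fraction
error stays below 0.01 over 200 replicates.

## Gene selection

Per gene, ordinary least squares of linear-scale abundance on
`[1, f, batch indicators]` over the patient visits.  Two-sided t p-values on
the slope are Benjamini–Hochberg adjusted across genes; selection requires
slope > 0 and q < 0.05.  A second filter drops genes whose late-treatment
expression (default: cycles 9–12) falls significantly below the healthy-donor
level: a one-sided test of late < healthy must give p > 0.5 for the gene to
survive.  That printed criterion is deliberately lenient — under exact
equality it discards about half of borderline genes — and is implemented as
printed, with the threshold exposed as a parameter.

Batch effects are multiplicative on the intensity scale, so the floor test
runs on log2 values with additive batch covariates (an OLS group contrast)
when batch labels are available for both groups, falling back to a Welch
test otherwise.  Keeping the selection regression itself on the linear scale
is a deliberate mismatch: the mixture signal is linear in `f`, while the
small (2%) residual batch effects perturb it negligibly.  A singular design
(a batch confounded with the burden trajectory) raises an error naming the
collinear columns rather than silently dropping them.

Fold change per gene is model-predicted expression at the maximum versus
minimum trajectory fraction, `(a + b·f_max)/(a + b·f_min)`; the "strong"
subset keeps selected genes with fold ≥ 2.

## The predictor (calibration inversion)

Training fits per-gene lines `x_g = a_g + b_g·f` on the visit series
(≥ 5 samples spanning a burden range ≥ 0.3; narrower ranges leave the
calibration unidentifiable and error out).  Prediction inverts all
calibration lines at once by precision weighting:

    f̂ = Σ_g w_g·b_g·(x_g − a_g) / Σ_g w_g·b_g²,   w_g = b_g² / s_g²,

i.e. the generalized-least-squares estimate of `f` given the gene-wise
linear models, clipped to [0, 100] after scaling to percent.  Genes with
zero slope get zero weight; zero residual variance caps the weight at 1e12.
The estimator is exactly invariant to rescaling all expression by a
constant (slopes, intercepts and weights co-scale).

Cross-platform application first maps each gene's external distribution onto
the training healthy reference by a location/scale transform estimated from
≥ 2 external healthy-like samples (`(x − m_ext)/s_ext · s_train + m_train`).
Using SD ratios keeps the transform invariant to pure location shifts, at
the cost of noisy per-gene scale estimates when reference groups are small;
the noise averages out across hundreds of signature genes (correlations are
preserved; a few percent of multiplicative bias in `f̂` can remain).

## Signature cascades

*Surface markers*: a candidate must be annotated plasma membrane
(GO:0005886) or receptor activity (GO:0004872) and pass four
expression criteria — ≥ 2-fold change across the index patient's treatment;
significant pre-treatment elevation over healthy donors in the other
patients (p < 0.05); ≥ 1.2-fold significant difference between purified
CD26⁻ and CD26⁺ cells; significant difference between purified patient CD4
and healthy CD4 cells.  Genes with any missing comparison are reported as
not evaluable, never passed silently.  "At least"-folds are inclusive
boundaries; a relapse re-expression fold of exactly 1.5 is *not* "low"
(the low-relapse rule is strictly < 1.5).

*Residual disease*: stage 1 is a one-sided Welch test (log2 scale) of
remission > healthy per predictor gene, BH across candidates, keeping
fold ≥ 1.2 and q < 0.05.  Stage 2 tests the single relapse value against the
remission distribution with prediction-interval scaling
(`t = (x − mean)/(sd·√(1 + 1/n))`, df = n − 1 — the exact test for one new
observation against a normal sample), BH across stage-1 survivors, keeping
increase ≥ 1.2 at q < 0.05; increases > 1.5 are flagged strong.  Without a
relapse sample stage 2 is skipped and flagged on the result.  The remission
window defaults to treatment cycles 7–12 (the clinical-remission period),
configurable.

*Yin-yang*: Spearman rho with mid-ranks between the activator and repressor
across patient samples; the p-value is an exact permutation enumeration for
n ≤ 8 and the asymptotic approximation above (beyond n = 8 the exact and
asymptotic values agree to the precision anyone uses them at, and full
enumeration grows factorially).  Per-sample log2 activator/repressor ratios
use a pseudo-count (default 1).

## Regulatory-layer statistics

Overlap of a size-A and size-B set from a size-C universe reports expected
count A·B/C (an exact identity, not an estimate), fold k/expected, and the
exact hypergeometric upper tail P(X ≥ k).  Fisher's two-sided p uses the
minimum-likelihood rule.  Both match exhaustive rational enumeration to
1e−10 for all margins ≤ 30 (tested).  Motif enrichment is hypergeometric
per motif with Bonferroni correction and a fold ≥ 1.2 requirement, "20%
enrichment" read as fold ≥ 1.2 on the proportion scale.  miRNA families are
collapsed across members by the maximum (conservative for increase
detection; mean available), tested by one-sided Welch on log2 values between
high-burden (f ≥ 0.5) and low-burden (f ≤ 0.1) visits, BH-adjusted, keeping
fold ≥ 2 at FDR < 0.1%.  Methylation probes are screened by Spearman
correlation with the burden trajectory (BH across probes) with the effect
size `delta_beta` = mean(low-burden tercile) − mean(high-burden tercile);
"20% change" is read as absolute Δβ ≥ 0.20 (β is already a proportion), so a
probe moving 0.09 → 0.24 is a real but sub-threshold change.  Terciles are
defined on the trajectory with ties broken by visit order; constant probes
are excluded with a notice.

## The synthetic cohort

The generator defines the study conditions the tests run under.  Defaults:
28 visits across 12 four-week cycles (visits labelled `cXXwY`, spread evenly
over the cycle/week grid), pre-treatment fraction 0.93 decaying with
σ = 0.22·n_visits ≈ 6.2 visits (burden < 5% by visit 19, cycle 7) to a
residual remission floor of 0.03; flow observations at 9 evenly spaced
visits plus the relapse sample; relapse at one third of the pre-treatment
burden; 4 training and 5 validation healthy donors at fraction 0.

8000 genes with baselines log-uniform on [50, 5000]; 300 signature genes
with linear folds φ log-uniform on [1.2, 20], of which 20 are "zero in
normal" — baseline pinned to the detection floor (10 units) with φ forced
above 10, so they remain detectable at a 3% residual burden (these double as
the guaranteed strong tail).  The first of them is the plastin-like marker,
its fold calibrated so the pre-treatment/deepest-remission expression ratio
is exactly 18.7.  Noise is multiplicative log-normal with σ = 0.02 — the
technical replicate CV of quantile-normalized bead arrays for well-expressed
probes; since all patient samples are one subject's longitudinal series,
inter-individual biological variance is deliberately absent (see
limitations).  Two batches interleaved by collection order add per-gene
multiplicative shifts with σ = 0.02 (residual post-normalization batch
effect).  Detection p-values decay exponentially in abundance above the
floor, so floor-level genes are "undetected" (p > 0.05) in healthy samples.

The activator TF follows the mixture law (7-fold slope); the repressor
follows `base·((1−f)/(1−f_min))^γ` with γ solved so its span between
pre-treatment and deepest remission is 60-fold.  A convex mixture in (1−f)
cannot exceed ~14-fold over that range, and the repressor's rise is
per-cell regulatory rather than compositional, hence the power law — the
dependence stays monotone in (1−f), which is all the rank statistics see.

Methylation: planted probes mix (β_malignant, β_normal) pairs by `f` plus
Gaussian noise (σ = 0.01), clipped to [0, 1]; strong probes draw gaps of
0.32–0.5 (so the tercile Δβ clears 0.20 given the ~0.65 spread in mean
burden between terciles), one canonical probe uses the 0.23 → 0.61 pair, and
the plastin-like probe (0.09, 0.24) is planted deliberately below threshold.
miRNAs: 100 families × 2 members; 24 planted families scale as
`0.1 + 0.9·(1−f)` (≥ 2-fold increase over treatment), 6 of them carry
target tables drawn from the signature genes; the rest are flat.  Eleven
genes (signature indices 1–11) are planted in all three layers — motif
annotation, every designated family's targets, and strong hypomethylated
probes — forming the triple-regulated core.  The motif covers ~60% of
signature genes and 8% of the background; ten decoy motifs cover 8%
everywhere.

All randomness flows from one integer seed through `numpy.random.SeedSequence`
children per matrix, so identical (config, seed) bundles are byte-identical
when written.

## What passing tests do and do not show

The generator reproduces the statistical *structure* the pipeline assumes —
a linear mixture, monotone burden decay, planted regulatory layers — under
optimistic noise (one subject, technical noise only, no inter-individual
variance, no probe cross-hybridization, no outlier samples).  Recovery rates
near 100% therefore validate the implementation, not clinical performance:
with real inter-patient heterogeneity the healthy-floor filter and the
residual-disease cascade in particular would lose power, and the predictor's
external correlation would drop well below the synthetic value.  What the
suite establishes is that each stage computes exactly the statistic it
claims, controls FDR at the nominal level under the null, and recovers
planted truth whenever the signal exceeds the stated thresholds.

## Numerical conventions

- Burden-class boundaries: exactly 20% and 50% fall in the lower class
  (LTB/MTB), since the upper classes are defined by strict inequality.
- Quantile normalization assigns tied entries the mean of the order-
  statistic means their rank range spans; it is idempotent on tie-free data.
- Ratio filtering floors non-positive values at 1e−6 and records that the
  floor was applied.
- BH is the standard step-up procedure, capped at 1, input order preserved.
- Zero residual variance in calibration → weight capped at 1e12; slopes
  below 1e−9 relative to the intercept snap to zero (flat genes must carry
  exactly zero weight).
- Fold changes with non-positive model-predicted baselines report +inf
  rather than a sign-flipped ratio.
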