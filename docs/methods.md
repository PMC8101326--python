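# Methods

## The ratio-feature model

All analysis happens on the log2 scale. For miRNA *i* and sample *s* the
observed chip value is modelled as

```
x_i(s) = μ_i + class effect + c_s + ε_i(s)
```

where `c_s` is a sample-specific additive disturbance (dilution, input
amount, implicit reference choice) and `ε` is measurement noise. No
estimate of `c_s` is ever attempted: the pair feature
`r_ab(s) = x_a(s) − x_b(s)` removes it identically. This is the package's
defining invariant, and it is tested as *strict equality of floating-point
bits*, not approximate equality (see "Numerical choices").

For RT-qPCR, abundance is taken as proportional to `2^(−Ct)` (ideal
amplification efficiency), so the log2 ratio of a over b is
`Ct_b − Ct_a`. Pair orientation is canonical — lexicographic, `a < b` —
on both platforms, so a chip-trained model applies to ΔCt features with
no sign bookkeeping. Efficiency-corrected Ct models are out of scope.

## Differential expression

Candidate miRNAs are ranked by an empirical-Bayes moderated two-sample t:
per-miRNA pooled variances `s²` are shrunk toward a prior
`s̃² = (d₀s₀² + d·s²)/(d₀ + d)`, with `(d₀, s₀²)` estimated by method of
moments from the spread of `log s²` (digamma/trigamma identities,
trigamma inverted numerically; `d₀ = ∞`, i.e. complete pooling, when the
observed variances show no excess spread). The statistic is
`t = Δ / (s̃·√(1/n₁ + 1/n₂))` on `d₀ + d` degrees of freedom, two-sided.
Setting the prior weight to zero recovers the ordinary pooled t exactly;
a Welch option exists for unequal variances. A unit test checks the
implementation against Bioconductor limma's `eBayes` on a
heterogeneous-variance fixture (agreement to 1e-6 relative).

Defaults: BH-adjusted p < 0.05, no fold-change floor (`min_abs_lfc = 0`).
These cutoffs are conventional, configurable, and — because the upstream
cohorts behind the published counts are not bundled — not treated as
reproduction targets. `alpha = 1` disables the FDR filter entirely.

## Pair screen

Each pair feature gets a univariate logistic fit
`label ~ β₀ + β₁·r_ab` (Newton–Raphson, vectorized across all pairs via
closed-form 2×2 solves) and a two-sided Wald p-value; pairs with
`p < 0.05` (default) are kept. Two deliberate policies:

- **Perfect separation keeps the pair.** A monotone likelihood makes β̂
  diverge, but a separating ratio is the most promising biomarker in the
  matrix; it is kept with `p = 0`, `β = ±∞` and a `separated` flag.
  Downstream regularized fits handle it.
- **Constant features are dropped** with `p = 1` (slope inestimable).

The Wald test matches default univariate logistic reporting; statsmodels
`Logit` serves as the oracle in tests. On null data the screen keeps
~5% of pairs at α = 0.05 (checked on 1,000 noise pairs).

## Nested panel selection

The selection mechanism formalizes "controlling λ" on one L1 logistic
path: the size-*j* model is defined by the largest grid λ at which exactly
*j* features are active, which makes panels of sizes 1..k nested by
construction. The path solver is glmnet-style penalized IRLS: an outer
quadratic approximation, inner cyclic coordinate descent with
soft-thresholding, warm starts along a log-spaced grid of 100 λ values
from `λ_max = max_j |x_jᵀ(y − ȳ)|/n` (standardized features, mean
negative log-likelihood loss) down to `λ_max/100`. Features are z-scored
internally for the penalty; coefficients are reported on the original
scale. At `λ_max` the null model is recorded as the exact solution.

- Convergence: max coefficient change < 1e-7, cap 1e5 coordinate sweeps
  per λ (error if exceeded, naming the λ).
- Tie-breaks on simultaneous entry: larger |coefficient| at the next grid
  point, then lexicographic pair ID — deterministic and seed-free.
- Exact duplicate (standardized) columns: only the lexicographically
  first is eligible; the others are reported as aliased.
- Drop/re-entry along the path (rare): if no grid λ has exactly the
  wanted active set, the model is refitted by L1 on those features at the
  geometric midpoint of the neighbouring entry λs, and flagged.
- If fewer than k features ever activate, the maximal panel is returned
  with a warning rather than an error.

Correctness is checked against a generic convex solver (bound-constrained
L-BFGS-B on the split β = β⁺ − β⁻ formulation): on small instances the
path's objective value is within 1e-6 of the oracle optimum (measured
~1e-15). Cross-validated λ selection and elastic-net mixing are
non-goals: panels are chosen by size, not CV.

## Classifier families

Each family is bound to a fixed pair list (plus optional covariates);
feature names and order are a hard contract at predict time. Higher score
always means more case-like (control=0, case=1).

| family | engine | score | defaults |
|---|---|---|---|
| lasso_logistic | own coordinate-descent solver at the panel's recorded λ | linear predictor | not re-tuned |
| logistic | unpenalized ML (lbfgs) | linear predictor | ridge 1e-6 fallback on perfect separation |
| random_forest | 500 trees, √p features/split | case vote fraction | seeded |
| svm | RBF, C=1, γ=1/p on internally standardized features | signed decision value | mirrors e1071's scale=TRUE |

The published sources name the R packages but not their settings; the
defaults above are those packages' own defaults and are overridable via
`params`. Age is appended standardized (training statistics should be
reused on test data); sex is coded female=0/male=1. Probability
calibration and class reweighting are non-goals.

## Evaluation

AUC is the tie-aware Mann–Whitney statistic (½ credit for ties — this
makes AUC well-defined for the forest's discrete vote scores). The ROC
curve is enumerated at every distinct threshold, and the stored AUC is
the trapezoidal area of that curve, which equals the U statistic
identically; tests hold the two routes together to 1e-12 against
exhaustive pair counting. Splits are stratified by class, deterministic
given a seed; default training fraction 0.7 (mirroring a ~72/28 published
split). Subgroup evaluation scores {filtered cases} ∪ {all controls}.
Confidence intervals and DeLong comparisons are intentionally omitted.

## Synthetic cohorts

`SimConfig` defaults define the package's standard study conditions:

| parameter | default | meaning |
|---|---|---|
| n_case / n_control | 100 / 100 | cohort size |
| n_mirna | 40 | miRNA catalog |
| baseline_mean_range | (4, 14) log2 | per-miRNA abundance levels (uniform) |
| baseline_sd | 0.5 log2 | per-sample biological variation |
| signal_pairs | (m00↑, m02↓), (m01↑, m02↓), δ=1.5 | planted effects |
| sample_offset_sd | 1.5 log2 | the normalizer disturbance |
| measurement_sd | 0.5 log2 | technical noise |
| stage_fraction_early / early_attenuation | 0.3 / 0.6 | early cases carry 60% of the effect |
| ct_intercept / ct_noise_sd | 38 / 0.25 cycles | Ct rendering |
| quantum | 2⁻¹⁶ | export precision grid |

Signal is planted symmetrically (±δ/2 on the pair members) so the pair
feature carries the full δ while each single miRNA carries half — the
disturbance (SD 1.5) is then 3× the per-value noise (SD 0.5), exactly the
regime where per-miRNA testing collapses and ratios do not.

**Why the planted pairs share their down-member.** With two disjoint
planted pairs (a↑,b↓), (c↑,d↓) of equal δ, the cross pairs (a,d) and
(c,b) carry *identical* effect size, so "recover the planted pairs" is
unanswerable in principle (any method picks a planted or a cross pair at
coin-flip odds). Planting (a↑,b↓) and (c↑,b↓) instead gives the two
planted ratios effect 1.5δ — strictly the largest in the matrix (best
impostor: δ) — making recovery a well-posed question. The recovery study
additionally runs on a stageless cohort (`stage_fraction_early = 0`) so
every case carries the stated δ; stage attenuation is exercised
separately by the subgroup analyses. The recovery experiment pairs all 40
miRNAs (780 features) without a DE pre-filter: DE screening exists to cut
chip-scale catalogs (thousands of miRNAs) down to hundreds, and at 40
miRNAs it would only discard candidates using exactly the per-miRNA
statistic that sample offsets corrupt.

**What the generator does not emulate:** probe chemistry, hemolysis,
batch structure beyond per-sample offsets, heavy-tailed noise,
amplification-efficiency variation in Ct space, missing-value patterns.
Passing tests therefore demonstrate the algebraic and statistical
properties of the method under its stated noise model, not performance on
any real cohort; the published cohort-level AUCs require the original GEO
and hospital data and are documented, not reproduced.

## Numerical choices

- **Bit-exact invariance via quantization.** Floating-point addition is
  not exactly invertible, so `(x+c) − (y+c)` generally differs from
  `x − y` in the last ulp. The simulator quantizes every additive
  component to a 2⁻¹⁶ log2-unit grid (≈1.5e-5, far below any noise scale,
  emulating fixed-precision chip exports). All sums then stay well inside
  the 53-bit mantissa and are exact, so per-sample offsets cancel
  *bit-for-bit* in pair features and in end-to-end model scores. For
  arbitrary full-precision inputs the cancellation holds to ~1e-12 and is
  tested at that level.
- **Lossless TSV round trips.** Floats are written with `repr` (shortest
  exact decimal) and parsed back with `np.float64` per cell — pandas'
  fast numeric coercion can lose the final ulp.
- **Missing values** propagate: a pair feature with a missing member is
  missing for that sample; model fitting refuses missing features rather
  than imputing.
- **Degenerate inputs** have defined behaviour throughout: zero-variance
  miRNAs (t=0, p=1), constant pairs (dropped), separating pairs (kept,
  flagged), single-class cohorts (refused), k_max beyond the path
  (maximal panel + warning), one-case subgroups (valid degenerate ROC).

## Problem sizes

The validation studies use 20 replicate cohorts of 200 samples × 40
miRNAs (780 pair features) for recovery/nesting/transfer, 200 random
instances for the AUC oracle, 50 instances (≤ 8 features, ≤ 40 samples,
20-λ grids) for the convex-solver comparison, 50 offset draws for the
invariance check, and 1,000 null pairs for screen calibration — sizes at
which every study completes in a few minutes on one CPU while estimating
each rate with adequate precision.
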