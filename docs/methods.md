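# Methods

This note documents the statistical model behind `collinear-ewas`, the
synthetic-data generator's construction and its limitations, the
numerical conventions, and the design decisions that were genuinely
open.

## Regression model and inference

All model families are ordinary least squares with an intercept:

log_e BMI ~ CpG% + age + sex [+ cell proportions].

Methylation enters in percent (0–100), so a coefficient is the change in
log BMI per percentage-point of methylation. Standard errors are
classical (homoskedastic), 95% confidence intervals use the t
distribution on the residual degrees of freedom, and missing data are
handled complete-case *per fitted model* — each CpG therefore carries
its own n. Sex is coded 0/1; the coding affects only the sex
coefficient (asserted by test). Robust/clustered errors, mixed models
and M-value transforms are out of scope.

Exactly collinear designs are rejected with the aliased columns named
(QR with column pivoting), except in VIF computation, where a perfectly
collinear predictor is reported as VIF = ∞ with a warning so that
array-scale sweeps are not aborted by a single degenerate CpG.

## Collinearity diagnostics

For predictor j, VIF_j = 1/(1 − R²_j) with R²_j from regressing
predictor j on all other predictors with intercept (the `car::vif`
convention; the intercept itself never receives a VIF). Tolerance is
1/VIF and percent variance explained is (1 − 1/VIF)·100; VIF ≤ 5
(i.e. ≤ 80% shared variance) is treated as the conventional
acceptability cut-off. Condition indices divide the largest singular
value of the column-scaled (unit Euclidean length) design by each
singular value. Spearman p-values use the t approximation on
r√((n−2)/(1−r²)) everywhere — exact permutation p-values would be
intractable at array scale and matter only for n ≲ 10. The array-wide
screen streams CpG rows in configurable chunks (default 5,000) to keep
memory flat at 450K scale, and skips any cell type whose sample SD is
below 1e-6 (an essentially constant estimated fraction, as happens for
NK cells in some cohorts) with a logged notice.

## Synthetic cohort: latent near-compositional construction

The generator draws all 16 analysis variables (outcome on the log-BMI
scale, nine CpGs in percent, six cell proportions) as one multivariate
Gaussian and then transforms: BMI = exp(outcome draw) (log-normal),
methylation clipped to [0, 100], proportions clipped to [0, 1], per-CpG
completely-at-random missingness. Age ~ N(17, 0.25²) years and
sex ~ Bernoulli(0.5) are independent of everything else.

The target correlation matrix cannot be taken directly from published
summaries, because the cell-cell block is never printed. It is instead
*constructed* from a latent model chosen so that every quantity that is
printed is reproduced exactly, and the matrix is positive definite by
construction (`build_latent_correlation_matrix` returns the loading
matrix L with corr = LLᵀ):

1. The five non-granulocyte cells load on one shared latent factor F
   with loadings a_i = r_i / b, where r_i are the reference CpG's six
   published cell correlations (0.611, 0.553, 0.371, 0.215, −0.402) and
   b is the CpG's own loading on F (default 0.85).
2. Granulocytes are `constant − Σ(other cells) + remainder`: the
   compositional closure that makes the six proportions average ≈ 1.05
   (the deconvolution's estimates typically sum slightly above one) with
   a small remainder variance fixed by the granulocyte SD. This is the
   structural source of the collinearity: given the other five cells and
   the CpG, almost nothing of the granulocyte fraction is left
   unexplained.
3. The reference CpG (cpg4) loads on F, on the granulocyte remainder,
   and on an idiosyncratic term, with the two free loadings solved so
   its correlation with granulocytes is exactly −0.783.
4. The outcome loads on F, the remainder, and the CpG's idiosyncratic
   term, solved so that (a) its marginal correlations with granulocytes
   (0.16) and with the CpG (−0.0998, see below) are exact, and (b) its
   *conditional covariance with the CpG given all six cells* equals a
   parameter γ. γ is the single knob controlling the strength of the
   adjusted (reversed) association; its default 0.032 makes the
   cell-adjusted partial t-statistic at n = 812 approximately +1.88,
   matching the adjusted fit it emulates (β = 0.004, p ≈ 0.06). The
   marginal association stays negative (t ≈ −2.85, p ≈ 0.003), so the
   generator reproduces the reversal phenomenon by construction rather
   than by accident.
5. Every other CpG is an attenuated copy of the reference CpG's latent
   signal plus independent noise, with attenuation factors (0.70, 0.49,
   0.735, 1.0, 0.973, 0.98, 0.961, 0.98, 0.98) echoing the relative
   strengths of the nine CpGs' correlations with the leading cell-
   composition axis. These are structured defaults, not published
   values.

A naive alternative — assembling a matrix from the printed entries plus
an independent-cells compositional block and projecting to the nearest
positive-definite matrix — fails quietly: with mutually independent
cells the implied R² of the reference CpG on the six cells exceeds 1, so
the assembled matrix is far from feasible and the projection moves the
printed entries by more than the generator's own 0.02 recovery
tolerance. The latent construction avoids projection entirely.
Nearest-PD repair (Higham projection via statsmodels) remains available
as an opt-in (`repair=True`) for user-supplied matrices, logging the
Frobenius distance moved; by default a non-PD matrix raises with the
smallest eigenvalue named.

Means and SDs are documented placeholders, configurable in
`CohortSpec`: log-BMI mean log 22 ≈ 3.09 (median BMI 22 kg/m², typical
for adolescents), SD 0.15; methylation 8% ± 3.7% (a lowly methylated
promoter region; the SD makes the unadjusted coefficient ≈ −0.004 per
percent, the magnitude the model battery is designed around); cell
means (0.10, 0.17, 0.07, 0.08, 0.08, 0.55) with SDs (0.035, 0.06,
0.018, 0.014, 0.010, 0.095), typical Houseman whole-blood estimates.
Every collinearity conclusion depends only on the correlation structure
and n, not on these location/scale choices (asserted by test for the
Monte-Carlo experiment). Per-CpG missingness rates default to one minus
the published complete-case counts over 812 (e.g. 780/812 → 3.9% for
cpg1); the missingness mechanism is MCAR — the varying per-CpG counts
motivate the feature, but no mechanism beyond that is modeled.

Clipping proportions to [0, 1] rather than using a logit transform keeps
the Pearson targets directly interpretable; at the default parameters
the nearest boundary is ≈ 3.9 SDs away (NK cells), so clipping affects
< 0.1% of draws and biases each proportion mean by < 0.01 (asserted at
n = 10⁵).

What the generator does *not* emulate: beta-value heteroskedasticity
and boundary pile-up of real methylation data, informative missingness,
batch and plate effects, relatedness, or any nonlinear
methylation-phenotype relationship. Passing tests therefore demonstrate
the statistical mechanics of compositional collinearity, not properties
of any real cohort.

## Monte-Carlo sign-reversal experiment

Each replicate draws n = 812 observations of (outcome, methylation,
granulocyte) from a trivariate Gaussian with correlations
(r_ym, r_yg, r_mg) and fits outcome ~ methylation (+ granulocyte). The
fraction of replicates with a positive methylation coefficient is
reported with its binomial Monte-Carlo standard error
√(p(1−p)/replicates); a coefficient of exactly zero counts as
non-positive. Fits are vectorized (batched 3×3 normal equations), so
1,000 replicates take well under a second.

The outcome-methylation correlation is not printed anywhere; it is
derived from the unadjusted fit's printed β = −0.004, 95% CI (−0.0065,
−0.001) and n = 812 with two covariates via r = t/√(t² + df), df = 808,
giving −0.0998, and is exposed as a parameter. The simulated regressions
include no age/sex terms by default (only the three named variables are
simulated); an option adds independent age/sex covariates, which are
immaterial (asserted by test). Scenario seeds derive from the master
seed through `SeedSequence` spawning, so sweep scenarios are independent
but reproducible.

The closed-form oracle: the fitted coefficient's sign equals the sign of
the sample partial correlation ρ̂ of outcome and methylation given
granulocyte (marginal when granulocyte is omitted), and ρ̂ is
asymptotically normal around the population value ρ_p with variance
≈ (1−ρ_p²)²/n, so P(β̂ > 0) ≈ Φ(ρ_p√n / √(1−ρ_p²)). At n = 812 and the
default correlations this gives 88.0% / 25.3% / 3.7% / 0.2% for
r_mg = −0.783 / −0.5 / −0.25 / granulocyte-omitted; the Monte-Carlo
fractions agree within three Monte-Carlo standard errors across a
12-scenario grid (asserted by test).

## Remediation strategies

- **Drop the highest-VIF cell type** (granulocytes): brings all VIFs
  under 5 on default cohorts, but the adjusted coefficient stays
  positive because the remaining cells still carry the composition
  signal.
- **PC substitution**: PCA of the six proportions (SVD on the centered,
  optionally scaled matrix; centering on, scaling off by default —
  the defaults of the standard tooling; both exposed since practice
  varies). Component signs are fixed by making each component's
  largest-magnitude loading positive, so results are reproducible
  across linear-algebra backends. With all six components the scores
  span the same column space as the proportions, so the CpG coefficient
  is *identical* to the fully adjusted model's (asserted to 1e-8).
- **Residualization**: `mode="each"` regresses the CpG on one cell type
  at a time (six fits), `mode="all"` on the six jointly; the outcome
  model retains age and sex. An extended mode additionally residualizes
  on age and sex, which by the Frisch–Waugh–Lovell theorem reproduces
  the fully adjusted CpG coefficient exactly (asserted to 1e-8).

The two identities operationalize the study's conclusion: when
collinearity is structural (compositional), reparameterizing or
residualizing the covariates cannot change the adjusted estimate; only
removing information (fewer PCs, dropped cells) changes it, at the cost
of reintroducing the confounding one adjusted for.

## Numerical conventions and degenerate inputs

- PD checks use Cholesky; failures report the smallest eigenvalue.
- VIF auxiliary regressions use `lstsq`; R² ≥ 1 − 1e-12 ⇒ VIF = ∞.
- Constant columns: rejected in VIF (undefined), recorded as missing
  with a warning in correlation matrices, skipped in the screen, and
  rejected for scaled PCA (near-zero SD relative to column magnitude).
- Correlations need ≥ 3 complete pairs; fits need ≥ 2 more complete
  rows than design columns; PCA of six cells needs ≥ 7 complete rows.
- All randomness flows from integer seeds through numpy `default_rng`
  / `SeedSequence`; identical configuration ⇒ byte-identical outputs
  (asserted for the cohort CSV and every pipeline TSV).

## Problem sizes

Defaults mirror the emulated study: cohort n = 812 with nine CpGs;
Monte-Carlo scenarios use 1,000 replicates of n = 812. Correlation-
recovery checks run at n = 10⁵, where the Monte-Carlo SD of a sample
correlation (≲ 0.004) is well inside the 0.02 assertion band. The
array-wide screen is exercised on a 1,000-CpG, 1,000-participant
fixture with 50 planted associated CpGs; real 450K-scale counts depend
on data that is only available on application and are not asserted.

## Known limitations

- The Gaussian copula for proportions admits (rare) boundary clipping
  and cannot represent strongly skewed cell fractions.
- The cell-cell correlation block is a modeling choice constrained by
  printed marginals, not an estimate; different feasible completions
  would give different (equally defensible) VIF magnitudes, which is
  why only the qualitative VIF pattern (granulocytes ≫ 10 with six
  cells; all < 5 without) is asserted, not published VIF values.
- The analytic sign-probability oracle is a large-n normal
  approximation; for n ≲ 100 or |ρ_p| near 1 its error can exceed
  Monte-Carlo noise.
- Single-CpG inference only; no multiple-testing machinery is included.
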