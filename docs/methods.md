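# Methods

This note documents the statistical machinery in `pedqus`: the models, the
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical decisions a maintainer would want written down.

## Cohort model (synthetic data)

The generator is a structural-equation model: covariates are drawn first,
outcomes follow as linear/monotone links plus Gaussian noise. It emulates a
single-center healthy pediatric cohort (n = 129 recruited, 112 analyzed).

**Covariates.** Age follows a truncated normal on [0, 18). The underlying
location/scale are solved so the *truncated* moments match the requested
mean (default 6.89 y); a requested SD of 5.32 y at that mean is infeasible
for the truncated-normal family on this support (the family's SD tops out
near 4.9), so the realized SD is ≈ 4.7 — the one marginal the generator
knowingly under-disperses. Sex is a shuffled fixed-composition vector
(58% boys), which keeps the sex ratio tight at fixture size.
Anthropometric SD scores are Gaussian; BMI SDS is truncated to the
analyzed-sample range [−1.75, 1.96] except for deliberately planted
under-/overweight records. Abdominal wall thickness increases with age
(0.30 mm/y) and BMI SDS (0.9 mm/unit); the age slope is set somewhat below
what the strongest published wall–age association would imply so that the
ATI–SWE correlation induced through the age → wall path stays qualitatively
null (|r| ≈ 0.1), matching the observed independence of ATI from the
elastography outcomes.

**Outcomes.**

| outcome | link | defaults |
|---|---|---|
| ATI [dB/cm/MHz] | `0.66 − 0.0095·age + ε`, σ = 0.05 | 0.66 in infancy → 0.49 at age 18 |
| SWE [m/s] | `1.166 + 0.0069·wall − 0.036·female + 0.05·u + ε`, σ = 0.055 | girls lower; u shared latent |
| SWE [kPa] | `3ρc²`, ρ = 1000 kg/m³ | deterministic conversion, r(kPa, m/s) ≈ 1 |
| SWD [(m/s)/kHz] | `13.03 − 0.338·bmi_sds + 1.0·u + ε`, σ = 1.09 | u ties SWD to SWE (r ≈ 0.4) |

SWD is missing completely at random at rate 14/129 (the analyzed SWD sample
is smaller than the cohort and no mechanism is documented; MCAR is the
neutral choice). Sex is coded male = 0 / female = 1 wherever arithmetic
needs a number — the negative SWE–sex correlation therefore means "girls
lower". Cooperation is coded calm = 0 / restless = 1.

With these defaults the generated ATI–age correlation (≈ −0.7) is stronger
than typically reported (≈ −0.5): the intercept/slope are anchored to the
infancy/adolescence mean levels and the marginal SD to ≈ 0.07, and those
anchors take precedence over the correlation magnitude.

**What the generator does not emulate:** measurement replication (each
child contributes one averaged value), operator effects, right-skewed age
recruitment, device differences, and any pathology. Passing tests therefore
demonstrate that the *machinery* is correct under the documented structure,
not that real pediatric data obey it.

The 129-record fixture (`make_fixture_129`, default seed 20210201) plants
exactly 8 enzyme-elevated records (normal BMI) and 9 disjoint BMI-extreme
records, so the exclusion filters retain exactly 112. The two exclusion
groups are disjoint by construction because 129 − 8 − 9 = 112 only adds up
without overlap.

## Quality control

**Exclusions.** A record is excluded iff liver enzymes are elevated or
|BMI SDS| > 1.96. The two reasons are evaluated independently (a record can
carry both; marginal counts tally the enzyme reason first so they sum when
the reasons are disjoint).

**Semi-winsorization.** Outliers are replaced, not removed: values outside
median ± k·MAD (k = 2.5) are set to the nearest bound. The MAD is scaled by
1.4826 (normal-consistency), so the rule is roughly "beyond ±3.7 raw MADs";
a raw-MAD mode (`mad_constant=1.0`) is available for sensitivity analysis,
since published descriptions of the ±2.5 rule do not always state the
scaling. Winsorization is applied per outcome on the post-exclusion sample
(the order implied by audit counts quoted out of the analyzed n). Missing
values pass through untouched; a zero MAD on non-constant data degenerates
the bounds, so no replacement is performed and a warning is emitted.
Replacement preserves the sample median (at least half the sample lies
within one raw MAD of the median, so the central order statistics are never
touched) and is idempotent.

## Correlation battery and sensitivity

Pearson's r (t-transform p, n−2 df), point-biserial r (Pearson on the 0/1
coding; sign follows the coding), and Kendall's τ-b (tie-corrected; exact
enumeration p for n ≤ 8 without ties, tie-adjusted normal approximation
otherwise; used for coarsely-recorded variables such as wall thickness in
mm). Missing data: pairwise deletion, each pair reporting its own n. No
multiplicity correction — the battery is exploratory at p < .05.

Minimum detectable correlation uses the Fisher-z approximation
`r = tanh[(z₁₋α/₂ + z_power)/√(n−3)]`; at n = 85, power 80%, α = .05 this
gives 0.300. The formula is exposed rather than any particular power tool's
output (published sensitivity numbers for comparable sample sizes differ
slightly from the Fisher-z value; no attempt is made to reverse-engineer a
specific tool).

## Two-stage covariate selection

Stage 1: greedy forward selection of OLS covariates under AIC, one variable
at a time, stopping when no addition lowers AIC; ties break by declaration
order; candidates making the design rank-deficient are skipped with a
warning. k-fold CV prediction error (default k = 10) is computed for every
path prefix so subset sizes can be compared on held-out error.

Stage 2: for prefix size q, the test statistic is the RSS drop achieved by
the *best* single addition among the remaining candidates (identical to the
(q+1)-th path covariate). Its null distribution is built by residual
resampling: centered residuals of the size-q fit are resampled, y* rebuilt,
and the forward step redone on each resample, so the maximal character of
the statistic is present in the reference distribution — testing the
selected covariate against a fixed-covariate null would inflate the
per-step type-I error severalfold with ~9 candidates.
`p = (1 + #{T* ≥ T})/(B + 1)`, default B = 500. The chosen size is the
smallest q whose extension is non-significant at α = .05; cross-validation
is consulted and a disagreement (CV favoring a larger prefix) is logged but
does not override the bootstrap decision. Complete-case analysis per
outcome. This is a reimplementation of the two-stage idea, not a port of
any existing package. Linear models only; nonlinearity is the centile
stage's job.

## LMS centile estimation

The Box-Cox Cole–Green distribution for y > 0 given parameters (L, M, S):
`z = [(y/M)^L − 1]/(L·S)` (log branch for |L| < 1e-4) is standard normal;
the log-density is `log φ(z) − log(S·y) + L·log(y/M)`. The density is the
untruncated form, adequate for moderate skew (it integrates to 1 within
1e-8 at the parameter ranges charted here). Centile inversion
`M·(1 + L·S·z_α)^{1/L}` raises a domain error naming the offending α when
skew is strong enough that the base goes nonpositive.

**Curves and df semantics.** Each of L(x), M(x), S(x) is a cubic B-spline
(10 basis functions on an equally spaced knot grid over the observed
covariate range) with a second-order difference penalty. Links: identity
for L and M (the Cole–Green convention; M's positivity is guarded during
fitting by rejecting steps that drive it nonpositive), log for S.
Requested df d means: 0 → constant (1 parameter), 1 → straight line
(2 parameters, the penalty's null space), d ≥ 2 → penalized spline whose
smoother trace equals d + 1, calibrated by solving
Σ 1/(1 + λ·δᵢ) = d + 1 on the Demmler–Reinsch spectrum. Effective df for
BIC is the summed smoother trace (−2·loglik + log(n)·edf); whether one
counts trace or raw hyperparameters is a genuine convention choice, and
trace is used because it is the quantity the penalty actually controls.

**Fitting.** Cyclic penalized Fisher scoring (M, S, L in turn): analytic
score functions for M and S with expected-information weights
(`1/S² + 2L²` and 2 on their link scales), finite-difference observed
information for L, step-halving on the penalized log-likelihood, penalty
recalibrated every cycle. Start values: L ≡ 1, M ≡ sample median,
S ≡ scaled-MAD coefficient of variation. Convergence: penalized
log-likelihood change < 5e-7 (deviance 1e-6) or 200 cycles, else the model
returns flagged unconverged. Curve evaluation clips x to the fitted range;
tabulation and scoring refuse extrapolation unless explicitly allowed.

**Model choice.** `df_grid_search` fits every (df_L, df_M, df_S) in the
grid (default {0..5}³), excludes non-converged cells from the argmin,
breaks BIC ties toward smaller total df, and returns the full table.
`cross_validate_lms` reports mean held-out log-likelihood per observation
with seeded folds. Default chart centiles: 3, 10, 25, 50, 75, 90, 97.

## Pipeline

Stage order: exclusions → per-outcome winsorization → correlation matrix →
per-outcome selection → per-outcome (optionally sex-stratified) BIC grid
search and LMS fit → percentile tables and SVG charts. The chart covariate
is the first continuous covariate the selection stage retains (falling back
to the documented default per outcome: ATI–age, SWE–wall thickness,
SWD–BMI SDS); sex stratification happens when selection retains sex, or
when the config forces it. SWE in kPa reuses the m/s selection (the two are
a deterministic conversion apart). All stage randomness derives from the
single config seed. The manifest records config, input hash, version and
stage summaries; setting the `timestamp` config key to a fixed ISO string
(instead of the default `"now"`) makes reruns byte-identical, in the spirit
of `SOURCE_DATE_EPOCH` reproducible builds. Matplotlib's `svg.hashsalt` is
pinned so charts are byte-stable.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to make the tested property
overwhelmingly likely while keeping the suite quick: structural-recovery
and selection-recovery sweeps use 100 cohorts of n = 2000; bootstrap
type-I uses 500 replications at n = 120 with B = 199; LMS recovery,
coverage and calibration use n = 1000; the BIC model-selection consistency
sweep uses 50 seeds on a {0,1,2}³ df grid (the constant-vs-smooth contrast
that matters for consistency) at n = 1000.

## Known limitations

* The truncated-normal age model cannot reach the requested age SD (see
  above); the generated age distribution is slightly narrower than the
  emulated cohort's.
* The BCCG density is untruncated; for |L|·S large (strong skew with high
  CV) the normalization error grows and centile inversion can fail at
  extreme levels — both conditions are far outside the charted parameter
  ranges.
* One-covariate charts only (plus stratification); no multi-covariate LMS
  surfaces, and no four-parameter (kurtosis) extensions.
* The bootstrap q-test assumes exchangeable homoscedastic residuals; it is
  not robust to strong heteroscedasticity.
* Extrapolation beyond the observed covariate range is refused by default
  because spline behaviour there is unsupported by data.
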