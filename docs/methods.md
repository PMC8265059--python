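# Methods

## The estimation problem

Register-based case–control studies of drug effects observe prescription
*redemptions*, not drug *use*. For each subject we see the case/control
outcome `Y` at an index date, whether any redemption fell in the window of
length `δ` before that date (`V`), and, if so, the backward recurrence time
`R` from the last such redemption to the index date. Whether the subject was
actually exposed (in treatment) on the index date, `Z`, is latent: a recent
redemption usually means exposure, an old one usually means the treatment
episode has ended. Classifying exposure by a fixed decision rule ("exposed
iff a redemption within 90 days") misclassifies both ways and biases the
odds ratio.

`wtdcc` implements a joint maximum-likelihood model that treats `Z` as
latent and estimates the exposure–outcome odds ratio directly from
`(V, R, Y)`.

## Model

Redemptions of a continuing user follow a renewal process with
inter-arrival density (IAD) `f(t)`; intercepted at the index date, `R` then
follows the backward recurrence density (BRD)

    g(r) = (1 − F(r)) / M,        M = E(T),

with `F` the IAD cdf. The outcome follows
`P(Y=1|Z=z) = expit(β₀ + β₁ z)`, and `Y ⊥ (V,R) | Z`. Subjects decompose
into three types:

* **continuing users** (probability `p_v p_x`): `R ~ g`, exposed;
* **stoppers** (`p_v (1−p_x)`): the last redemption is uniform on the
  window (constant stopping rate); the subject is still exposed iff the
  final prescription's duration exceeds `r`, which has probability
  `1 − F(r)`;
* **non-redeemers** (`1 − p_v`): unexposed by assumption.

The likelihood contribution of a subject with `v = 1` is

    p_v p_x g(r) P(y|1) + p_v (1−p_x) (1/δ) [ F(r) P(y|0) + (1−F(r)) P(y|1) ],

and `(1−p_v) P(y|0)` for `v = 0`. `exp(β₁)` is the odds ratio of interest;
`(p_v, p_x, μ, σ)` are nuisance parameters estimated jointly, so the
uncertainty about latent exposure propagates into the standard error of
`log OR`.

The analysis BRD is log-normal: `F(r) = Φ((log r − μ)/σ)` and
`g(r) = Φ(−(log r − μ)/σ) / exp(μ + σ²/2)`. A Weibull IAD is provided for
generating misspecified data, moment-matched to a given log-normal (shape
from the coefficient-of-variation equation by 1-D root finding on the
log-gamma scale, scale from the mean).

### Optimization and inference

The likelihood is maximized over the unconstrained coordinates
`(logit p_v, logit p_x, β₀, β₁, μ, log σ)` with L-BFGS-B on the
mean log-likelihood. Warm starts come from an ordinary reverse-WTD mixture
fit (for `p_x, μ, σ`), the observed redemption fraction (`p_v`), and a
90-day fixed-window 2×2 table with Haldane correction (`β₀, β₁`); up to
five retries add seeded Gaussian jitter (sd 0.4) to the start. The mixture
log-likelihood is assembled in log space (log-sum-exp across the
continuer/stopper branches, `log_ndtr` for the normal tail) so far-tail
recurrence times do not underflow.

Standard errors come from the inverse of the observed information,
computed by central finite differences with absolute step `1e-5` on the
unconstrained scale; `se(log OR)` is read off the `β₁` diagonal entry and
Wald intervals are `exp(β̂₁ ± z·se)`. A fit is flagged non-converged when
the optimizer fails, the information matrix is singular, or the variance
estimate is non-positive; non-converged fits are never reported silently.

Any of `p_v, p_x, β₀, μ, σ` may depend on covariates through linear
predictors on the unconstrained scale (`covariate_spec`); `β₁` stays a
single coefficient (the target of estimation).

### Untruncated g on the window

The likelihood uses `g` exactly as written, without renormalizing it to
`(0, δ]`. At the default parameter values (`μ = log(1.5/12)`,
`σ = exp(−0.35)`, `δ = 1` year) about 0.2% of the BRD mass lies beyond the
window, so the model density sums to slightly less than 1; this is a
property of the published formulation that the package reproduces
deliberately. A warning is emitted when more than 1% of the fitted
duration mass lies beyond the window, where the approximation visibly
degrades. A corollary: on data generated with recurrence times truncated
to the window (as they must be, since exposed subjects have `v = 1`), the
nuisance parameters `μ, σ` acquire a small fixed offset that becomes
statistically visible at very large `n`, while the odds ratio is
unaffected at the precision studied here. The exact parameter-recovery
test therefore uses `σ = 0.45`, where the window captures the duration
tail (mass beyond `δ` ≈ 1e-5) and generator and model coincide.

## Reference analyses

* `true_expo` — logistic regression on the latent truth (simulation
  benchmark; defines VIF = 1).
* `wtd_prob` — two-step method: fit the reverse-WTD mixture
  `p·g(r) + (1−p)/δ` on controls with a window redemption; use the
  predicted *still-treated* probability `1 − F̂(r)` (0 for non-redeemers)
  as the exposure covariate in a logistic regression. The fully Bayesian
  posterior `[p g + (1−p)(1/δ)(1−F)] / [p g + (1−p)(1/δ)]` is available
  via `prob_kind="posterior"`; it is close to unbiased in simulation and
  is therefore *not* what the published two-step approach computes — the
  still-treated probability reproduces the published standard errors and
  variance inflation of that approach.
* `window_90` / `window_30` — exposed iff `v = 1` and `r < w/365.25`
  (strict `<` at day resolution: "within w days" reads exclusively; at
  the generator's continuous resolution the boundary has measure zero but
  the convention is fixed for reproducibility on day-resolved data). By
  default all subjects are retained (comparable standard errors across
  methods); `keep_all=False` drops subjects whose only redemption lies
  outside the window, the convention of applied analyses.

All logistic regressions are ML fits (statsmodels, Newton/IRLS) with
inverse-Fisher covariance.

## Synthetic cohorts

The generator draws from exactly the joint density the model describes,
so that estimator calibration can be measured against a known truth.

1. Case/control status is assigned with an exact ratio (1:1 or 1:10), as
   in a designed sample.
2. The marginal exposure prevalence implied by `(p_v, p_x)` and the BRD is
   `p_Z = p_v (p_x + (1−p_x) q)` with `q = (1/δ)∫₀^δ (1−F)`, the exposed
   fraction among stoppers. Exposure probabilities for cases and controls
   `(p₁, p₀)` are then solved from `odds(p₁)/odds(p₀) = OR` and
   `cf·p₁ + (1−cf)·p₀ = p_Z` (cf = case fraction) by bracketed root
   finding on `logit p₀`; both constraints hold to 1e-10.
3. Exposed subjects are continuers with probability
   `p_x / (p_x + (1−p_x) q)`; continuers draw `r` from the BRD truncated
   to the window by inverse-cdf sampling (the BRD cdf has the closed form
   `M·G(r) = r(1−F(r)) + E[T; T≤r]`, evaluated on a dense grid). Exposed
   stoppers draw `r` by rejection: uniform proposals accepted with
   probability `1−F(r)`. Unexposed subjects carry a redemption with
   probability `p_v (1−p_x)(1−q)/(1−p_Z)` and draw `r` accepted with
   probability `F(r)`. Mixing the two stopper streams in proportion
   `q : 1−q` makes the pooled stopper marginal exactly uniform, which is
   verified by a Kolmogorov–Smirnov test.
4. `(v, x, r)` are drawn conditionally on `z` only, matching the model's
   conditional-independence assumption.

What the generator deliberately does **not** emulate: covariate-dependent
redemption behaviour, longitudinal prescription histories (only the last
pre-index redemption matters to every method here), matched-set sampling
(matching is ignored in the analysis, as in the study design), or
departures from the renewal/uniform-stopping model. Passing simulation
tests therefore demonstrates internal calibration under the model and
moderate BRD misspecification (Weibull vs log-normal), not robustness to
real-world exposure dynamics.

## Performance harness

Per scenario the harness simulates `n_reps` cohorts (replicate `k` uses
seed `base_seed + k`, so runs extend without recomputation) and reports per
method the median relative bias of the OR, the median `se(log OR)`,
the coverage of nominal 95% intervals, and the variance inflation factor
`(median se / median se_true_expo)²`. Medians are used throughout; metrics
are computed over converged replicates and the convergence count is
reported alongside, keeping the exclusion auditable.

Problem sizes: the bundled acceptance study (`scripts/acceptance.py`) runs
the eight study settings at the full cohort size `n = 39,600` with 150
replicates per scenario (and the eight Weibull variants likewise); the
test suite uses 150 replicates for the base setting, 60 per grid scenario
and 30 for the variant settings. At these counts the Monte-Carlo standard
error is ≈0.3 pp for median bias and ≈1.8–2.8 pp for coverage, matching
the acceptance tolerances (±1.5 pp bias, ±2 pp coverage, ±0.1 VIF).

## Numerical choices and conventions

* Time unit: years; a year is 365.25 days everywhere; `δ` defaults to 1.
* A redemption on the index date (`r = 0`, day-resolved data) is remapped
  to half a day rather than rejected.
* Φ is evaluated through `scipy.special.ndtr` / `log_ndtr` (erfc-based),
  stable in the far tail; tests cross-check against an independent
  `math.erfc` transcription.
* `brentq` tolerances for the exposure split and Weibull moment match are
  set near machine precision; the moment match is verified to 1e-10.
* Degenerate inputs fail loudly: cohorts without both `v` classes or both
  outcomes are rejected (the `p_v` boundary is unidentifiable), pure-
  continuer rWTD data flag a boundary estimate, perfect separation in a
  logistic fit raises.
* The two-step rWTD is fitted on controls only (predictions for everyone);
  fitting on all subjects is exposed as an option since the study's
  simulation description leaves it open.

## Known limitations

* Only log-normal (analysis) and Weibull (generation) IAD families; no
  Gamma or spline BRDs, no non-parametric WTD estimation.
* No conditional (matched-set) likelihood; matching variables must enter
  as covariates.
* Exposure is a binary index-date status; time-since-initiation or dose
  metrics are out of scope.
* The two-step method's published bias is reproduced in direction and
  approximate size, but its 1:1-matched settings run ~3 pp above the
  published figures here (see the still-treated-probability note above);
  standard errors, coverage and VIF match closely.
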