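# wtdcc

Joint likelihood estimation of exposure–outcome odds ratios in
pharmacoepidemiologic case–control studies where drug exposure is latent
and only prescription redemptions are observed.

## The problem

Register-based case–control studies see *redemptions*, not *use*: for each
subject there is an outcome `Y` (case/control) at an index date, an
indicator `V` of any redemption within a window of length `δ` (default one
year) before that date, and — when `V = 1` — the time `R` from the last
such redemption back to the index date. Whether the subject was actually
in treatment on the index date (`Z`) is unobserved. The usual fix, a fixed
exposure window ("exposed iff a redemption within 90 days"), misclassifies
both ways and biases the estimated odds ratio; using an estimated exposure
*probability* as covariate is biased too.

`wtdcc` models `Z` as latent. Continuing users' recurrence times follow
the backward recurrence density `g(r) = (1 − F(r))/M` of the prescription
inter-arrival distribution `F` (log-normal, mean `M`); stoppers redeem
uniformly on the window and remain exposed with probability `1 − F(r)`;
non-redeemers are unexposed; and `P(Y=1|Z=z) = expit(β₀ + β₁ z)`. The
per-subject likelihood for `v = 1`,

    p_v p_x g(r) P(y|1) + p_v (1−p_x) (1/δ) [F(r) P(y|0) + (1−F(r)) P(y|1)],

and `(1−p_v) P(y|0)` for `v = 0`, is maximized jointly over
`(p_v, p_x, β₀, β₁, μ, σ)`, so `exp(β̂₁)` estimates the odds ratio with
the exposure uncertainty propagated into its standard error. Any parameter
except `β₁` can depend on covariates. See `docs/methods.md` for the full
model, numerical choices and limitations.

The package also ships the comparison analyses (true-exposure benchmark,
the two-step rWTD exposure-probability method, 30/90-day fixed windows), a
synthetic-cohort generator drawing from exactly the model's joint density,
and a Monte-Carlo harness reporting median relative bias, median
`se(log OR)`, 95%-CI coverage and variance inflation factors.

## Worked example

```python
import numpy as np
from wtdcc import BrdParams, JointWtdModel, Scenario, simulate_dataset, estimate_or

brd = BrdParams("lognormal", mu=float(np.log(1.5 / 12)), sigma=float(np.exp(-0.35)))
scenario = Scenario(n_total=39_600, controls_per_case=1, or_true=3.0,
                    pv=0.25, px=0.8, brd=brd)
cohort = simulate_dataset(scenario, seed=1)

model = JointWtdModel(delta=1.0, seed=1).fit(cohort[["v", "r"]], cohort["y"])
print(f"joint model: OR = {model.or_:.3f} "
      f"(95% CI {model.or_ci_[0]:.3f}-{model.or_ci_[1]:.3f}), "
      f"se(log OR) = {model.se_log_or_:.4f}")

for method in ("true_expo", "wtd_prob", "window_90", "window_30"):
    est = estimate_or(method, cohort, seed=1)
    print(f"{method:10s} OR = {est.or_hat:.3f} (95% CI {est.ci_95[0]:.3f}-{est.ci_95[1]:.3f})")
```

prints

```
joint model: OR = 3.081 (95% CI 2.912-3.259), se(log OR) = 0.0287
true_expo  OR = 3.096 (95% CI 2.937-3.263)
wtd_prob   OR = 3.605 (95% CI 3.353-3.876)
window_90  OR = 2.817 (95% CI 2.667-2.975)
window_30  OR = 2.586 (95% CI 2.407-2.779)
```

The cohort was generated with a true odds ratio of 3, a quarter of
subjects redeeming within the year and 80% of redeemers continuing
treatment. The joint model (3.08) sits on top of the unattainable
true-exposure benchmark (3.10) with only a slightly wider interval; the
two-step probability method overshoots (+20%) and the fixed windows
undershoot (−6% and −14%), their intervals excluding the truth — the
misclassification biases the model is designed to remove.

A command-line interface mirrors the library
(`wtdcc simulate | fit-joint | fit-rwtd | estimate | simstudy`; see
`wtdcc --help`); cohorts are plain CSV with columns `y, v, r` (years, or
days via `--r-unit days`, or derived from dates via `--mode dates`), and
scenarios are YAML.

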