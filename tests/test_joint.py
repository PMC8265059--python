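"""Joint likelihood: contribution algebra, fitting, posterior probabilities."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special

from wtdcc.brd import BrdParams
from wtdcc.datagen import Scenario, simulate_dataset
from wtdcc.joint import (
    FitResult,
    JointParams,
    JointWtdModel,
    fit_joint,
    individual_loglik,
    logistic_prob,
    posterior_exposure_prob,
    total_loglik,
    wald_ci_or,
)
from tests.conftest import BASE_MU


def phi_erfc(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


def transcription_oracle(rec, p, delta):
    """One-line transcription of the printed likelihood contribution with an
    independent (erfc-based) normal cdf; deliberately naive."""
    y, v = rec["y"], rec["v"]
    e0 = math.exp(p.beta0)
    e1 = math.exp(p.beta0 + p.beta1)
    py0 = e0**y / (1 + e0)
    py1 = e1**y / (1 + e1)
    if v == 0:
        return math.log((1 - p.pv) * py0)
    r = rec["r"]
    mu, sig = p.brd.mu, p.brd.sigma
    g = phi_erfc(-(math.log(r) - mu) / sig) / math.exp(mu + 0.5 * sig**2)
    F = phi_erfc((math.log(r) - mu) / sig)
    lik = p.px * p.pv * g * py1 + (1 - p.px) * p.pv * (1 / delta) * (py0 * F + py1 * (1 - F))
    return math.log(lik)


def random_joint_params(rng):
    return JointParams(
        pv=rng.uniform(0.05, 0.9),
        px=rng.uniform(0.1, 0.95),
        beta0=rng.uniform(-2, 1),
        beta1=rng.uniform(-1, 2),
        brd=BrdParams("lognormal", mu=rng.uniform(-3, 0), sigma=rng.uniform(0.3, 1.2)),
    )


def random_record(rng, delta):
    v = int(rng.random() < 0.6)
    return {
        "y": int(rng.random() < 0.5),
        "v": v,
        "r": float(rng.uniform(1e-3, delta)) if v else np.nan,
    }


class TestLogisticProb:
    def test_baseline(self):
        assert logistic_prob(0, 0.0, 1.0) == pytest.approx(0.5)

    def test_odds_three(self):
        assert logistic_prob(1, 0.0, math.log(3)) == pytest.approx(0.75)

    def test_or_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            b0, b1 = rng.normal(size=2)
            p1, p0 = logistic_prob(1, b0, b1), logistic_prob(0, b0, b1)
            odds_ratio = (p1 / (1 - p1)) / (p0 / (1 - p0))
            assert odds_ratio == pytest.approx(math.exp(b1), rel=1e-10)


class TestIndividualLoglik:
    def test_no_redemption_direct_substitution(self, base_brd):
        p = JointParams(pv=0.25, px=0.8, beta0=0.0, beta1=1.0, brd=base_brd)
        got = individual_loglik({"y": 0, "v": 0, "r": np.nan}, p, delta=1.0)
        assert got == pytest.approx(math.log(0.75 * 0.5), rel=1e-14)

    def test_matches_transcription_oracle(self):
        rng = np.random.default_rng(12)
        delta = 1.0
        for _ in range(50):
            p = random_joint_params(rng)
            rec = random_record(rng, delta)
            got = individual_loglik(rec, p, delta)
            want = transcription_oracle(rec, p, delta)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_null_effect_factorizes(self, base_brd):
        """With beta1 = 0 the outcome is independent of (v, r): the
        contribution minus log P(Y=y) must not depend on y."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = JointParams(
                pv=rng.uniform(0.1, 0.9),
                px=rng.uniform(0.1, 0.9),
                beta0=rng.normal(),
                beta1=0.0,
                brd=base_brd,
            )
            rec = random_record(rng, 1.0)
            parts = {}
            for y in (0, 1):
                log_py = y * p.beta0 - math.log1p(math.exp(p.beta0))
                parts[y] = individual_loglik({**rec, "y": y}, p, 1.0) - log_py
            assert parts[0] == pytest.approx(parts[1], rel=1e-12)

    def test_out_of_window_r_rejected(self, base_brd):
        p = JointParams(pv=0.2, px=0.8, beta0=0.0, beta1=1.0, brd=base_brd)
        with pytest.raises(ValueError):
            individual_loglik({"y": 0, "v": 1, "r": 1.5}, p, delta=1.0)


class TestTotalLoglik:
    @pytest.fixture()
    def small_cohort(self, base_brd):
        rng = np.random.default_rng(3)
        return pd.DataFrame([random_record(rng, 1.0) for _ in range(40)])

    @pytest.fixture()
    def params(self, base_brd):
        return JointParams(pv=0.3, px=0.7, beta0=-0.2, beta1=1.0, brd=base_brd)

    def test_single_record_equals_individual(self, params, small_cohort):
        one = small_cohort.iloc[[0]]
        assert total_loglik(one, params) == pytest.approx(
            individual_loglik(small_cohort.iloc[0], params), rel=1e-14
        )

    def test_additive_over_concatenation(self, params, small_cohort):
        a, b = small_cohort.iloc[:15], small_cohort.iloc[15:]
        assert total_loglik(small_cohort, params) == pytest.approx(
            total_loglik(a, params) + total_loglik(b, params), rel=1e-12
        )

    def test_permutation_invariant(self, params, small_cohort):
        shuffled = small_cohort.sample(frac=1.0, random_state=9)
        assert total_loglik(shuffled, params) == pytest.approx(
            total_loglik(small_cohort, params), rel=1e-12
        )

    def test_invalid_record_named(self, params, small_cohort):
        bad = small_cohort.copy()
        bad.loc[7, ["v", "r"]] = (1, 2.5)
        with pytest.raises(ValueError, match="7"):
            total_loglik(bad, params)


class TestNormalization:
    def test_density_sums_to_one_when_window_captures_tail(self):
        """With essentially no duration mass beyond delta, summing the model
        density over y and integrating r over the window must give 1."""
        brd = BrdParams("lognormal", mu=BASE_MU, sigma=0.3)
        p = JointParams(pv=0.3, px=0.7, beta0=-0.4, beta1=0.8, brd=brd)
        delta = 1.0
        total = 0.0
        for y in (0, 1):
            total += math.exp(individual_loglik({"y": y, "v": 0, "r": np.nan}, p, delta))
            val, _ = integrate.quad(
                lambda r: math.exp(individual_loglik({"y": y, "v": 1, "r": r}, p, delta)),
                1e-12,
                delta,
                limit=200,
            )
            total += val
        assert total == pytest.approx(1.0, abs=1e-5)


class TestPosterior:
    def test_all_continuers_always_exposed(self, base_brd):
        p = JointParams(pv=0.25, px=1 - 1e-12, beta0=0.0, beta1=1.0, brd=base_brd)
        assert posterior_exposure_prob({"y": 0, "v": 1, "r": 0.9}, p) == pytest.approx(1.0)

    def test_recent_redemption_certainly_exposed(self, base_brd):
        p = JointParams(pv=0.25, px=0.5, beta0=0.0, beta1=1.0, brd=base_brd)
        assert posterior_exposure_prob({"y": 0, "v": 1, "r": 1e-9}, p) == pytest.approx(1.0, abs=1e-6)

    def test_no_redemption_unexposed(self, base_brd):
        p = JointParams(pv=0.25, px=0.5, beta0=0.0, beta1=1.0, brd=base_brd)
        assert posterior_exposure_prob({"y": 1, "v": 0, "r": np.nan}, p) == 0.0

    def test_monotone_and_algebraic_rearrangement(self):
        rng = np.random.default_rng(21)
        grid = np.linspace(1e-3, 1.0, 50)
        for _ in range(10):
            p = random_joint_params(rng)
            df = pd.DataFrame({"y": 0, "v": 1, "r": grid})
            post = posterior_exposure_prob(df, p, delta=1.0)
            assert np.all(post >= 0) and np.all(post <= 1)
            assert np.all(np.diff(post) <= 1e-12)
            # algebra: post = 1 - (1-px)(1/delta) F / [px g + (1-px)/delta]
            from wtdcc.brd import brd_pdf, iad_cdf

            g = brd_pdf(grid, p.brd)
            F = iad_cdf(grid, p.brd)
            alt = 1.0 - (1 - p.px) * F / (p.px * g + (1 - p.px))
            np.testing.assert_allclose(post, alt, rtol=1e-8, atol=1e-12)


class TestFit:
    def test_parameter_recovery_large_sample(self):
        # sigma chosen so the one-year window captures the duration tail
        # (mass beyond delta ~1e-5): generator and analysis model then
        # coincide and every parameter must be recovered
        brd = BrdParams("lognormal", mu=BASE_MU, sigma=0.45)
        scn = Scenario(200_000, 1, 3.0, 0.25, 0.8, brd)
        df = simulate_dataset(scn, seed=17)
        model = JointWtdModel(seed=17).fit(df, df["y"].to_numpy())
        assert model.converged_
        est = model.params_
        # truth on the unconstrained scale, matching theta_/vcov_ layout;
        # beta0 is the design intercept logit P(Y=1 | Z=0) of this sample
        from wtdcc.datagen import case_control_exposure_probs, exposure_prevalence

        p_z = exposure_prevalence(0.25, 0.8, brd, 1.0)
        p0, p1 = case_control_exposure_probs(p_z, 3.0, 0.5)
        pr_y1_z0 = 0.5 * (1 - p1) / (0.5 * (1 - p1) + 0.5 * (1 - p0))
        truth = np.array(
            [
                special.logit(0.25),
                special.logit(0.8),
                special.logit(pr_y1_z0),
                math.log(3.0),
                BASE_MU,
                math.log(0.45),
            ]
        )
        se = np.sqrt(np.diag(model.vcov_))
        assert np.all(np.abs(model.theta_ - truth) < 3 * se)

    def test_same_optimum_from_different_inits(self, base_brd):
        scn = Scenario(10_000, 1, 3.0, 0.25, 0.8, base_brd)
        df = simulate_dataset(scn, seed=4)
        y = df["y"].to_numpy()
        fit1 = JointWtdModel(seed=1).fit(df, y)
        alt = JointParams(pv=0.5, px=0.5, beta0=0.5, beta1=0.0, brd=BrdParams("lognormal", mu=-1.0, sigma=1.0))
        fit2 = JointWtdModel(seed=2, init=alt).fit(df, y)
        assert fit1.loglik_ == pytest.approx(fit2.loglik_, abs=1e-6)
        assert fit1.or_ == pytest.approx(fit2.or_, rel=1e-4)

    def test_all_redeemers_is_unidentifiable(self, base_brd):
        df = pd.DataFrame({"y": [0, 1] * 20, "v": 1, "r": np.linspace(0.01, 0.9, 40)})
        with pytest.raises(ValueError, match="identifiability|boundary"):
            JointWtdModel().fit(df, df["y"].to_numpy())

    def test_single_outcome_class_rejected(self, base_brd):
        df = pd.DataFrame({"y": 0, "v": [0, 1] * 20, "r": [np.nan, 0.3] * 20})
        with pytest.raises(ValueError):
            JointWtdModel().fit(df, df["y"].to_numpy())

    def test_fit_joint_wrapper_consistent_with_estimator(self, base_brd):
        scn = Scenario(8_000, 1, 3.0, 0.25, 0.8, base_brd)
        df = simulate_dataset(scn, seed=6)
        res = fit_joint(df, delta=1.0, seed=6)
        assert isinstance(res, FitResult)
        model = JointWtdModel(delta=1.0, seed=6).fit(df, df["y"].to_numpy())
        assert res.loglik == pytest.approx(model.loglik_, abs=1e-6)
        assert res.or_ci_95 == pytest.approx(wald_ci_or(res, 0.95))

    def test_noise_covariate_has_null_effect(self, base_brd):
        scn = Scenario(20_000, 1, 3.0, 0.25, 0.8, base_brd)
        df = simulate_dataset(scn, seed=8)
        df["age"] = np.random.default_rng(8).normal(size=len(df))
        m = JointWtdModel(covariate_spec={"beta0": ["age"]}, seed=8).fit(df, df["y"].to_numpy())
        assert m.converged_
        coef = m.theta_[-1]
        se = math.sqrt(m.vcov_[-1, -1])
        assert abs(coef) < 3 * se
        assert m.param_names_[-1] == "beta0:age"


class TestWaldCi:
    def _result(self, beta1, se, converged=True):
        brd = BrdParams("lognormal", mu=-2.0, sigma=0.7)
        est = JointParams(pv=0.2, px=0.8, beta0=0.0, beta1=beta1, brd=brd)
        return FitResult(
            estimates=est,
            vcov=np.eye(6),
            loglik=0.0,
            converged=converged,
            n_obs=10,
            se_log_or=se,
            or_ci_95=(0.0, 0.0),
        )

    def test_degenerate_zero_se(self):
        lo, hi = wald_ci_or(self._result(math.log(3), 0.0))
        assert lo == hi == pytest.approx(3.0)

    def test_log_scale_agrees_with_direct(self):
        fit = self._result(math.log(3), 0.038)
        lo, hi = wald_ci_or(fit, level=0.95)
        zc = 1.959963984540054
        assert lo == pytest.approx(3.0 * math.exp(-zc * 0.038), rel=1e-12)
        assert hi == pytest.approx(3.0 * math.exp(zc * 0.038), rel=1e-12)

    def test_wider_level_nests(self):
        fit = self._result(math.log(3), 0.05)
        lo95, hi95 = wald_ci_or(fit, 0.95)
        lo99, hi99 = wald_ci_or(fit, 0.99)
        assert lo99 < lo95 < hi95 < hi99

    def test_nonconverged_rejected(self):
        with pytest.raises(ValueError):
            wald_ci_or(self._result(1.0, 0.1, converged=False))
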