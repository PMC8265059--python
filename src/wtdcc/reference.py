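"""Comparison analyses for the latent-exposure case-control problem.

Four reference approaches accompany the joint likelihood model:

* ``true_expo`` — logistic regression on the actually assigned (latent)
  exposure; only possible on simulated data, where it is the benchmark with
  no misclassification.
* ``wtd_prob`` — the two-step method: fit an ordinary reverse waiting-time
  distribution (rWTD) mixture to the observed backward recurrence times,
  predict each subject's probability of being exposed on the index date,
  and use that probability as the exposure covariate in logistic regression.
  The predicted probability is the *still-treated* probability
  ``1 - F_hat(r)`` — the chance that the duration of the last dispensed
  prescription outlasts the observed time ``r`` back to the index date —
  with 0 for subjects without a window redemption; the fully Bayesian
  posterior P(Z=1 | v, r) is available as an alternative
  (``prob_kind="posterior"``).
* ``window_90`` / ``window_30`` — classify a subject exposed iff a
  redemption fell within 90 (30) days before the index date, then run
  logistic regression on the binary classification.

The rWTD mixture treats the observed time ``r`` since the last redemption
as coming from a continuing user with probability ``p`` (density ``g``, the
backward recurrence density) and from a treatment stopper with probability
``1 - p`` (uniform on the window):  ``p g(r) + (1 - p)/delta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._optim import ParamLayout, hessian_cfd
from .brd import BrdParams, iad_cdf, log_brd_pdf
from .io import DAYS_PER_YEAR, validate_cohort

__all__ = [
    "RwtdParams",
    "OrEstimate",
    "ReverseWtdMixture",
    "FixedWindowExposure",
    "fit_rwtd",
    "rwtd_exposure_probability",
    "still_treated_probability",
    "logistic_fit",
    "fixed_window_exposure",
    "estimate_or",
    "METHODS",
]

METHODS = ("true_expo", "cc_wtd", "wtd_prob", "window_90", "window_30")

_BOUNDARY_LOGIT = 8.0  # |logit p| beyond this flags a boundary estimate


@dataclass(frozen=True)
class RwtdParams:
    """Ordinary reverse-WTD mixture: continuation probability and BRD."""

    p: float
    brd: BrdParams

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must lie strictly between 0 and 1")


@dataclass(frozen=True)
class OrEstimate:
    """An odds-ratio estimate with Wald inference on the log scale."""

    method: str
    or_hat: float
    se_log_or: float
    ci_95: tuple[float, float]
    n_used: int
    converged: bool = True


def _softplus(x):
    return np.logaddexp(0.0, x)


class ReverseWtdMixture(BaseEstimator, TransformerMixin):
    """Reverse waiting-time distribution mixture, fitted by maximum likelihood.

    Maximizes ``sum log[p g(r) + (1 - p)/delta]`` over the unconstrained
    coordinates (logit p, mu, log sigma) for the log-normal BRD ``g``.
    Covariates may enter any of the three coordinates through
    ``covariate_spec`` (``{"p": [...], "mu": [...], "sigma": [...]}``).

    Parameters
    ----------
    delta : float
        Observation-window length in years.
    controls_only : bool
        Fit on controls (y = 0) only, the convention of the two-step method;
        predictions are still made for everyone.
    probability : {"still_treated", "posterior"}
        What ``transform``/``exposure_probability`` predict: the
        still-treated probability ``1 - F(r)`` (the two-step method's
        covariate) or the posterior P(Z=1 | v, r) under the mixture.
    covariate_spec : dict or None
    seed : int or None
        Seeds the jitter used when an optimization attempt fails.
    max_retries : int

    Attributes
    ----------
    p_, brd_ : mixture parameters at the optimum (covariate-free part)
    rwtd_ : RwtdParams
    theta_, vcov_ : unconstrained coordinates and their covariance
    loglik_, converged_, boundary_, n_obs_
    """

    _BASE = ("p", "mu", "sigma")

    def __init__(
        self,
        delta=1.0,
        controls_only=True,
        probability="still_treated",
        covariate_spec=None,
        seed=None,
        max_retries=5,
    ):
        self.delta = delta
        self.controls_only = controls_only
        self.probability = probability
        self.covariate_spec = covariate_spec
        self.seed = seed
        self.max_retries = max_retries

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        df = validate_cohort(X, delta=self.delta)
        mask = df["v"].to_numpy() == 1
        if y is not None and self.controls_only:
            mask &= np.asarray(y).astype(int) == 0
        if not mask.any():
            raise ValueError("no usable subjects with v=1 to fit the rWTD on")
        sub = df.loc[mask]
        r = sub["r"].to_numpy(dtype=float)
        layout = ParamLayout(self._BASE, self.covariate_spec)
        design = layout.design(sub)
        log_r = np.log(r)
        m = r.size
        log_delta = np.log(self.delta)

        def nll(theta):
            lp = layout.resolve(theta, "p", design)
            mu = layout.resolve(theta, "mu", design)
            sigma = np.exp(layout.resolve(theta, "sigma", design))
            z = (log_r - mu) / sigma
            log_g = special.log_ndtr(-z) - (mu + 0.5 * sigma**2)
            a = -_softplus(-lp) + log_g
            b = -_softplus(lp) - log_delta
            val = -np.sum(np.logaddexp(a, b)) / m
            return val if np.isfinite(val) else np.inf

        x0 = layout.pack(
            {
                "p": special.logit(0.7),
                "mu": float(np.log(np.median(r))),
                "sigma": np.log(0.8),
            }
        )
        theta, res, ok = _minimize_with_retries(nll, x0, self.seed, self.max_retries)
        vcov, se_ok = _vcov_from_hessian(nll, theta, m)

        self.layout_ = layout
        self.theta_ = theta
        self.vcov_ = vcov
        self.loglik_ = -res.fun * m
        self.p_ = float(special.expit(theta[0]))
        self.brd_ = BrdParams("lognormal", mu=float(theta[1]), sigma=float(np.exp(theta[2])))
        self.rwtd_ = RwtdParams(p=float(np.clip(self.p_, 1e-12, 1.0 - 1e-12)), brd=self.brd_)
        self.boundary_ = bool(abs(theta[0]) > _BOUNDARY_LOGIT)
        self.converged_ = bool(ok and se_ok and not self.boundary_)
        self.n_obs_ = int(m)
        return self

    def exposure_probability(self, X) -> np.ndarray:
        """Exposure probability on the index date; 0 for v=0 (see
        ``probability`` for the two available definitions)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "theta_")
        if self.probability not in ("still_treated", "posterior"):
            raise ValueError(f"unknown probability kind {self.probability!r}")
        df = validate_cohort(pd.DataFrame(X), delta=self.delta)
        v = df["v"].to_numpy()
        out = np.zeros(len(df))
        if (v == 1).any():
            sub = df.loc[v == 1]
            design = self.layout_.design(sub)
            mu = self.layout_.resolve(self.theta_, "mu", design)
            sigma = np.exp(self.layout_.resolve(self.theta_, "sigma", design))
            r = sub["r"].to_numpy(dtype=float)
            if self.probability == "still_treated":
                out[v == 1] = special.ndtr(-(np.log(r) - mu) / sigma)
            else:
                lp = self.layout_.resolve(self.theta_, "p", design)
                out[v == 1] = _mixture_exposure_prob(
                    r, special.expit(lp), (mu, sigma), self.delta
                )
        return out

    def transform(self, X) -> np.ndarray:
        return self.exposure_probability(X)[:, None]


def _mixture_exposure_prob(r, p, brd, delta):
    """Shared kernel: [p g + (1-p)(1/delta)(1-F)] / [p g + (1-p)(1/delta)].

    ``brd`` is either a BrdParams or a (mu, sigma) tuple of per-record
    log-normal parameters.
    """
    if isinstance(brd, BrdParams):
        log_g = log_brd_pdf(r, brd)
        F = iad_cdf(r, brd)
    else:
        mu, sigma = brd
        z = (np.log(r) - mu) / sigma
        log_g = special.log_ndtr(-z) - (mu + 0.5 * sigma**2)
        F = special.ndtr(z)
    g = np.exp(log_g)
    num = p * g + (1.0 - p) * (1.0 - F) / delta
    den = p * g + (1.0 - p) / delta
    return num / den


def _minimize_with_retries(nll, x0, seed, max_retries, jitter=0.4):
    """L-BFGS-B with seeded jittered restarts; returns (theta, result, ok)."""
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max_retries + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(0.0, jitter, size=x0.size)
        res = optimize.minimize(
            nll,
            start,
            method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-7},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        if res.success and np.isfinite(res.fun):
            break
    if best is None:
        best = res
    ok = bool(best.success and np.isfinite(best.fun) and np.all(np.isfinite(best.x)))
    return best.x, best, ok


def _vcov_from_hessian(nll_scaled, theta, m, step=1e-5):
    """Invert the observed information m * H(scaled nll); (vcov, ok)."""
    H = hessian_cfd(nll_scaled, theta, step=step) * m
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((theta.size, theta.size), np.nan), False
    diag = np.diag(vcov)
    return vcov, bool(np.all(np.isfinite(vcov)) and np.all(diag > 0))


def fit_rwtd(times, delta=1.0, covariate_spec=None, seed=None):
    """Fit the rWTD mixture to backward recurrence times directly.

    ``times`` are the r-values of subjects with v = 1.  Returns the fitted
    :class:`ReverseWtdMixture` (with ``rwtd_``, ``vcov_``, ``converged_``).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("no observations")
    X = pd.DataFrame({"y": 0, "v": 1, "r": times})
    est = ReverseWtdMixture(delta=delta, controls_only=False, covariate_spec=covariate_spec, seed=seed)
    return est.fit(X)


def still_treated_probability(rec, brd, delta=1.0):
    """``1 - F(r)`` — probability the last prescription's duration outlasts
    the observed recurrence time; 0 for subjects without a window
    redemption.  The two-step method's exposure covariate."""
    df = rec if isinstance(rec, pd.DataFrame) else pd.DataFrame([dict(rec)])
    df = validate_cohort(df, delta=delta)
    v = df["v"].to_numpy()
    out = np.zeros(len(df))
    if (v == 1).any():
        from .brd import iad_sf

        out[v == 1] = iad_sf(df.loc[v == 1, "r"].to_numpy(dtype=float), brd)
    return out if isinstance(rec, pd.DataFrame) else float(out[0])


def rwtd_exposure_probability(rec, rwtd: RwtdParams, delta=1.0):
    """Posterior exposure probability for one record (or a cohort frame)
    given rWTD parameters: the mixture formula with the continuation
    probability ``p`` in place of the joint model's ``px``; subjects
    without a window redemption are unexposed (0)."""
    df = rec if isinstance(rec, pd.DataFrame) else pd.DataFrame([dict(rec)])
    df = validate_cohort(df, delta=delta)
    v = df["v"].to_numpy()
    out = np.zeros(len(df))
    if (v == 1).any():
        r = df.loc[v == 1, "r"].to_numpy(dtype=float)
        out[v == 1] = _mixture_exposure_prob(r, rwtd.p, rwtd.brd, delta)
    return out if isinstance(rec, pd.DataFrame) else float(out[0])


def logistic_fit(y, x, add_constant=True):
    """ML logistic regression (IRLS/Newton); returns (coefs, vcov).

    ``x`` is a 1-D covariate or 2-D design; an intercept is prepended unless
    ``add_constant=False``.  Raises on perfect separation or a singular
    information matrix.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_constant:
        X = np.column_stack([np.ones(len(y)), X])
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ) as err:
            raise ValueError(f"logistic regression failed: {err}") from err
    return np.asarray(res.params), np.asarray(res.cov_params())


class FixedWindowExposure(BaseEstimator, TransformerMixin):
    """Binary exposure classifier: exposed iff a redemption fell strictly
    within ``window_days`` days before the index date."""

    def __init__(self, window_days=90, delta=1.0):
        self.window_days = window_days
        self.delta = delta

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        df = validate_cohort(pd.DataFrame(X), delta=self.delta)
        return fixed_window_exposure(df, self.window_days)[:, None]


def fixed_window_exposure(rec, window_days):
    """1 iff v = 1 and r < window_days/365.25 years (strict '<' at day
    resolution, reading 'within N days' exclusively)."""
    df = rec if isinstance(rec, pd.DataFrame) else pd.DataFrame([dict(rec)])
    v = df["v"].to_numpy()
    r = pd.to_numeric(df["r"], errors="coerce").to_numpy(dtype=float)
    out = ((v == 1) & (r < window_days / DAYS_PER_YEAR)).astype(int)
    return out if isinstance(rec, pd.DataFrame) else int(out[0])


def _or_from_logistic(method, y, x, n_used) -> OrEstimate:
    coefs, vcov = logistic_fit(y, x)
    beta = float(coefs[1])
    se = float(np.sqrt(vcov[1, 1]))
    zc = stats.norm.ppf(0.975)
    return OrEstimate(
        method=method,
        or_hat=float(np.exp(beta)),
        se_log_or=se,
        ci_95=(float(np.exp(beta - zc * se)), float(np.exp(beta + zc * se))),
        n_used=int(n_used),
    )


def estimate_or(
    method: str,
    data: pd.DataFrame,
    delta: float = 1.0,
    *,
    keep_all: bool = True,
    seed=None,
    rwtd_controls_only: bool = True,
    prob_kind: str = "still_treated",
) -> OrEstimate:
    """Estimate the exposure-outcome odds ratio with one of the five methods.

    ``data`` is a cohort frame with columns y, v, r (plus the latent z for
    ``true_expo``).  Fixed-window methods default to keeping all subjects in
    the analysis (comparable standard errors across methods); with
    ``keep_all=False`` subjects whose only redemption lies outside the
    window are excluded, the convention of applied fixed-window analyses.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    df = validate_cohort(data, delta=delta, require_truth=(method == "true_expo"))
    y = df["y"].to_numpy()

    if method == "true_expo":
        return _or_from_logistic(method, y, df["z"].to_numpy(dtype=float), len(df))

    if method == "cc_wtd":
        from .joint import JointWtdModel

        model = JointWtdModel(delta=delta, seed=seed).fit(df, y)
        return OrEstimate(
            method=method,
            or_hat=model.or_,
            se_log_or=model.se_log_or_,
            ci_95=model.or_ci_,
            n_used=len(df),
            converged=model.converged_,
        )

    if method == "wtd_prob":
        est = ReverseWtdMixture(
            delta=delta, controls_only=rwtd_controls_only, probability=prob_kind, seed=seed
        )
        est.fit(df, y)
        prob = est.exposure_probability(df)
        out = _or_from_logistic(method, y, prob, len(df))
        return OrEstimate(**{**out.__dict__, "converged": est.converged_})

    window_days = 90 if method == "window_90" else 30
    expo = fixed_window_exposure(df, window_days)
    if keep_all:
        return _or_from_logistic(method, y, expo.astype(float), len(df))
    keep = (df["v"].to_numpy() == 0) | (expo == 1)
    return _or_from_logistic(method, y[keep], expo[keep].astype(float), int(keep.sum()))
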