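"""Joint maximum-likelihood model for case-control status and the reverse
waiting-time distribution.

The observable data per subject are the case/control outcome ``Y``, the
indicator ``V`` of any prescription redemption within the window of length
``delta`` before the index date, and — when ``V = 1`` — the backward
recurrence time ``R`` from the last such redemption to the index date.
Exposure on the index date, ``Z``, is latent.  The outcome follows a
logistic model ``P(Y=1|Z=z) = expit(beta0 + beta1 z)``, so ``exp(beta1)``
is the exposure-outcome odds ratio of interest, and ``Y`` is assumed
independent of ``(V, R)`` given ``Z``.

The likelihood contribution of one subject mixes three patient types:

* continuing users (probability ``pv px``): ``R`` follows the backward
  recurrence density ``g`` and the subject is exposed;
* stoppers (``pv (1 - px)``): the last redemption is uniform on the window
  (constant stopping rate), and the subject is still exposed with
  probability ``1 - F(r)`` — the chance that the final prescription's
  duration outlasts ``r``;
* no redemption in the window (``1 - pv``): unexposed.

giving, for ``v = 1``,

    l = pv px g(r) P(y|1) + pv (1-px) (1/delta) [F(r) P(y|0) + (1-F(r)) P(y|1)]

and ``l = (1 - pv) P(y|0)`` for ``v = 0``.  Maximizing the product over
subjects estimates the odds ratio jointly with the nuisance parameters
``(pv, px, mu, sigma)``, propagating the exposure uncertainty into the
standard error of ``log OR``.

Optimization runs on the unconstrained coordinates
``(logit pv, logit px, beta0, beta1, mu, log sigma)``; any of
``pv, px, beta0, mu, sigma`` may additionally depend on covariates through
linear predictors on those scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from ._optim import ParamLayout
from .brd import BrdParams, iad_cdf, log_brd_pdf
from .io import DAYS_PER_YEAR, validate_cohort
from .reference import (
    _minimize_with_retries,
    _mixture_exposure_prob,
    _softplus,
    _vcov_from_hessian,
    fit_rwtd,
)

__all__ = [
    "JointParams",
    "FitResult",
    "JointWtdModel",
    "logistic_prob",
    "individual_loglik",
    "total_loglik",
    "fit_joint",
    "posterior_exposure_prob",
    "wald_ci_or",
]

_BASE = ("pv", "px", "beta0", "beta1", "mu", "sigma")
_COV_ALLOWED = {"pv", "px", "beta0", "mu", "sigma"}


@dataclass(frozen=True)
class JointParams:
    """Full parameter set of the joint model (natural scales).

    ``coefs`` optionally attaches covariate coefficients to any of
    pv, px, beta0, mu, sigma; the coefficients act on the unconstrained
    scale of the parameter (logit, logit, identity, identity, log).
    """

    pv: float
    px: float
    beta0: float
    beta1: float
    brd: BrdParams
    coefs: dict[str, dict[str, float]] | None = None

    def __post_init__(self):
        if not (0.0 < self.pv < 1.0 and 0.0 < self.px < 1.0):
            raise ValueError("pv and px must lie strictly between 0 and 1")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a joint-model fit (unconstrained-scale covariance)."""

    estimates: JointParams
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    se_log_or: float
    or_ci_95: tuple[float, float]
    param_names: tuple[str, ...] = field(default=_BASE)


def logistic_prob(z, beta0, beta1) -> float:
    """``P(Y=1 | Z=z) = expit(beta0 + beta1 z)``."""
    return special.expit(np.asarray(beta0) + np.asarray(beta1) * np.asarray(z))


def _log_py(y, eta):
    """log P(Y=y) for a logistic linear predictor eta; stable both tails."""
    sign = np.where(np.asarray(y) == 1, -1.0, 1.0)
    return -_softplus(sign * np.asarray(eta))


def _loglik_v1(y, r, lpv, lpx, beta0, beta1, mu, sigma, log_delta, brd=None):
    """Vector of log-contributions for subjects with v = 1.

    Parameters may be scalars or per-record arrays.  ``brd`` overrides the
    log-normal (mu, sigma) pair with an arbitrary BrdParams family.
    """
    if brd is not None and brd.family != "lognormal":
        log_g = log_brd_pdf(r, brd)
        F = iad_cdf(r, brd)
    else:
        z = (np.log(r) - mu) / sigma
        log_g = special.log_ndtr(-z) - (mu + 0.5 * sigma**2)
        F = special.ndtr(z)
    p1 = np.exp(_log_py(y, beta0 + beta1))
    p0 = np.exp(_log_py(y, beta0))
    a = -_softplus(-lpx) + log_g + np.log(p1)  # continuing user
    b = -_softplus(lpx) - log_delta + np.log(F * p0 + (1.0 - F) * p1)  # stopper
    return -_softplus(-lpv) + np.logaddexp(a, b)


def _loglik_v0(y, lpv, beta0):
    return -_softplus(lpv) + _log_py(y, beta0)


class JointWtdModel(BaseEstimator):
    """Joint likelihood estimator of a latent-exposure odds ratio.

    scikit-learn style: ``fit(X, y)`` with ``X`` a cohort frame holding
    columns ``v`` and ``r`` (plus any covariate columns named in
    ``covariate_spec``) and ``y`` the binary case/control outcome.

    Parameters
    ----------
    delta : float
        Observation-window length in years (default one year).
    covariate_spec : dict or None
        ``{"pv"|"px"|"beta0"|"mu"|"sigma": [column, ...]}`` linear
        predictors on the unconstrained parameter scales.
    init : JointParams or None
        Optional starting values; otherwise the fit warm-starts from an
        ordinary rWTD fit (pv, px, mu, sigma) and a 90-day fixed-window
        logistic fit (beta0, beta1).
    seed : int or None
        Seeds the jitter of retry starts after a failed optimization.
    max_retries : int
    ci_level : float

    Attributes
    ----------
    params_ : JointParams
    theta_ : ndarray, unconstrained coordinates at the optimum
    vcov_ : ndarray, inverse observed information (central differences)
    loglik_, converged_, n_obs_
    se_log_or_ : standard error of beta1 (= log OR)
    or_, or_ci_ : odds ratio and Wald CI at ``ci_level``
    result_ : FitResult
    """

    def __init__(self, delta=1.0, covariate_spec=None, init=None, seed=None, max_retries=5, ci_level=0.95):
        self.delta = delta
        self.covariate_spec = covariate_spec
        self.init = init
        self.seed = seed
        self.max_retries = max_retries
        self.ci_level = ci_level

    # -- internal pieces -------------------------------------------------
    def _make_nll(self, df, y):
        layout = ParamLayout(_BASE, self.covariate_spec, allowed=_COV_ALLOWED)
        v = df["v"].to_numpy() == 1
        y = np.asarray(y, dtype=float)
        y1, y0 = y[v], y[~v]
        r1 = df.loc[v, "r"].to_numpy(dtype=float)
        d1 = layout.design(df.loc[v]) if layout.spec else {}
        d0 = layout.design(df.loc[~v]) if layout.spec else {}
        n = len(df)
        log_delta = np.log(self.delta)

        if not layout.spec:
            # covariate-free fast path: v=0 rows collapse to two counts and
            # the v=1 logistic factors are scalars chosen by a case mask
            case1 = y1 == 1.0
            m1 = y1.size
            n0_case = float(np.sum(y0 == 1.0))
            n0_ctrl = float(y0.size - n0_case)
            log_r1 = np.log(r1)

            def sp(x):  # scalar softplus
                return float(np.logaddexp(0.0, x))

            def nll_fast(theta):
                lpv, lpx, b0, b1, mu, ls = theta
                sigma = np.exp(ls)
                z = (log_r1 - mu) / sigma
                log_g = special.log_ndtr(-z) - (mu + 0.5 * sigma * sigma)
                F = special.ndtr(z)
                l_p1_case = -sp(-(b0 + b1))  # log P(Y=1|Z=1)
                l_p1_ctrl = -sp(b0 + b1)
                p1_case, p1_ctrl = np.exp(l_p1_case), np.exp(l_p1_ctrl)
                p0_case = special.expit(b0)
                p0_ctrl = 1.0 - p0_case
                a = (-sp(-lpx)) + log_g + np.where(case1, l_p1_case, l_p1_ctrl)
                mix = F * np.where(case1, p0_case, p0_ctrl) + (1.0 - F) * np.where(
                    case1, p1_case, p1_ctrl
                )
                b = (-sp(lpx)) - log_delta + np.log(mix)
                ll = m1 * (-sp(-lpv)) + float(np.sum(np.logaddexp(a, b)))
                l_1mpv = -sp(lpv)
                ll += n0_case * (l_1mpv + b0 - sp(b0)) + n0_ctrl * (l_1mpv - sp(b0))
                val = -ll / n
                return val if np.isfinite(val) else np.inf

            return nll_fast, layout, n

        def nll(theta):
            lpv1 = layout.resolve(theta, "pv", d1)
            lpx1 = layout.resolve(theta, "px", d1)
            b0_1 = layout.resolve(theta, "beta0", d1)
            b1 = theta[3]
            mu1 = layout.resolve(theta, "mu", d1)
            sig1 = np.exp(layout.resolve(theta, "sigma", d1))
            ll = np.sum(_loglik_v1(y1, r1, lpv1, lpx1, b0_1, b1, mu1, sig1, log_delta))
            lpv0 = layout.resolve(theta, "pv", d0)
            b0_0 = layout.resolve(theta, "beta0", d0)
            ll += np.sum(_loglik_v0(y0, lpv0, b0_0))
            val = -ll / n
            return val if np.isfinite(val) else np.inf

        return nll, layout, n

    def _initial_theta(self, df, y, layout):
        if self.init is not None:
            p = self.init
            base = {
                "pv": special.logit(p.pv),
                "px": special.logit(p.px),
                "beta0": p.beta0,
                "beta1": p.beta1,
                "mu": p.brd.mu,
                "sigma": np.log(p.brd.sigma),
            }
            return layout.pack(base, p.coefs)
        v = df["v"].to_numpy()
        y = np.asarray(y)
        pv0 = float(np.clip(v.mean(), 1e-4, 1 - 1e-4))
        r1 = df.loc[v == 1, "r"].to_numpy(dtype=float)
        try:
            warm = fit_rwtd(r1, delta=self.delta, seed=self.seed)
            px0, mu0, sig0 = warm.rwtd_.p, warm.brd_.mu, warm.brd_.sigma
            if not (1e-4 < px0 < 1 - 1e-4):
                raise ValueError("rWTD warm start at boundary")
        except (ValueError, RuntimeError):
            px0, mu0, sig0 = 0.6, float(np.log(np.median(r1))), 0.8
        # 90-day fixed-window 2x2 with Haldane correction for (beta0, beta1)
        w = (v == 1) & (df["r"].to_numpy(dtype=float) < 90.0 / DAYS_PER_YEAR)
        a = np.sum((y == 1) & w) + 0.5
        b = np.sum((y == 0) & w) + 0.5
        c = np.sum((y == 1) & ~w) + 0.5
        d = np.sum((y == 0) & ~w) + 0.5
        beta0_0 = float(np.log(c / d))
        beta1_0 = float(np.log(a * d / (b * c)))
        base = {
            "pv": special.logit(pv0),
            "px": special.logit(px0),
            "beta0": beta0_0,
            "beta1": beta1_0,
            "mu": mu0,
            "sigma": np.log(sig0),
        }
        return layout.pack(base)

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y have different lengths")
        df = validate_cohort(X.assign(y=y), delta=self.delta)
        v = df["v"].to_numpy()
        if not ((v == 1).any() and (v == 0).any()):
            raise ValueError(
                "identifiability requires subjects both with and without a "
                "window redemption (pv would lie on the boundary)"
            )
        if len(np.unique(y)) < 2:
            raise ValueError("both cases and controls must be present")

        nll, layout, n = self._make_nll(df, y)
        x0 = self._initial_theta(df, y, layout)
        theta, res, ok = _minimize_with_retries(nll, x0, self.seed, self.max_retries)
        vcov, se_ok = _vcov_from_hessian(nll, theta, n)
        se = float(np.sqrt(vcov[3, 3])) if se_ok else float("nan")

        self.layout_ = layout
        self.param_names_ = tuple(layout.names)
        self.theta_ = theta
        self.vcov_ = vcov
        self.loglik_ = float(-res.fun * n)
        self.converged_ = bool(ok and se_ok)
        self.n_obs_ = int(n)
        brd = BrdParams("lognormal", mu=float(theta[4]), sigma=float(np.exp(theta[5])))
        self.params_ = JointParams(
            pv=float(special.expit(theta[0])),
            px=float(special.expit(theta[1])),
            beta0=float(theta[2]),
            beta1=float(theta[3]),
            brd=brd,
            coefs=layout.unpack_coefs(theta) or None,
        )
        self.se_log_or_ = se
        self.or_ = float(np.exp(theta[3]))
        self.or_ci_ = self._ci(self.ci_level)
        self.result_ = FitResult(
            estimates=self.params_,
            vcov=vcov,
            loglik=self.loglik_,
            converged=self.converged_,
            n_obs=n,
            se_log_or=se,
            or_ci_95=self._ci(0.95),
            param_names=tuple(layout.names),
        )
        if iad_cdf(self.delta, brd) < 0.99:
            warnings.warn(
                "more than 1% of the fitted prescription-duration mass lies "
                "beyond the observation window; the untruncated BRD "
                "normalization degrades",
                stacklevel=2,
            )
        return self

    def _ci(self, level):
        zc = stats.norm.ppf(0.5 + level / 2.0)
        b1 = float(self.theta_[3])
        se = self.se_log_or_
        return (float(np.exp(b1 - zc * se)), float(np.exp(b1 + zc * se)))

    def exposure_probability(self, X) -> np.ndarray:
        """Posterior P(Z=1 | v, r) under the fitted parameters (0 for v=0).

        Mirrors the two-step method's usage: the outcome does not enter."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "theta_")
        df = validate_cohort(pd.DataFrame(X), delta=self.delta)
        v = df["v"].to_numpy()
        out = np.zeros(len(df))
        if (v == 1).any():
            sub = df.loc[v == 1]
            d = self.layout_.design(sub) if self.layout_.spec else {}
            lpx = self.layout_.resolve(self.theta_, "px", d)
            mu = self.layout_.resolve(self.theta_, "mu", d)
            sigma = np.exp(self.layout_.resolve(self.theta_, "sigma", d))
            out[v == 1] = _mixture_exposure_prob(
                sub["r"].to_numpy(dtype=float), special.expit(lpx), (mu, sigma), self.delta
            )
        return out

    def predict_proba(self, X) -> np.ndarray:
        """(n, 2) array of [P(Z=0), P(Z=1)] for scikit-learn interop."""
        p = self.exposure_probability(X)
        return np.column_stack([1.0 - p, p])


# -- module-level operations ---------------------------------------------


def _params_to_frame(rec) -> pd.DataFrame:
    if isinstance(rec, pd.DataFrame):
        return rec
    return pd.DataFrame([dict(rec)])


def _resolved_params(params: JointParams, df: pd.DataFrame):
    """Per-record (lpv, lpx, beta0, beta1, mu, sigma) honouring coefs."""
    layout = ParamLayout(_BASE, {k: list(v) for k, v in (params.coefs or {}).items()}, allowed=_COV_ALLOWED)
    base = {
        "pv": special.logit(params.pv),
        "px": special.logit(params.px),
        "beta0": params.beta0,
        "beta1": params.beta1,
        "mu": params.brd.mu if params.brd.family == "lognormal" else 0.0,
        "sigma": np.log(params.brd.sigma) if params.brd.family == "lognormal" else 0.0,
    }
    theta = layout.pack(base, params.coefs)
    d = layout.design(df) if layout.spec else {}
    return tuple(layout.resolve(theta, name, d) for name in _BASE)


def individual_loglik(rec, params: JointParams, delta: float = 1.0) -> float:
    """Log likelihood contribution of a single subject record."""
    return float(total_loglik(_params_to_frame(rec), params, delta))


def total_loglik(data: pd.DataFrame, params: JointParams, delta: float = 1.0) -> float:
    """Sum of individual log-likelihood contributions over a cohort."""
    df = validate_cohort(pd.DataFrame(data), delta=delta)
    if len(df) == 0:
        raise ValueError("empty cohort")
    y = df["y"].to_numpy(dtype=float)
    v = df["v"].to_numpy() == 1
    lpv, lpx, b0, b1, mu, lsig = _resolved_params(params, df)

    def pick(val, mask):
        return val[mask] if isinstance(val, np.ndarray) else val

    ll = 0.0
    if v.any():
        ll += np.sum(
            _loglik_v1(
                y[v],
                df.loc[v, "r"].to_numpy(dtype=float),
                pick(lpv, v),
                pick(lpx, v),
                pick(b0, v),
                b1,
                pick(mu, v),
                np.exp(pick(lsig, v)) if params.brd.family == "lognormal" else None,
                np.log(delta),
                brd=params.brd if params.brd.family != "lognormal" else None,
            )
        )
    if (~v).any():
        ll += np.sum(_loglik_v0(y[~v], pick(lpv, ~v), pick(b0, ~v)))
    return float(ll)


def fit_joint(data, delta=1.0, covariate_spec=None, init=None, seed=None) -> FitResult:
    """Fit the joint model on a cohort frame (columns y, v, r, ...)."""
    df = pd.DataFrame(data)
    model = JointWtdModel(delta=delta, covariate_spec=covariate_spec, init=init, seed=seed)
    model.fit(df, df["y"].to_numpy())
    return model.result_


def posterior_exposure_prob(rec, params: JointParams, delta: float = 1.0):
    """P(Z=1 | v, r) under given joint parameters; 0 when v = 0."""
    df = validate_cohort(_params_to_frame(rec), delta=delta)
    v = df["v"].to_numpy()
    out = np.zeros(len(df))
    if (v == 1).any():
        sub = df.loc[v == 1]
        _lpv, lpx, _b0, _b1, mu, lsig = _resolved_params(params, sub)
        if params.brd.family == "lognormal":
            brd = (mu, np.exp(lsig))
        else:
            brd = params.brd
        out[v == 1] = _mixture_exposure_prob(
            sub["r"].to_numpy(dtype=float), special.expit(lpx), brd, delta
        )
    return out if isinstance(rec, pd.DataFrame) else float(out[0])


def wald_ci_or(fit, level: float = 0.95) -> tuple[float, float]:
    """Wald interval ``exp(beta1 -+ z se)`` for the odds ratio."""
    if isinstance(fit, JointWtdModel):
        fit = fit.result_
    if not fit.converged:
        raise ValueError("cannot form a Wald interval from a non-converged fit")
    beta1 = fit.estimates.beta1
    zc = stats.norm.ppf(0.5 + level / 2.0)
    return (float(np.exp(beta1 - zc * fit.se_log_or)), float(np.exp(beta1 + zc * fit.se_log_or)))
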