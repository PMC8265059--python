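"""Parametric inter-arrival densities and their backward recurrence densities.

A subject in continued treatment redeems prescriptions following a renewal
process whose inter-arrival density (IAD) ``f(t)`` describes the time between
successive redemptions.  Intercepting the process at an index date, the time
``R`` back to the last redemption follows the backward recurrence density
(BRD)

    g(r) = (1 - F(r)) / M,

where ``F`` is the IAD cdf and ``M = E(T)`` the mean prescription duration.
Two IAD families are supported: log-normal (the analysis model) and Weibull
(used to generate moderately misspecified data after moment matching).

All times are in years; the log-normal ``mu`` is the log of a duration in
years, so ``mu = log(1.5/12)`` means a median inter-arrival time of
1.5 months.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "BrdParams",
    "iad_cdf",
    "iad_sf",
    "mean_duration",
    "var_duration",
    "brd_pdf",
    "log_brd_pdf",
    "brd_cdf",
    "mean_survival_fraction",
    "weibull_match_moments",
    "sample_iad",
]

#: day-zero remap: a redemption on the index date is treated as half a day back
HALF_DAY_YEARS = 0.5 / 365.25


@dataclass(frozen=True)
class BrdParams:
    """Parameters of an inter-arrival density (and hence of its BRD).

    Parameters
    ----------
    family : {"lognormal", "weibull"}
    mu, sigma : float
        Log-normal location (log-years) and scale; required iff
        ``family == "lognormal"``.
    shape, scale : float
        Weibull shape and scale (years); required iff ``family == "weibull"``.
    """

    family: str
    mu: float | None = None
    sigma: float | None = None
    shape: float | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.family == "lognormal":
            if self.mu is None or self.sigma is None:
                raise ValueError("lognormal BrdParams require mu and sigma")
            if not np.isfinite(self.mu) or not (self.sigma > 0):
                raise ValueError(f"invalid lognormal parameters mu={self.mu}, sigma={self.sigma}")
        elif self.family == "weibull":
            if self.shape is None or self.scale is None:
                raise ValueError("weibull BrdParams require shape and scale")
            if not (self.shape > 0 and self.scale > 0):
                raise ValueError(f"invalid weibull parameters shape={self.shape}, scale={self.scale}")
        else:
            raise ValueError(f"unknown IAD family {self.family!r}")


def iad_cdf(r, params: BrdParams):
    """Cdf ``F(r)`` of the inter-arrival time ``T``; defined for r >= 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    if params.family == "lognormal":
        with np.errstate(divide="ignore"):
            z = (np.log(r) - params.mu) / params.sigma
        out = special.ndtr(z)
    else:
        out = -np.expm1(-((r / params.scale) ** params.shape))
    return out if out.ndim else float(out)


def iad_sf(r, params: BrdParams):
    """Survival function ``1 - F(r)``, computed without cancellation."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    if params.family == "lognormal":
        with np.errstate(divide="ignore"):
            z = (np.log(r) - params.mu) / params.sigma
        out = special.ndtr(-z)
    else:
        out = np.exp(-((r / params.scale) ** params.shape))
    return out if out.ndim else float(out)


def mean_duration(params: BrdParams) -> float:
    """Mean prescription duration ``M = E(T)`` in years."""
    if params.family == "lognormal":
        return float(np.exp(params.mu + 0.5 * params.sigma**2))
    return float(params.scale * special.gamma(1.0 + 1.0 / params.shape))


def var_duration(params: BrdParams) -> float:
    """Variance of the inter-arrival time ``T``."""
    if params.family == "lognormal":
        s2 = params.sigma**2
        return float(np.expm1(s2) * np.exp(2.0 * params.mu + s2))
    k = params.shape
    g1 = special.gamma(1.0 + 1.0 / k)
    g2 = special.gamma(1.0 + 2.0 / k)
    return float(params.scale**2 * (g2 - g1**2))


def brd_pdf(r, params: BrdParams):
    """Backward recurrence density ``g(r) = (1 - F(r)) / M`` for r > 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be strictly positive")
    out = iad_sf(r, params) / mean_duration(params)
    return out if np.asarray(out).ndim else float(out)


def log_brd_pdf(r, params: BrdParams):
    """``log g(r)``, stable in the far tail (uses log_ndtr for lognormal)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be strictly positive")
    if params.family == "lognormal":
        z = (np.log(r) - params.mu) / params.sigma
        out = special.log_ndtr(-z) - (params.mu + 0.5 * params.sigma**2)
    else:
        out = -((r / params.scale) ** params.shape) - np.log(mean_duration(params))
    return out if np.asarray(out).ndim else float(out)


def _partial_expectation(r, params: BrdParams):
    """``E(T; T <= r) = integral_0^r t f(t) dt`` in closed form."""
    r = np.asarray(r, dtype=float)
    if params.family == "lognormal":
        with np.errstate(divide="ignore"):
            z = (np.log(r) - params.mu) / params.sigma
        return mean_duration(params) * special.ndtr(z - params.sigma)
    a = 1.0 + 1.0 / params.shape
    return mean_duration(params) * special.gammainc(a, (r / params.scale) ** params.shape)


def brd_cdf(r, params: BrdParams):
    """Cdf ``G(r) = integral_0^r g(u) du`` of the BRD, in closed form.

    Integration by parts gives ``M * G(r) = r (1 - F(r)) + E(T; T <= r)``,
    which is evaluated with the family's partial-expectation formula.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    out = (r * iad_sf(r, params) + _partial_expectation(r, params)) / mean_duration(params)
    return out if out.ndim else float(out)


def mean_survival_fraction(params: BrdParams, delta: float) -> float:
    """``q = (1/delta) * integral_0^delta (1 - F(r)) dr``.

    This is the probability that a treatment episode started at a uniform
    time within the window of length ``delta`` is still running at its end —
    the exposed fraction among treatment stoppers under the uniform
    stopping-time model.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    return float(mean_duration(params) * brd_cdf(delta, params) / delta)


def _weibull_shape_from_cv2(cv2: float) -> float:
    """Solve Gamma(1+2/k)/Gamma(1+1/k)^2 - 1 = cv2 for the shape k."""

    def h(log_k: float) -> float:
        k = np.exp(log_k)
        return (
            special.gammaln(1.0 + 2.0 / k)
            - 2.0 * special.gammaln(1.0 + 1.0 / k)
            - np.log1p(cv2)
        )

    lo, hi = -7.0, 25.0  # k in [~1e-3, ~7e10]; h is decreasing in k
    if h(lo) < 0 or h(hi) > 0:
        raise RuntimeError(
            f"no Weibull shape bracketed for squared CV {cv2:.3g}; "
            "the coefficient of variation is outside the solvable range"
        )
    log_k = optimize.brentq(h, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return float(np.exp(log_k))


def weibull_match_moments(lognormal_params: BrdParams) -> BrdParams:
    """Weibull IAD with the same mean and variance as a log-normal IAD.

    The squared coefficient of variation ``exp(sigma^2) - 1`` pins down the
    Weibull shape through a 1-D root find (on the log-gamma scale, so very
    small and very large shapes stay representable); the scale then follows
    from the mean.
    """
    if lognormal_params.family != "lognormal":
        raise ValueError("moment matching starts from a lognormal IAD")
    cv2 = float(np.expm1(lognormal_params.sigma**2))
    shape = _weibull_shape_from_cv2(cv2)
    scale = mean_duration(lognormal_params) / special.gamma(1.0 + 1.0 / shape)
    return BrdParams(family="weibull", shape=shape, scale=float(scale))


def sample_iad(params: BrdParams, n: int, rng) -> np.ndarray:
    """Draw ``n`` i.i.d. inter-arrival times.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if params.family == "lognormal":
        return rng.lognormal(params.mu, params.sigma, size=n)
    return params.scale * rng.weibull(params.shape, size=n)
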