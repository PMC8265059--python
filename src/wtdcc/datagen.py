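"""Synthetic case-control cohorts with latent drug exposure.

The generator draws from exactly the process the joint likelihood models:

1. case/control status is assigned with an exact control:case ratio;
2. latent exposure ``z`` is drawn per outcome group with probabilities
   ``(p0, p1)`` chosen so that the exposure odds ratio equals the target
   and the sample-marginal exposure prevalence matches the one implied by
   ``(pv, px)`` and the BRD;
3. continuing users (``x = 1``) receive a backward recurrence time from the
   BRD truncated to the window; treatment stoppers receive a redemption
   time uniform on the window, split by rejection sampling into an
   exposed stream (density proportional to the duration survival
   ``1 - F(r)``) and an unexposed stream (proportional to ``F(r)``) so that
   the pooled stopper marginal is exactly uniform;
4. unexposed subjects carry a window redemption with the complementary
   probability that keeps ``P(V=1) = pv``.

``(v, x, r)`` depend on the outcome only through ``z``, matching the
model's conditional-independence assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

from .brd import BrdParams, brd_cdf, iad_cdf, iad_sf, mean_survival_fraction, weibull_match_moments

__all__ = [
    "Scenario",
    "exposure_prevalence",
    "case_control_exposure_probs",
    "sample_stopper_time",
    "sample_truncated_brd",
    "simulate_dataset",
    "make_weibull_variant",
]


@dataclass(frozen=True)
class Scenario:
    """One simulation setting.

    ``n_total`` must be divisible by ``1 + controls_per_case`` so the
    case:control ratio is exact, as in a designed case-control sample.
    """

    n_total: int
    controls_per_case: int
    or_true: float
    pv: float
    px: float
    brd: BrdParams
    delta: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_total % (1 + self.controls_per_case) != 0:
            raise ValueError("n_total must be divisible by 1 + controls_per_case")
        if not (0 < self.pv < 1 and 0 < self.px < 1):
            raise ValueError("pv and px must lie strictly between 0 and 1")
        if self.or_true <= 0 or self.delta <= 0:
            raise ValueError("or_true and delta must be positive")

    @property
    def n_cases(self) -> int:
        return self.n_total // (1 + self.controls_per_case)

    @property
    def case_fraction(self) -> float:
        return 1.0 / (1 + self.controls_per_case)


def exposure_prevalence(pv: float, px: float, brd: BrdParams, delta: float = 1.0) -> float:
    """Sample-marginal probability of being exposed on the index date.

    ``p_Z = pv (px + (1 - px) q)`` where ``q = (1/delta) int_0^delta
    (1 - F(r)) dr`` is the exposed fraction among stoppers under the
    uniform-redemption model.
    """
    q = mean_survival_fraction(brd, delta)
    return float(pv * (px + (1.0 - px) * q))


def case_control_exposure_probs(p_z: float, or_true: float, case_fraction: float) -> tuple[float, float]:
    """Exposure probabilities (p0 controls, p1 cases) consistent with a
    marginal prevalence ``p_z`` and exposure odds ratio ``or_true``.

    Solves ``case_fraction * p1 + (1 - case_fraction) * p0 = p_z`` with
    ``logit p1 = logit p0 + log(or_true)`` by a bracketed root find on
    ``logit p0``; both constraints hold to 1e-10.
    """
    if not (0.0 < p_z < 1.0):
        raise ValueError("p_z must lie strictly between 0 and 1")
    if not (0.0 <= case_fraction < 1.0):
        raise ValueError("case_fraction must lie in [0, 1)")
    log_or = np.log(or_true)
    if case_fraction == 0.0:
        p0 = p_z
        return float(p0), float(special.expit(special.logit(p0) + log_or))

    def gap(l0):
        return (
            case_fraction * special.expit(l0 + log_or)
            + (1.0 - case_fraction) * special.expit(l0)
            - p_z
        )

    lo, hi = -45.0, 45.0
    if not (gap(lo) < 0 < gap(hi)):
        raise ValueError(
            f"no exposure split reproduces prevalence {p_z} at OR {or_true} "
            f"and case fraction {case_fraction}"
        )
    l0 = optimize.brentq(gap, lo, hi, xtol=1e-13, rtol=8.9e-16)
    p0 = float(special.expit(l0))
    p1 = float(special.expit(l0 + log_or))
    if abs(case_fraction * p1 + (1 - case_fraction) * p0 - p_z) > 1e-10:
        raise RuntimeError("root finding did not reach the prevalence constraint")
    return p0, p1


def sample_stopper_time(exposed_at_index: bool, brd: BrdParams, delta: float, rng, size: int = 1) -> np.ndarray:
    """Redemption times for treatment stoppers, by rejection sampling.

    Stopper redemptions are uniform on the window marginally; conditioning
    on exposure at the index date tilts the density to be proportional to
    the duration survival ``1 - F(r)`` (exposed) or the cdf ``F(r)``
    (unexposed).  A uniform proposal is accepted with exactly that
    probability, so mixing the two streams in proportion ``q : 1 - q``
    recovers the uniform marginal.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    accept_mass = mean_survival_fraction(brd, delta)
    if not exposed_at_index:
        accept_mass = 1.0 - accept_mass
    if accept_mass < 1e-12:
        raise ValueError(
            "acceptance probability is numerically zero on the window; "
            "this BRD/delta combination admits no such stoppers"
        )
    out = np.empty(size)
    filled = 0
    while filled < size:
        want = size - filled
        m = int(min(max(want / accept_mass * 1.2 + 16, 32), 4_000_000))
        prop = rng.uniform(0.0, delta, size=m)
        acc_p = iad_sf(prop, brd) if exposed_at_index else iad_cdf(prop, brd)
        keep = prop[rng.random(m) < acc_p]
        take = min(keep.size, want)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def sample_truncated_brd(brd: BrdParams, delta: float, rng, size: int = 1, grid_size: int = 32769) -> np.ndarray:
    """Backward recurrence times from the BRD truncated to (0, delta].

    Inverse-cdf sampling against the closed-form BRD cdf evaluated on a
    dense grid (linear interpolation of the inverse).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = np.linspace(0.0, delta, grid_size)
    cdf = brd_cdf(grid, brd)
    cdf /= cdf[-1]
    u = rng.random(size)
    return np.interp(u, cdf, grid)


def simulate_dataset(scn: Scenario, seed: int | None = None) -> pd.DataFrame:
    """Generate one cohort; columns id, y, v, r (NaN when v=0), z, x.

    Byte-identical output for identical scenario and seed.  Cases occupy
    the first ``n_cases`` rows; every analysis here is order-invariant.
    """
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    n1, n = scn.n_cases, scn.n_total
    n0 = n - n1
    q = mean_survival_fraction(scn.brd, scn.delta)
    p_z = exposure_prevalence(scn.pv, scn.px, scn.brd, scn.delta)
    p0, p1 = case_control_exposure_probs(p_z, scn.or_true, scn.case_fraction)
    p_v_given_z0 = scn.pv * (1.0 - scn.px) * (1.0 - q) / (1.0 - p_z)
    if p_v_given_z0 > 1.0:
        raise ValueError("scenario infeasible: implied P(V=1|Z=0) exceeds 1")
    p_cont_given_z1 = scn.px / (scn.px + (1.0 - scn.px) * q)

    y = np.concatenate([np.ones(n1, dtype=np.int8), np.zeros(n0, dtype=np.int8)])
    z = np.zeros(n, dtype=np.int8)
    z[:n1] = rng.random(n1) < p1
    z[n1:] = rng.random(n0) < p0

    x = np.zeros(n, dtype=np.int8)
    v = np.zeros(n, dtype=np.int8)
    r = np.full(n, np.nan)

    idx_z1 = np.flatnonzero(z == 1)
    v[idx_z1] = 1  # exposed subjects always have a window redemption
    cont = rng.random(idx_z1.size) < p_cont_given_z1
    idx_cont = idx_z1[cont]
    idx_stop1 = idx_z1[~cont]
    x[idx_cont] = 1
    r[idx_cont] = sample_truncated_brd(scn.brd, scn.delta, rng, size=idx_cont.size)
    r[idx_stop1] = sample_stopper_time(True, scn.brd, scn.delta, rng, size=idx_stop1.size)

    idx_z0 = np.flatnonzero(z == 0)
    has_v = rng.random(idx_z0.size) < p_v_given_z0
    idx_stop0 = idx_z0[has_v]
    v[idx_stop0] = 1
    r[idx_stop0] = sample_stopper_time(False, scn.brd, scn.delta, rng, size=idx_stop0.size)

    return pd.DataFrame(
        {"id": np.arange(n), "y": y, "v": v, "r": r, "z": z, "x": x}
    )


def make_weibull_variant(scn: Scenario) -> Scenario:
    """Same scenario with the generating BRD swapped for the Weibull of
    equal mean and variance (the misspecification setting)."""
    if scn.brd.family != "lognormal":
        raise ValueError("the Weibull variant starts from a lognormal scenario")
    return replace(scn, brd=weibull_match_moments(scn.brd))
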