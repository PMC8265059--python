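"""Monte-Carlo performance harness: scenarios x methods x replicates.

For each replicate a cohort is generated and analyzed with the requested
methods; per method the harness reports

* median relative bias (%) of the estimated odds ratio,
* median standard error of the log odds ratio,
* coverage (%) of nominal 95% Wald confidence intervals,
* the variance inflation factor (VIF): the squared ratio of a method's
  median SE to that of the true-exposure benchmark.

Medians (not means) are used for bias and SE; metrics are computed over
converged replicates only, and the convergence count is reported so the
exclusion stays auditable.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datagen import Scenario, simulate_dataset
from .reference import METHODS, estimate_or

__all__ = [
    "MethodMetrics",
    "relative_bias_pct",
    "coverage",
    "vif",
    "run_scenario",
    "summarize",
    "parse_summary",
]


@dataclass(frozen=True)
class MethodMetrics:
    method: str
    median_rel_bias_pct: float
    median_se_log_or: float
    coverage_pct: float
    vif: float
    n_converged: int
    n_reps: int

    def __post_init__(self):
        if not (0.0 <= self.coverage_pct <= 100.0):
            raise ValueError("coverage must lie in [0, 100]")
        if self.n_converged > self.n_reps:
            raise ValueError("n_converged cannot exceed n_reps")


def relative_bias_pct(or_hat: float, or_true: float) -> float:
    """``100 (or_hat - or_true) / or_true``."""
    if or_hat <= 0 or or_true <= 0:
        raise ValueError("odds ratios must be positive")
    return 100.0 * (or_hat - or_true) / or_true


def coverage(ci_list, or_true: float) -> float:
    """Percentage of intervals containing the true OR (inclusive ends)."""
    ci = np.asarray(list(ci_list), dtype=float)
    if ci.size == 0:
        raise ValueError("no intervals")
    hit = (ci[:, 0] <= or_true) & (or_true <= ci[:, 1])
    return 100.0 * float(hit.mean())


def vif(median_se_method: float, median_se_reference: float) -> float:
    """Squared ratio of median SEs versus the true-exposure benchmark."""
    if median_se_method <= 0 or median_se_reference <= 0:
        raise ValueError("standard errors must be positive")
    return (median_se_method / median_se_reference) ** 2


def run_scenario(
    scn: Scenario,
    n_reps: int,
    methods=METHODS,
    base_seed: int = 0,
    analysis_delta: float | None = None,
):
    """Run one scenario; returns (list of MethodMetrics, replicate frame).

    Replicate ``k`` uses seed ``base_seed + k``, so a scenario can be
    extended with more replicates without rerunning earlier ones.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    methods = list(methods)
    delta = scn.delta if analysis_delta is None else analysis_delta
    rows = []
    for rep in range(n_reps):
        seed = base_seed + rep
        data = simulate_dataset(scn, seed=seed)
        for method in methods:
            est = estimate_or(method, data, delta=delta, seed=seed)
            rows.append(
                {
                    "rep": rep,
                    "seed": seed,
                    "method": method,
                    "or_hat": est.or_hat,
                    "se_log_or": est.se_log_or,
                    "ci_lo": est.ci_95[0],
                    "ci_hi": est.ci_95[1],
                    "converged": est.converged,
                }
            )
    reps = pd.DataFrame(rows)

    ref_median_se = np.nan
    if "true_expo" in methods:
        ok = reps[(reps["method"] == "true_expo") & reps["converged"]]
        ref_median_se = float(ok["se_log_or"].median())

    metrics = []
    for method in methods:
        sub = reps[reps["method"] == method]
        ok = sub[sub["converged"]]
        if len(ok) == 0:
            raise RuntimeError(f"no converged replicates for method {method!r}")
        med_se = float(ok["se_log_or"].median())
        metrics.append(
            MethodMetrics(
                method=method,
                median_rel_bias_pct=float(
                    np.median([relative_bias_pct(v, scn.or_true) for v in ok["or_hat"]])
                ),
                median_se_log_or=med_se,
                coverage_pct=coverage(ok[["ci_lo", "ci_hi"]].to_numpy(), scn.or_true),
                vif=vif(med_se, ref_median_se) if np.isfinite(ref_median_se) else float("nan"),
                n_converged=int(len(ok)),
                n_reps=int(len(sub)),
            )
        )
    return metrics, reps


_COLUMNS = [
    "scenario",
    "method",
    "median_rel_bias_pct",
    "median_se_log_or",
    "coverage_pct",
    "vif",
    "n_converged",
    "n_reps",
]


def summarize(results: dict[str, list[MethodMetrics]]) -> pd.DataFrame:
    """Deterministic summary grid: one row per scenario x method, methods in
    the benchmark-first order true_expo, cc_wtd, wtd_prob, window_90,
    window_30."""
    rows = []
    order = {m: i for i, m in enumerate(METHODS)}
    for scenario, metrics in results.items():
        for m in sorted(metrics, key=lambda m: order.get(m.method, 99)):
            rows.append({"scenario": scenario, **m.__dict__})
    return pd.DataFrame(rows, columns=_COLUMNS)


def render_table(summary: pd.DataFrame) -> str:
    """Text rendering of the summary grid (CSV; round-trips via
    :func:`parse_summary`)."""
    buf = _io.StringIO()
    summary.to_csv(buf, index=False)
    return buf.getvalue()


def parse_summary(text: str) -> pd.DataFrame:
    return pd.read_csv(_io.StringIO(text))
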