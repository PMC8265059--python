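"""Shared plumbing for likelihood optimization: covariate linear predictors
on (transformed) model parameters, and a central-difference Hessian for
observed-information standard errors."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ParamLayout", "hessian_cfd"]


class ParamLayout:
    """Maps a flat unconstrained parameter vector to per-record values.

    Each base parameter (already on its unconstrained scale: logits for
    probabilities, log for sigma) may carry a block of covariate
    coefficients; the resolved value for a record is then
    ``base + sum(coef * covariate)``.

    Parameters
    ----------
    base_names : sequence of str
        Ordered names of the base parameters.
    covariate_spec : dict or None
        Mapping ``param -> list of covariate column names``.
    allowed : set or None
        Parameters permitted to carry covariates (defaults to all).
    """

    def __init__(self, base_names, covariate_spec=None, allowed=None):
        self.base_names = tuple(base_names)
        spec = {k: list(v) for k, v in (covariate_spec or {}).items() if v}
        allowed = set(self.base_names) if allowed is None else set(allowed)
        for key in spec:
            if key not in self.base_names:
                raise ValueError(f"unknown parameter {key!r} in covariate_spec")
            if key not in allowed:
                raise ValueError(f"covariates not supported on parameter {key!r}")
        self.spec = spec
        self._offsets = {}
        pos = len(self.base_names)
        for name in self.base_names:
            cols = self.spec.get(name, [])
            self._offsets[name] = (pos, pos + len(cols))
            pos += len(cols)
        self.n_params = pos

    @property
    def names(self) -> list[str]:
        out = list(self.base_names)
        for name in self.base_names:
            out.extend(f"{name}:{col}" for col in self.spec.get(name, []))
        return out

    def has_covariates(self, name: str) -> bool:
        return bool(self.spec.get(name))

    def design(self, X: pd.DataFrame | None) -> dict[str, np.ndarray]:
        """Extract, per parameter, the (n, k) covariate matrix from ``X``."""
        mats = {}
        for name, cols in self.spec.items():
            if X is None:
                raise ValueError(f"covariates {cols} required but no data given")
            missing = [c for c in cols if c not in X.columns]
            if missing:
                raise ValueError(f"missing covariate columns {missing}")
            mats[name] = np.ascontiguousarray(X[cols].to_numpy(dtype=float))
        return mats

    def resolve(self, theta: np.ndarray, name: str, design: dict[str, np.ndarray]):
        """Per-record value of parameter ``name`` (scalar when no covariates)."""
        base = theta[self.base_names.index(name)]
        lo, hi = self._offsets[name]
        if lo == hi:
            return base
        return base + design[name] @ theta[lo:hi]

    def pack(self, base_values: dict[str, float], coefs: dict | None = None) -> np.ndarray:
        theta = np.zeros(self.n_params)
        for i, name in enumerate(self.base_names):
            theta[i] = base_values[name]
        for name, cmap in (coefs or {}).items():
            lo, _hi = self._offsets[name]
            for j, col in enumerate(self.spec.get(name, [])):
                theta[lo + j] = cmap.get(col, 0.0)
        return theta

    def unpack_coefs(self, theta: np.ndarray) -> dict[str, dict[str, float]]:
        out = {}
        for name, cols in self.spec.items():
            lo, _hi = self._offsets[name]
            out[name] = {col: float(theta[lo + j]) for j, col in enumerate(cols)}
        return out


def hessian_cfd(f, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Hessian of ``f`` at ``x`` by central finite differences (absolute step)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        for j in range(i, n):
            ej = np.zeros(n)
            ej[j] = step
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step * step)
    return H
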