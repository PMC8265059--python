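"""Cohort file reading/writing, validation, and scenario configuration.

The cohort table is a plain delimited-text (CSV) file with one row per
subject and columns

    y   case/control status (1 = case, 0 = control)
    v   1 if any prescription redemption fell in the window before the index
        date, else 0
    r   time from the last redemption to the index date, in years; present
        iff v = 1 and in (0, delta]

plus optional latent-truth columns ``z`` (exposed on the index date) and
``x`` (continues treatment) written by the simulator, and arbitrary numeric
covariate columns.  In ``dates`` mode, ``r`` is derived from
``last_rx_date`` and ``index_date`` columns instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .brd import HALF_DAY_YEARS, BrdParams

__all__ = [
    "CohortTable",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
    "load_scenario",
    "dump_scenario",
    "brd_params_to_dict",
    "brd_params_from_dict",
]

DAYS_PER_YEAR = 365.25


@dataclass
class CohortTable:
    """A validated cohort with its observation-window length (years)."""

    data: pd.DataFrame
    delta: float = 1.0
    attrs: dict = field(default_factory=dict)


def validate_cohort(df: pd.DataFrame, delta: float = 1.0, require_truth: bool = False) -> pd.DataFrame:
    """Check the column contract of a cohort table and return a clean copy.

    Raises ``ValueError`` naming offending row labels on any violation:
    y and v must be 0/1; r must be present iff v = 1 and lie in (0, delta];
    r = 0 exactly (a redemption on the index date) is remapped to half a day
    rather than rejected, since registry dates are day-resolved.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    required = {"y", "v"} | ({"z"} if require_truth else set())
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns {sorted(missing)}")
    out = df.copy()
    for col in ("y", "v"):
        vals = out[col].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            raise ValueError(f"column {col!r} must be 0/1; offending rows: {list(out.index[bad])[:10]}")
        out[col] = vals.astype(np.int8)
    if "r" not in out.columns:
        if int(out["v"].sum()) > 0:
            raise ValueError("column 'r' required when any subject has v=1")
        out["r"] = np.nan
    r = pd.to_numeric(out["r"], errors="coerce").to_numpy(dtype=float)
    v = out["v"].to_numpy()
    r = np.where((v == 1) & (r == 0.0), HALF_DAY_YEARS, r)
    bad_v1 = (v == 1) & ~((r > 0) & (r <= delta))
    bad_v0 = (v == 0) & ~np.isnan(r)
    if bad_v1.any():
        raise ValueError(
            "subjects with v=1 need r in (0, delta]; offending rows: "
            f"{list(out.index[bad_v1])[:10]}"
        )
    if bad_v0.any():
        raise ValueError(
            f"subjects with v=0 must have empty r; offending rows: {list(out.index[bad_v0])[:10]}"
        )
    out["r"] = r
    return out


def read_cohort(
    path,
    mode: str = "durations",
    delta: float = 1.0,
    r_unit: str = "years",
    date_format: str | None = None,
) -> CohortTable:
    """Read a cohort CSV.

    In ``durations`` mode the file carries ``r`` directly (``r_unit`` is
    ``"years"`` or ``"days"``).  In ``dates`` mode it carries ``index_date``
    and ``last_rx_date`` columns; ``r`` is their difference in years and
    v = 0 when the redemption is absent or more than ``delta`` years back.
    """
    df = pd.read_csv(path)
    if mode == "durations":
        if "r" in df.columns and r_unit == "days":
            df["r"] = pd.to_numeric(df["r"], errors="coerce") / DAYS_PER_YEAR
        elif r_unit not in ("years", "days"):
            raise ValueError(f"unknown r_unit {r_unit!r}")
        if "v" not in df.columns:
            df["v"] = (~pd.to_numeric(df.get("r"), errors="coerce").isna()).astype(int)
    elif mode == "dates":
        for col in ("index_date", "last_rx_date"):
            if col not in df.columns:
                raise ValueError(f"dates mode requires column {col!r}")
        idx = pd.to_datetime(df["index_date"], format=date_format)
        last = pd.to_datetime(df["last_rx_date"], format=date_format, errors="coerce")
        r = (idx - last).dt.days / DAYS_PER_YEAR
        if (r < 0).any():
            bad = list(df.index[r < 0])[:10]
            raise ValueError(f"last_rx_date after index_date in rows {bad}")
        in_window = r.notna() & (r <= delta)
        df["v"] = in_window.astype(int)
        df["r"] = r.where(in_window)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    data = validate_cohort(df, delta=delta)
    return CohortTable(data=data, delta=delta)


def write_cohort(cohort, path, with_truth: bool = False) -> None:
    """Write a cohort table to CSV (latent columns only on request)."""
    df = cohort.data if isinstance(cohort, CohortTable) else cohort
    if not with_truth:
        df = df.drop(columns=[c for c in ("z", "x") if c in df.columns])
    df.to_csv(path, index=False)


def brd_params_to_dict(params: BrdParams) -> dict:
    d = {"family": params.family}
    if params.family == "lognormal":
        d.update(mu=float(params.mu), sigma=float(params.sigma))
    else:
        d.update(shape=float(params.shape), scale=float(params.scale))
    return d


def brd_params_from_dict(d: dict) -> BrdParams:
    return BrdParams(**d)


def load_scenario(path):
    """Load a simulation scenario (or a list of them) from a YAML file."""
    from .datagen import Scenario

    with open(path) as fh:
        raw = yaml.safe_load(fh)

    def one(d):
        d = dict(d)
        d["brd"] = brd_params_from_dict(d["brd"])
        return Scenario(**d)

    if isinstance(raw, list):
        return [one(d) for d in raw]
    return one(raw)


def dump_scenario(scenario, path) -> None:
    from dataclasses import asdict

    def one(s):
        d = asdict(s)
        d["brd"] = brd_params_to_dict(s.brd)
        return d

    payload = [one(s) for s in scenario] if isinstance(scenario, list) else one(scenario)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
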