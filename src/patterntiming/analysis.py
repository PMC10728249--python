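"""Behavioral summary pipeline: outlier exclusion, central-tendency slopes,
condition means/variability, endpoint categorization, repeated-measures ANOVA.

All functions take the long-format trial table (one row per trial x position,
columns participant_id, trial, condition, set_id, position, sample_ms,
reproduced_ms) and return tidy frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "exclude_outliers",
    "central_tendency_slope",
    "condition_means",
    "interval_variability",
    "categorize_rs_by_endpoint",
    "rm_anova_oneway",
    "AnovaResult",
]

#: Boundary between "short" and "long" endpoint intervals (the design mean).
ENDPOINT_SPLIT_MS = 700.0
_MIDDLE_TOL = 1e-6


def _trial_means(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-trial mean of the four reproduced intervals."""
    return (
        frame.groupby(["participant_id", "condition", "trial"], sort=False)[
            "reproduced_ms"
        ]
        .mean()
        .rename("trial_mean")
        .reset_index()
    )


def exclude_outliers(frame: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop trials whose reproduced-sequence mean is an outlier within its cell.

    Within each participant x condition cell, a trial is excluded when its
    mean reproduced interval deviates from the cell mean of those per-trial
    means by at least twice their (population) SD; cells with zero SD are
    passed through untouched.  Single pass, no re-iteration.  Returns the kept
    rows and the number of excluded trials.
    """
    tm = _trial_means(frame)
    cell = tm.groupby(["participant_id", "condition"], sort=False)["trial_mean"]
    center = cell.transform("mean")
    sd = cell.transform(lambda x: float(np.std(x, ddof=0)))
    n_cell = cell.transform("size")
    if (n_cell < 2).any():
        bad = tm.loc[n_cell < 2, ["participant_id", "condition"]].drop_duplicates()
        for rec in bad.to_dict("records"):
            logger.warning("outlier rule skipped for cell with < 2 trials: %s", rec)
    out = (sd > 0) & (np.abs(tm["trial_mean"] - center) >= 2.0 * sd) & (n_cell >= 2)
    dropped = tm.loc[out, ["participant_id", "condition", "trial"]]
    key = ["participant_id", "condition", "trial"]
    merged = frame.merge(dropped.assign(_drop=True), on=key, how="left")
    kept = merged.loc[merged["_drop"].isna()].drop(columns="_drop")
    return kept.reset_index(drop=True), int(len(dropped))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    denom = float(dx @ dx)
    slope = float(dx @ (y - ym)) / denom
    return slope, float(ym - slope * xm)


def central_tendency_slope(
    frame: pd.DataFrame, by_set: bool = False
) -> pd.DataFrame:
    """OLS slope of reproduced on sample interval per participant x condition.

    Pools rows over positions (and over interval sets unless ``by_set``).  A
    slope below 1 quantifies the central-tendency bias.  Groups with fewer
    than two distinct sample intervals are rejected.
    """
    keys = ["participant_id", "condition"] + (["set_id"] if by_set else [])
    records = []
    for key, g in frame.groupby(keys, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        x = g["sample_ms"].to_numpy(float)
        y = g["reproduced_ms"].to_numpy(float)
        if np.unique(x).size < 2:
            raise ValueError(
                f"group {dict(zip(keys, key))} has < 2 distinct "
                "sample intervals; slope undefined"
            )
        slope, intercept = _ols(x, y)
        rec = dict(zip(keys, key))
        rec.update(slope=slope, intercept=intercept, n_points=len(g))
        records.append(rec)
    return pd.DataFrame(records)


def condition_means(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of reproduced intervals per participant x condition.

    Row-level aggregation (equivalent to averaging per-trial sequence means
    when every trial contributes four rows), pooled over interval sets.
    """
    out = (
        frame.groupby(["participant_id", "condition"], sort=False)["reproduced_ms"]
        .agg(mean_reproduced_ms="mean", sd_reproduced_ms="std", n_rows="size")
        .reset_index()
    )
    return out


def interval_variability(frame: pd.DataFrame) -> pd.DataFrame:
    """SD of reproductions per participant x condition x sample interval."""
    return (
        frame.groupby(
            ["participant_id", "condition", "set_id", "sample_ms"], sort=False
        )["reproduced_ms"]
        .agg(sd_reproduced_ms="std", n_rows="size")
        .reset_index()
    )


def categorize_rs_by_endpoint(
    frame: pd.DataFrame, endpoint: str = "first"
) -> pd.DataFrame:
    """Tag random-sequence trials by their first or last interval.

    Adds an ``endpoint_category`` column: ``short`` (< 700 ms), ``middle``
    (= 700 ms, only interval set 2 can produce it) or ``long`` (> 700 ms).
    Only RS trials are accepted.
    """
    if endpoint not in ("first", "last"):
        raise ValueError("endpoint must be 'first' or 'last'")
    if (frame["condition"] != "RS").any():
        raise ValueError("categorize_rs_by_endpoint accepts RS trials only")
    pos = 1 if endpoint == "first" else int(frame["position"].max())
    ref = (
        frame.loc[frame["position"] == pos, ["participant_id", "trial", "sample_ms"]]
        .rename(columns={"sample_ms": "_endpoint_ms"})
    )
    df = frame.merge(ref, on=["participant_id", "trial"], how="left", validate="m:1")
    if df["_endpoint_ms"].isna().any():
        raise ValueError(f"some trials lack position {pos}")
    e = df.pop("_endpoint_ms").to_numpy(float)
    cat = np.where(
        np.abs(e - ENDPOINT_SPLIT_MS) <= _MIDDLE_TOL,
        "middle",
        np.where(e < ENDPOINT_SPLIT_MS, "short", "long"),
    )
    return df.assign(endpoint_category=cat)


class AnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


def rm_anova_oneway(
    frame: pd.DataFrame,
    dv: str = "value",
    within: str = "level",
    subject: str = "participant_id",
) -> AnovaResult:
    """Classical one-way repeated-measures ANOVA (descriptive utility).

    Expects one value per subject x level (balanced, no missing cells) and
    returns the F ratio with (k-1, (k-1)(n-1)) degrees of freedom and its
    uncorrected p-value.
    """
    wide = frame.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("missing cells: design must be balanced")
    x = wide.to_numpy(float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    grand = x.mean()
    ss_subj = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_treat = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_treat
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_treat = ss_treat / df1
    ms_err = ss_err / df2
    f = 0.0 if ms_treat == 0 else ms_treat / ms_err
    return AnovaResult(F=f, df1=df1, df2=df2, p=float(stats.f.sf(f, df1, df2)))
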