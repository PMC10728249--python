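"""Generative Bayesian observer for four-interval sequence reproduction.

The observer forms an ensemble prior for the sequence whose mean is a weighted
average of the first presented interval D1 and the fixed design mean (700 ms),

    mu_e = alpha * D1 + 700 * (1 - alpha),        sigma_e = wf_p * mu_e,

measures each interval with scalar (Weber) noise inflated by a per-condition
volatility factor k_j,

    sigma_i^2 = k_j * (wf_s * D_i)^2,

and reproduces each interval as the precision-weighted fusion of prior and
measurement,

    R_i = (1 - w) * mu_e + w * D_i,   w = sigma_e^2 / (sigma_e^2 + sigma_i^2),
    sigma_r^2 = sigma_i^2 * sigma_e^2 / (sigma_i^2 + sigma_e^2).

Fusion pulls reproductions toward mu_e, producing the central-tendency bias
(regression slope < 1 of reproduced on sample interval); larger k_j means a
noisier, more volatile-seeming sequence and a stronger pull.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .design import CONDITIONS, DESIGN_MEAN_MS, TrialSpec

__all__ = [
    "ObserverParams",
    "SequencePrediction",
    "DEFAULT_GROUP_PARAMS",
    "ensemble_prior",
    "sensory_variance",
    "integration_weight",
    "reproduce_expected",
    "reproduction_sd",
    "predict_sequence",
    "predict_table",
]


@dataclass(frozen=True)
class ObserverParams:
    """Observer parameters: Weber fractions, first-interval weight, volatility map.

    wf_s
        Sensory Weber fraction: measurement SD per unit duration (> 0).
    wf_p
        Prior Weber fraction: prior SD relative to the prior mean (> 0).
    alpha
        Weight of the first interval in the ensemble-prior mean, in [0, 1].
    k
        Volatility factor per sequence type (e.g. ``{"AS": 2.0, "DS": 2.4}``),
        each > 0; multiplies the sensory variance.
    """

    wf_s: float
    wf_p: float
    alpha: float
    k: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.wf_s > 0:
            raise ValueError(f"wf_s must be > 0, got {self.wf_s}")
        if not self.wf_p > 0:
            raise ValueError(f"wf_p must be > 0, got {self.wf_p}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        for cond, kj in self.k.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} in k")
            if not kj > 0:
                raise ValueError(f"k[{cond!r}] must be > 0, got {kj}")
        object.__setattr__(self, "k", dict(self.k))

    def with_k(self, **updates: float) -> "ObserverParams":
        k = dict(self.k)
        k.update(updates)
        return replace(self, k=k)


#: Group-level reference estimates for this paradigm, used as simulation defaults.
DEFAULT_GROUP_PARAMS = ObserverParams(
    wf_s=0.18, wf_p=0.35, alpha=0.195, k={"AS": 2.0, "DS": 2.4, "RS": 2.13}
)


def ensemble_prior(alpha: float, d1: float, anchor_ms: float = DESIGN_MEAN_MS) -> float:
    """Prior mean of the sequence: alpha * D1 + (1 - alpha) * design mean."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if d1 <= 0:
        raise ValueError("d1 must be positive")
    return alpha * d1 + anchor_ms * (1.0 - alpha)


def sensory_variance(wf_s: float, k_j: float, d_i: float) -> float:
    """Volatility-scaled Weber variance of one interval: k_j * (wf_s * D_i)^2."""
    if wf_s <= 0 or k_j <= 0 or d_i <= 0:
        raise ValueError("wf_s, k_j and d_i must all be positive")
    return k_j * (wf_s * d_i) ** 2


def integration_weight(sigma_i2: float, sigma_e2: float) -> float:
    """Reliability weight of the sensory measurement: sigma_e^2/(sigma_e^2+sigma_i^2)."""
    if sigma_i2 <= 0 or sigma_e2 <= 0:
        raise ValueError("variances must be positive")
    return sigma_e2 / (sigma_e2 + sigma_i2)


def reproduce_expected(mu_e: float, w: float, d_i: float) -> float:
    """Expected reproduction: convex combination (1 - w) * mu_e + w * D_i."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must be in [0, 1], got {w}")
    return (1.0 - w) * mu_e + w * d_i


def reproduction_sd(sigma_i: float, sigma_e: float) -> float:
    """Posterior SD of the fused estimate; never exceeds min(sigma_i, sigma_e)."""
    if sigma_i <= 0 or sigma_e <= 0:
        raise ValueError("SDs must be positive")
    si2, se2 = sigma_i**2, sigma_e**2
    return math.sqrt(si2 * se2 / (si2 + se2))


@dataclass(frozen=True)
class SequencePrediction:
    """Closed-form observer prediction for one presented sequence."""

    mu_e: float
    sigma_e: float
    d: tuple[float, ...]
    sigma: tuple[float, ...]
    w: tuple[float, ...]
    r: tuple[float, ...]
    sigma_r: tuple[float, ...]


def predict_sequence(params: ObserverParams, trial: TrialSpec) -> SequencePrediction:
    """Predicted reproduction mean and SD for each position of one trial."""
    if trial.condition not in params.k:
        raise ValueError(
            f"no volatility factor for condition {trial.condition!r} in params.k"
        )
    k_j = params.k[trial.condition]
    d = tuple(float(x) for x in trial.sample_ms)
    mu_e = ensemble_prior(params.alpha, d[0])
    sigma_e = params.wf_p * mu_e
    se2 = sigma_e**2
    sigma, w, r, sigma_r = [], [], [], []
    for d_i in d:
        si2 = sensory_variance(params.wf_s, k_j, d_i)
        w_i = integration_weight(si2, se2)
        sigma.append(math.sqrt(si2))
        w.append(w_i)
        r.append(reproduce_expected(mu_e, w_i, d_i))
        sigma_r.append(reproduction_sd(math.sqrt(si2), sigma_e))
    return SequencePrediction(
        mu_e=mu_e,
        sigma_e=sigma_e,
        d=d,
        sigma=tuple(sigma),
        w=tuple(w),
        r=tuple(r),
        sigma_r=tuple(sigma_r),
    )


def predict_table(params: ObserverParams, frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized forward model over a long-format trial table.

    Returns a copy with columns mu_e, sigma_i, w, r_pred and sigma_r added.
    Requires participant_id, trial, condition, position and sample_ms columns;
    every trial must include position 1 (source of the prior mean).
    """
    missing = {c for c in params_required_conditions(frame)} - set(params.k)
    if missing:
        raise ValueError(f"no volatility factor for condition(s) {sorted(missing)}")
    df = frame.copy()
    first = (
        df.loc[df["position"] == 1, ["participant_id", "trial", "sample_ms"]]
        .rename(columns={"sample_ms": "_d1"})
    )
    df = df.merge(first, on=["participant_id", "trial"], how="left", validate="m:1")
    if df["_d1"].isna().any():
        bad = df.loc[df["_d1"].isna(), ["participant_id", "trial"]].drop_duplicates()
        raise ValueError(f"trials missing position 1: {bad.to_dict('records')[:5]}")
    d = df["sample_ms"].to_numpy(float)
    d1 = df.pop("_d1").to_numpy(float)
    k = df["condition"].map(params.k).to_numpy(float)
    mu_e = params.alpha * d1 + DESIGN_MEAN_MS * (1.0 - params.alpha)
    se2 = (params.wf_p * mu_e) ** 2
    si2 = k * (params.wf_s * d) ** 2
    w = se2 / (se2 + si2)
    df["mu_e"] = mu_e
    df["sigma_i"] = np.sqrt(si2)
    df["w"] = w
    df["r_pred"] = (1.0 - w) * mu_e + w * d
    df["sigma_r"] = np.sqrt(si2 * se2 / (si2 + se2))
    return df


def params_required_conditions(frame: pd.DataFrame) -> set[str]:
    return set(frame["condition"].unique())
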