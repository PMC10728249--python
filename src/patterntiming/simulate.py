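"""Synthetic trial-level data with the statistical structure the analysis assumes.

Each participant gets a randomized 264-trial session (three sequence types x
two interval sets); reproduced intervals are drawn independently per position
from Normal(R_i, sigma_r_i) given by the observer model, truncated to positive
values by resampling.  Defaults emulate the study scale: 15 participants,
264 trials, observer parameters at the group-level reference estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import design
from .observer import DEFAULT_GROUP_PARAMS, ObserverParams, predict_table

__all__ = ["SimulationConfig", "simulate_dataset", "population_draw"]


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one synthetic dataset.

    ``truth`` is either a single ObserverParams applied to all participants or
    a sequence of per-participant ObserverParams; ``population_sd`` (optional)
    instead draws each participant's parameters from truncated normals around
    ``truth``.  ``noise_scale`` multiplies sigma_r at the sampling stage only
    (0 or tiny values give noiseless data for pipeline checks).
    """

    master_seed: int
    n_participants: int = 15
    n_trials: int = design.TRIALS_PER_SESSION
    truth: ObserverParams | Sequence[ObserverParams] = DEFAULT_GROUP_PARAMS
    population_sd: Optional[object] = None  # ObserverParams or dict of SDs
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def _truncnorm_draws(
    mean: float, sd: float, low: float, high: float, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Truncated-normal draws by resampling (no point mass at the bounds)."""
    if sd < 0:
        raise ValueError("population SD must be >= 0")
    if sd == 0:
        return np.full(size, float(mean))
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw > low) & (draw < high)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _sd_dict(pop_sd) -> dict:
    """Accept SDs either as an ObserverParams-shaped dict or ObserverParams."""
    if isinstance(pop_sd, ObserverParams):
        return {"wf_s": pop_sd.wf_s, "wf_p": pop_sd.wf_p, "alpha": pop_sd.alpha,
                "k": dict(pop_sd.k)}
    d = dict(pop_sd)
    d.setdefault("k", {})
    return d


def population_draw(
    pop_mean: ObserverParams,
    pop_sd,
    rng_seed,
    size: Optional[int] = None,
):
    """Draw observer parameters from independent truncated normals.

    Weber fractions and volatility factors are truncated to (0, inf), alpha to
    [0, 1].  ``pop_sd`` holds the population SDs, either as an ObserverParams
    or as a plain dict ``{"wf_s": ..., "wf_p": ..., "alpha": ..., "k": {...}}``
    (a dict permits exact-zero SDs, which return the mean exactly).  Returns
    one ObserverParams, or a list of ``size`` when given.
    """
    sd = _sd_dict(pop_sd)
    rng = design._as_rng(rng_seed)
    n = 1 if size is None else int(size)
    wf_s = _truncnorm_draws(pop_mean.wf_s, sd.get("wf_s", 0.0), 0.0, np.inf, rng, n)
    wf_p = _truncnorm_draws(pop_mean.wf_p, sd.get("wf_p", 0.0), 0.0, np.inf, rng, n)
    alpha = _truncnorm_draws(pop_mean.alpha, sd.get("alpha", 0.0), 0.0, 1.0, rng, n)
    # alpha bounds are attainable values; sd=0 path returns the mean exactly,
    # and resampling treats [0,1] as open, which is measure-equivalent.
    ks = {
        cond: _truncnorm_draws(pop_mean.k[cond], sd["k"].get(cond, 0.0), 0.0, np.inf, rng, n)
        for cond in pop_mean.k
    }
    draws = [
        ObserverParams(
            wf_s=float(wf_s[i]),
            wf_p=float(wf_p[i]),
            alpha=float(min(max(alpha[i], 0.0), 1.0)),
            k={c: float(v[i]) for c, v in ks.items()},
        )
        for i in range(n)
    ]
    return draws[0] if size is None else draws


def _sample_reproductions(
    r: np.ndarray, sd: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Normal draws truncated to > 0 by resampling (no point mass at zero)."""
    out = r + sd * rng.standard_normal(r.size)
    bad = np.flatnonzero(out <= 0)
    while bad.size:
        out[bad] = r[bad] + sd[bad] * rng.standard_normal(bad.size)
        bad = bad[out[bad] <= 0]
    return out


def simulate_dataset(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate one synthetic dataset and its reproducibility metadata.

    Returns the long-format trial table (design columns + reproduced_ms) and a
    metadata dict recording the master seed, per-participant seeds and true
    parameters.
    """
    ss = np.random.SeedSequence(cfg.master_seed)
    children = ss.spawn(cfg.n_participants)
    if isinstance(cfg.truth, ObserverParams):
        truths = [cfg.truth] * cfg.n_participants
    else:
        truths = list(cfg.truth)
        if len(truths) != cfg.n_participants:
            raise ValueError("per-participant truth list length != n_participants")

    frames = []
    meta_participants = []
    for p_idx, child in enumerate(children):
        pid = f"P{p_idx + 1:02d}"
        session_rng, noise_rng, param_rng = (
            np.random.default_rng(s) for s in child.spawn(3)
        )
        truth = truths[p_idx]
        if cfg.population_sd is not None:
            truth = population_draw(truth, cfg.population_sd, param_rng)
        trials = design.generate_session(pid, session_rng, n_trials=cfg.n_trials)
        frame = design.trials_to_frame(trials)
        pred = predict_table(truth, frame)
        sd = cfg.noise_scale * pred["sigma_r"].to_numpy(float)
        r = pred["r_pred"].to_numpy(float)
        if cfg.noise_scale == 0:
            reproduced = r.copy()
        else:
            reproduced = _sample_reproductions(r, sd, noise_rng)
        frame = frame.assign(reproduced_ms=reproduced)
        frames.append(frame)
        meta_participants.append(
            {
                "participant_id": pid,
                "truth": _params_dict(truth),
                "seed_state": child.entropy if isinstance(child.entropy, int) else None,
            }
        )
    table = pd.concat(frames, ignore_index=True)
    meta = {
        "master_seed": cfg.master_seed,
        "n_participants": cfg.n_participants,
        "n_trials": cfg.n_trials,
        "noise_scale": cfg.noise_scale,
        "participants": meta_participants,
    }
    return table, meta


def _params_dict(p: ObserverParams) -> dict:
    return {"wf_s": p.wf_s, "wf_p": p.wf_p, "alpha": p.alpha, "k": dict(p.k)}
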