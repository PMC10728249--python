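"""Two-stage estimation of observer parameters from trial data.

Stage 1 ("structured") fits wf_s, wf_p, alpha and the volatility factors
k_AS, k_DS to a participant's AS and DS trials; stage 2 ("rs") freezes those
shared parameters at their stage-1 point estimates and fits only k_RS to the
random-sequence trials.  The likelihood treats each reproduced interval as an
independent Normal draw with mean R_i and SD sigma_r_i from the observer
model.  Point estimates come from a seeded multi-start MAP optimizer
(default) or from affine-invariant ensemble MCMC (emcee) with split-R-hat
diagnostics; weakly informative, support-respecting priors regularize the fit
(half-normal(0.5) on Weber fractions, uniform(0,1) on alpha, half-normal(3)
on volatility factors).

Note on identifiability: the likelihood depends on wf_s and k_j only through
the products k_j * wf_s^2, so when every fitted condition carries a free k_j
the split between wf_s and the k_j is resolved by the priors, not the data.
The products, alpha and wf_p are data-identified.  See docs/methods.md.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .observer import ObserverParams, predict_table

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "FitSettings",
    "log_likelihood",
    "fit_structured",
    "fit_rs",
    "two_stage_fit",
    "predictions_frame",
    "goodness_r2",
]

_LOG2PI = math.log(2.0 * math.pi)

# prior scales (support-respecting, weakly informative)
_WF_PRIOR_SCALE = 0.5
_K_PRIOR_SCALE = 3.0

_BOUNDS = {
    "wf_s": (1e-4, 3.0),
    "wf_p": (1e-4, 3.0),
    "alpha": (0.0, 1.0),
    "k": (1e-3, 30.0),
}

_RHAT_LIMIT = 1.05


@dataclass(frozen=True)
class FitSettings:
    """Estimator settings; ``estimator`` is "map" or "mcmc"."""

    estimator: str = "map"
    seed: int = 0
    draws: int = 600
    walkers: int = 16
    n_starts: int = 3

    def __post_init__(self) -> None:
        if self.estimator not in ("map", "mcmc"):
            raise ValueError("estimator must be 'map' or 'mcmc'")


@dataclass
class FitResult:
    """Per-participant estimates from one fitting stage."""

    participant_id: str
    stage: str  # "structured" or "rs"
    estimates: dict[str, float]
    sd: dict[str, Optional[float]]
    log_likelihood: float
    r2: Optional[dict[str, float]] = None
    diagnostics: dict = field(default_factory=dict)

    def params(self, base: Optional[ObserverParams] = None) -> ObserverParams:
        """Materialize ObserverParams from the estimates (merging ``base``'s k)."""
        k = dict(base.k) if base is not None else {}
        est = self.estimates
        for name, v in est.items():
            if name.startswith("k_"):
                k[name[2:]] = v
        return ObserverParams(
            wf_s=est.get("wf_s", base.wf_s if base else None),
            wf_p=est.get("wf_p", base.wf_p if base else None),
            alpha=est.get("alpha", base.alpha if base else None),
            k=k,
        )


# ---------------------------------------------------------------- likelihood


def _pack(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    """Precompute arrays for fast repeated likelihood evaluation."""
    df = frame
    first = (
        df.loc[df["position"] == 1, ["participant_id", "trial", "sample_ms"]]
        .rename(columns={"sample_ms": "_d1"})
    )
    df = df.merge(first, on=["participant_id", "trial"], how="left", validate="m:1")
    if df["_d1"].isna().any():
        raise ValueError("every trial must include position 1")
    conds = sorted(df["condition"].unique())
    return {
        "d": df["sample_ms"].to_numpy(float),
        "d1": df["_d1"].to_numpy(float),
        "y": df["reproduced_ms"].to_numpy(float),
        "cond_idx": df["condition"].map({c: i for i, c in enumerate(conds)}).to_numpy(int),
        "conds": conds,
    }


def _loglik_packed(
    packed: dict, wf_s: float, wf_p: float, alpha: float, k_by_cond: np.ndarray
) -> float:
    d, d1, y = packed["d"], packed["d1"], packed["y"]
    k = k_by_cond[packed["cond_idx"]]
    mu_e = alpha * d1 + 700.0 * (1.0 - alpha)
    se2 = (wf_p * mu_e) ** 2
    si2 = k * (wf_s * d) ** 2
    w = se2 / (se2 + si2)
    r = (1.0 - w) * mu_e + w * d
    var_r = si2 * se2 / (si2 + se2)
    if not np.all(var_r > 0):
        raise ValueError("degenerate reproduction variance (sigma_r = 0)")
    resid = y - r
    return float(-0.5 * np.sum(_LOG2PI + np.log(var_r) + resid**2 / var_r))


def log_likelihood(params: ObserverParams, frame: pd.DataFrame) -> float:
    """Gaussian log-likelihood of reproduced intervals under the observer model."""
    if frame.empty:
        raise ValueError("trials must be non-empty")
    packed = _pack(frame)
    missing = set(packed["conds"]) - set(params.k)
    if missing:
        raise ValueError(f"no volatility factor for condition(s) {sorted(missing)}")
    k = np.array([params.k[c] for c in packed["conds"]])
    return _loglik_packed(packed, params.wf_s, params.wf_p, params.alpha, k)


def _log_prior_wf(x: float) -> float:
    return -0.5 * (x / _WF_PRIOR_SCALE) ** 2


def _log_prior_k(x: float) -> float:
    return -0.5 * (x / _K_PRIOR_SCALE) ** 2


# ---------------------------------------------------------------- stage fits


def _check_single_participant(frame: pd.DataFrame) -> str:
    pids = frame["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"expected a single participant, got {len(pids)}")
    return str(pids[0])


def _map_optimize(
    neg_log_post, x0_list: Sequence[np.ndarray], bounds
) -> optimize.OptimizeResult:
    best = None
    for x0 in x0_list:
        res = optimize.minimize(
            neg_log_post, x0, method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def _map_se(res: optimize.OptimizeResult) -> list[Optional[float]]:
    """Approximate posterior SDs from the L-BFGS-B inverse-Hessian estimate."""
    try:
        h = res.hess_inv.todense()
        d = np.diag(h)
        return [math.sqrt(v) if v > 0 else None for v in d]
    except Exception:  # pragma: no cover - defensive
        return [None] * len(res.x)


def _run_mcmc(log_post, x0: np.ndarray, bounds, settings: FitSettings):
    import arviz as az
    import emcee

    ndim = len(x0)
    nwalk = max(settings.walkers, 2 * ndim + 2)
    rng = np.random.default_rng(settings.seed + 1)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    p0 = np.clip(
        x0 + 1e-2 * np.abs(x0 + 0.1) * rng.standard_normal((nwalk, ndim)),
        lo + 1e-6,
        hi - 1e-6,
    )

    def bounded_log_post(x):
        if np.any(x <= lo) or np.any(x >= hi):
            return -np.inf
        return log_post(x)

    sampler = emcee.EnsembleSampler(nwalk, ndim, bounded_log_post)
    state = sampler.run_mcmc(p0, settings.draws, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=settings.draws // 2)  # (draw, walker, dim)
    flat = chain.reshape(-1, ndim)
    rhat = [
        float(az.rhat(np.asarray(chain[:, :, j].T)))  # (chain, draw)
        for j in range(ndim)
    ]
    return flat.mean(axis=0), flat.std(axis=0, ddof=1), max(rhat)


def fit_structured(
    frame: pd.DataFrame, settings: FitSettings = FitSettings()
) -> FitResult:
    """Fit wf_s, wf_p, alpha, k_AS, k_DS to one participant's AS + DS trials."""
    pid = _check_single_participant(frame)
    df = frame.loc[frame["condition"].isin(["AS", "DS"])]
    present = set(df["condition"].unique())
    if present != {"AS", "DS"}:
        raise ValueError(f"need both AS and DS trials, found {sorted(present)}")
    packed = _pack(df)
    i_as, i_ds = packed["conds"].index("AS"), packed["conds"].index("DS")
    names = ["wf_s", "wf_p", "alpha", "k_AS", "k_DS"]
    bounds = [_BOUNDS["wf_s"], _BOUNDS["wf_p"], _BOUNDS["alpha"], _BOUNDS["k"], _BOUNDS["k"]]

    def log_post(x: np.ndarray) -> float:
        wf_s, wf_p, alpha, k_as, k_ds = x
        k = np.empty(2)
        k[i_as], k[i_ds] = k_as, k_ds
        ll = _loglik_packed(packed, wf_s, wf_p, alpha, k)
        return (
            ll
            + _log_prior_wf(wf_s)
            + _log_prior_wf(wf_p)
            + _log_prior_k(k_as)
            + _log_prior_k(k_ds)
        )

    neg = lambda x: -log_post(x)
    rng = np.random.default_rng(settings.seed)
    base = np.array([0.2, 0.3, 0.2, 1.5, 1.5])
    starts = [base] + [
        np.clip(base * rng.uniform(0.5, 2.0, size=5), 1e-3, [2.9, 2.9, 0.99, 29, 29])
        for _ in range(settings.n_starts - 1)
    ]
    res = _map_optimize(neg, starts, bounds)
    est = dict(zip(names, (float(v) for v in res.x)))
    diagnostics: dict = {"converged": bool(res.success), "estimator": settings.estimator}
    if settings.estimator == "map":
        sd = dict(zip(names, _map_se(res)))
        loglik = _loglik_from_est(packed, est, i_as, i_ds)
    else:
        mean, sd_arr, rhat = _run_mcmc(log_post, res.x, bounds, settings)
        est = dict(zip(names, (float(v) for v in mean)))
        sd = dict(zip(names, (float(v) for v in sd_arr)))
        diagnostics["rhat"] = rhat
        diagnostics["divergences"] = None  # not a concept in ensemble MCMC
        if rhat > _RHAT_LIMIT:
            diagnostics["converged"] = False
            logger.warning("participant %s: max R-hat %.3f > %.2f", pid, rhat, _RHAT_LIMIT)
        loglik = _loglik_from_est(packed, est, i_as, i_ds)
    return FitResult(
        participant_id=pid,
        stage="structured",
        estimates=est,
        sd=sd,
        log_likelihood=loglik,
        diagnostics=diagnostics,
    )


def _loglik_from_est(packed, est: dict, i_as: int, i_ds: int) -> float:
    k = np.empty(2)
    k[i_as], k[i_ds] = est["k_AS"], est["k_DS"]
    return _loglik_packed(packed, est["wf_s"], est["wf_p"], est["alpha"], k)


def fit_rs(
    frame: pd.DataFrame,
    frozen: FitResult,
    settings: FitSettings = FitSettings(),
) -> FitResult:
    """Fit k_RS to one participant's RS trials with shared parameters frozen.

    ``frozen`` must be a stage-"structured" result; its wf_s, wf_p and alpha
    point estimates are held fixed and never modified.
    """
    pid = _check_single_participant(frame)
    if frozen.stage != "structured":
        raise ValueError("frozen must be a stage-'structured' FitResult")
    df = frame.loc[frame["condition"] == "RS"]
    if df.empty:
        raise ValueError("no RS trials")
    packed = _pack(df)
    wf_s = frozen.estimates["wf_s"]
    wf_p = frozen.estimates["wf_p"]
    alpha = frozen.estimates["alpha"]

    def log_post(x: np.ndarray) -> float:
        (k_rs,) = x
        return _loglik_packed(packed, wf_s, wf_p, alpha, np.array([k_rs])) + _log_prior_k(
            k_rs
        )

    neg = lambda x: -log_post(np.atleast_1d(x))
    bounds = [_BOUNDS["k"]]
    starts = [np.array([1.0]), np.array([3.0])]
    res = _map_optimize(neg, starts, bounds)
    diagnostics: dict = {"converged": bool(res.success), "estimator": settings.estimator}
    if settings.estimator == "map":
        est = {"k_RS": float(res.x[0])}
        sd = {"k_RS": _map_se(res)[0]}
    else:
        mean, sd_arr, rhat = _run_mcmc(log_post, res.x, bounds, settings)
        est = {"k_RS": float(mean[0])}
        sd = {"k_RS": float(sd_arr[0])}
        diagnostics["rhat"] = rhat
        diagnostics["divergences"] = None
        if rhat > _RHAT_LIMIT:
            diagnostics["converged"] = False
    loglik = _loglik_packed(packed, wf_s, wf_p, alpha, np.array([est["k_RS"]]))
    return FitResult(
        participant_id=pid,
        stage="rs",
        estimates=est,
        sd=sd,
        log_likelihood=loglik,
        diagnostics=diagnostics,
    )


def two_stage_fit(
    frame: pd.DataFrame, settings: FitSettings = FitSettings()
) -> dict[str, list[FitResult]]:
    """Run both stages for every participant; returns {"structured": [...], "rs": [...]}."""
    structured, rs = [], []
    for offset, (pid, g) in enumerate(frame.groupby("participant_id", sort=True)):
        st = FitSettings(
            estimator=settings.estimator,
            seed=settings.seed + offset,
            draws=settings.draws,
            walkers=settings.walkers,
            n_starts=settings.n_starts,
        )
        s = fit_structured(g, st)
        structured.append(s)
        rs.append(fit_rs(g, s, st))
    return {"structured": structured, "rs": rs}


# ---------------------------------------------------------------- goodness


def combined_params(structured: FitResult, rs: FitResult) -> ObserverParams:
    """Merge both stages into one ObserverParams (k_AS, k_DS, k_RS)."""
    est = structured.estimates
    return ObserverParams(
        wf_s=est["wf_s"],
        wf_p=est["wf_p"],
        alpha=est["alpha"],
        k={"AS": est["k_AS"], "DS": est["k_DS"], "RS": rs.estimates["k_RS"]},
    )


def predictions_frame(
    frame: pd.DataFrame, fits: dict[str, list[FitResult]]
) -> pd.DataFrame:
    """Mean observed vs fitted-model-predicted reproduction per sample interval.

    Returns one row per participant x condition x sample interval with the
    mean observed and mean predicted reproduction, using each participant's
    own fitted parameters.
    """
    by_pid = {
        s.participant_id: combined_params(s, r)
        for s, r in zip(fits["structured"], fits["rs"])
    }
    parts = []
    for pid, g in frame.groupby("participant_id", sort=True):
        pred = predict_table(by_pid[str(pid)], g)
        agg = (
            pred.groupby(["participant_id", "condition", "sample_ms"], sort=True)
            .agg(observed_mean=("reproduced_ms", "mean"), predicted_mean=("r_pred", "mean"))
            .reset_index()
        )
        parts.append(agg)
    return pd.concat(parts, ignore_index=True)


def goodness_r2(pred_obs: pd.DataFrame) -> dict[str, float]:
    """Per-condition R^2 between predicted and observed per-interval means.

    Squared Pearson correlation over each participant's per-sample-interval
    means, averaged across participants within each condition.  Constant
    vectors (zero variance) are rejected.
    """
    out: dict[str, list[float]] = {}
    for (pid, cond), g in pred_obs.groupby(["participant_id", "condition"], sort=True):
        x = g["predicted_mean"].to_numpy(float)
        y = g["observed_mean"].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(
                f"constant prediction or observation vector for {pid}/{cond}"
            )
        r = np.corrcoef(x, y)[0, 1]
        out.setdefault(str(cond), []).append(float(r**2))
    return {cond: float(np.mean(v)) for cond, v in out.items()}


def fits_to_frame(fits: dict[str, list[FitResult]]) -> pd.DataFrame:
    """Tidy frame: one row per participant x stage x parameter."""
    rows = []
    for stage in ("structured", "rs"):
        for f in fits[stage]:
            for name, v in f.estimates.items():
                rows.append(
                    {
                        "participant_id": f.participant_id,
                        "stage": stage,
                        "parameter": name,
                        "estimate": v,
                        "sd": f.sd.get(name),
                        "log_likelihood": f.log_likelihood,
                        "converged": f.diagnostics.get("converged"),
                        "rhat": f.diagnostics.get("rhat"),
                    }
                )
    return pd.DataFrame(rows)
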