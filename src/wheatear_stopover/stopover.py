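"""Monte Carlo stopover-duration estimation from a fitted departure model.

A bird's observed (minimum) stopover spans first capture to last detection,
but the true stopover extends to the unobserved departure night.  Given
posterior draws of the staging-model coefficients, each draw predicts a
nightly departure probability 1 - Phi for every day after the last
observation; simulating the departure night over draws yields a posterior
distribution of the individual's stopover duration, and averaging across
individuals a posterior of the population mean.

Covariates beyond the study window are extended by an explicit rule: weather
columns carry their last observed value, the centered study day continues
linearly, and evening fuel load follows the imputation model's per-bird
trajectory, capped at a physiological ceiling (default 1.3, the most extreme
fuel load on record for the species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cjs import DesignMatrices, EflImputationModel, Model, _sigmoid

__all__ = [
    "StopoverEstimate",
    "minimum_stopover",
    "extend_phi_design",
    "simulate_stopover",
    "summarize_stopover",
]


@dataclass
class StopoverEstimate:
    """Per-bird and population stopover-duration summaries."""

    per_bird: pd.DataFrame  # ring_id, min_stopover_days, mean, se, cri_low, cri_high
    population_mean: float
    population_se: float  # SD of the posterior of the population mean
    population_cri: tuple[float, float]
    across_bird_se: float  # SD of per-bird means / sqrt(n_birds)
    n_truncated: int


def minimum_stopover(detections: np.ndarray) -> int:
    """Minimum stopover duration in days, including the capture day.

    ``detections`` is a binary encounter row; the duration is last detected
    day minus first detected day plus one (gaps tolerated).
    """
    days = np.flatnonzero(np.asarray(detections))
    if days.size == 0:
        raise ValueError("need at least the capture-day detection")
    return int(days[-1] - days[0] + 1)


def extend_phi_design(
    design: DesignMatrices,
    model: Model,
    horizon_days: int = 30,
    efl_model: EflImputationModel | None = None,
    efl_cap: float = 1.3,
) -> np.ndarray:
    """Staging design tensor extended to ``horizon_days`` after each arrival.

    Returns an (N, T_ext, 9) array where T_ext covers the latest horizon.
    Weather covariates carry the last study-day value; day.c continues its
    linear trend; daysa keeps counting; efl follows ``efl_model``'s per-bird
    trajectory (required for the efl model), capped at ``efl_cap``.
    """
    hist = design.history
    N, T = hist.Y.shape
    T_ext = int(max(hist.first + horizon_days + 1))
    if T_ext <= T:
        return design.phi_design(model)
    if model == "with_efl" and efl_model is None:
        raise ValueError("efl model needed to extend evening fuel loads")
    t_grid = np.arange(T_ext)
    daysa = np.where(t_grid >= hist.first[:, None], t_grid - hist.first[:, None] + 1, 0.0)
    indfirst = (t_grid == hist.first[:, None]).astype(float)
    day_c = np.concatenate([design.day_c, design.day_c[-1] + np.arange(1, T_ext - T + 1)])
    temp = np.concatenate([design.temp_z, np.full(T_ext - T, design.temp_z[-1])])
    wind = np.concatenate([design.wind_z, np.full(T_ext - T, design.wind_z[-1])])
    twc = np.concatenate([design.twc_z, np.full(T_ext - T, design.twc_z[-1])])
    ones = np.ones((N, T_ext))
    day_c_b = np.broadcast_to(day_c, (N, T_ext))
    temp_b = np.broadcast_to(temp, (N, T_ext))
    wind_b = np.broadcast_to(wind, (N, T_ext))
    twc_b = np.broadcast_to(twc, (N, T_ext))
    if model == "with_afl":
        afl = np.broadcast_to(design.afl_z[:, None], (N, T_ext))
        cols = [ones, daysa, day_c_b, afl, temp_b, wind_b, twc_b, indfirst, afl * day_c_b]
    else:
        efl = np.full((N, T_ext), np.nan)
        efl[:, :T] = design.efl
        for i in range(N):
            for t in range(hist.first[i], T_ext):
                if not np.isfinite(efl[i, t]):
                    efl[i, t] = efl_model.predict(i, t - hist.first[i] + 1.0)
        efl = np.where(t_grid >= hist.first[:, None], np.minimum(efl, efl_cap), 0.0)
        cols = [ones, daysa, day_c_b, temp_b, wind_b, twc_b, indfirst, efl, efl * day_c_b]
    return np.stack(cols, axis=-1)


def simulate_stopover(
    design: DesignMatrices,
    draws: np.ndarray,
    model: Model = "with_efl",
    n_sim: int = 2000,
    horizon_days: int = 30,
    efl_model: EflImputationModel | None = None,
    efl_cap: float = 1.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate stopover durations for every bird.

    For each of ``n_sim`` replicates a posterior draw of the staging
    coefficients is taken (cycled through ``draws``), the bird is carried from
    its last observation day forward, departing after day t with probability
    1 - Phi(t), and the duration (days from arrival through the day of the
    departure night, inclusive) is recorded.  Birds still present at the
    horizon are truncated there and counted.

    Returns ``(durations, truncated)``: arrays of shape (n_birds, n_sim).
    """
    rng = np.random.default_rng(seed)
    hist = design.history
    N, T = hist.Y.shape
    X = extend_phi_design(design, model, horizon_days, efl_model, efl_cap)
    T_ext = X.shape[1]
    flat = draws.reshape(-1, draws.shape[-1]) if draws.ndim == 3 else draws
    idx = np.arange(n_sim) % len(flat)
    alpha = flat[idx, :9]  # (n_sim, 9)
    phi = _sigmoid(np.einsum("sk,ntk->snt", alpha, X))  # (n_sim, N, T_ext)

    last_obs = np.array([np.flatnonzero(hist.Y[i])[-1] for i in range(N)])
    # departure forced on the horizon day, so durations never exceed
    # horizon_days counted from (and including) the arrival day
    horizon_day = hist.first + horizon_days - 1
    durations = np.zeros((N, n_sim), dtype=float)
    truncated = np.zeros((N, n_sim), dtype=bool)
    u = rng.random((n_sim, N, T_ext))
    for i in range(N):
        depart = u[:, i, :] >= phi[:, i, :]  # departs after day t
        depart[:, : last_obs[i]] = False  # present through last observation
        cap = min(horizon_day[i], T_ext - 1)
        depart[:, cap:] = True  # force truncation at horizon
        day = np.argmax(depart, axis=1)
        trunc = day >= cap
        durations[i] = day - hist.first[i] + 1
        truncated[i] = trunc
    n_trunc = int(truncated.sum())
    if n_trunc:
        warnings.warn(
            f"{n_trunc} of {N * n_sim} stopover draws truncated at the "
            f"{horizon_days}-day horizon"
        )
    return durations, truncated


def summarize_stopover(
    durations: np.ndarray,
    history_Y: np.ndarray,
    ring_ids: list,
    truncated: np.ndarray | None = None,
) -> StopoverEstimate:
    """Summarize per-bird duration draws and the population mean.

    The population SE is the posterior SD of the across-bird mean (computed
    per simulation replicate); the across-bird SE (SD of per-bird posterior
    means over sqrt(n)) is also reported since either convention appears in
    field studies.
    """
    N, n_sim = durations.shape
    rows = []
    for i in range(N):
        d = durations[i]
        rows.append(
            {
                "ring_id": ring_ids[i],
                "min_stopover_days": minimum_stopover(history_Y[i]),
                "mean": float(d.mean()),
                "se": float(d.std(ddof=1)) if n_sim > 1 else 0.0,
                "cri_low": float(np.quantile(d, 0.025)),
                "cri_high": float(np.quantile(d, 0.975)),
            }
        )
    per_bird = pd.DataFrame(rows)
    pop_draws = durations.mean(axis=0)  # posterior of the population mean
    pop_mean = float(pop_draws.mean())
    pop_se = float(pop_draws.std(ddof=1)) if n_sim > 1 else 0.0
    cri = (float(np.quantile(pop_draws, 0.025)), float(np.quantile(pop_draws, 0.975)))
    across = float(per_bird["mean"].std(ddof=1) / np.sqrt(N)) if N > 1 else 0.0
    return StopoverEstimate(
        per_bird=per_bird,
        population_mean=pop_mean,
        population_se=pop_se,
        population_cri=cri,
        across_bird_se=across,
        n_truncated=int(truncated.sum()) if truncated is not None else 0,
    )
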