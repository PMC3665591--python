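"""Shared fixtures: a small synthetic study, its design matrices, and the
brute-force latent-state enumeration oracle for the CJS likelihood."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wheatear_stopover import solarwind
from wheatear_stopover.cjs import build_design, impute_efl
from wheatear_stopover.energetics import build_fuel_profiles, evening_fuel_loads
from wheatear_stopover.synthdata import SimulationConfig, simulate_study

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def enumerate_loglik(Y: np.ndarray, first: np.ndarray, phi: np.ndarray, p: np.ndarray) -> float:
    """Brute-force marginal likelihood: sum over all latent departure days.

    A bird present on days first..d (then absent) contributes the product of
    staying probabilities up to d, a departure factor if it leaves before the
    study end, and detection factors on present days (absent days must be
    undetected).  Independent oracle for the forward recursion, O(T) terms
    per bird but evaluated term by term.
    """
    N, T = Y.shape
    total = 0.0
    for i in range(N):
        f = first[i]
        L = 0.0
        for d in range(f, T):  # d = last day present
            term = 1.0
            for t in range(f, d):
                term *= phi[i, t]
            if d < T - 1:
                term *= 1.0 - phi[i, d]
            for t in range(f + 1, T):
                if t <= d:
                    term *= p[i, t] if Y[i, t] else 1.0 - p[i, t]
                elif Y[i, t]:
                    term = 0.0
            L += term
        total += np.log(L) if L > 0 else -np.inf
    return total


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(SimulationConfig(n_birds=40, n_days=21, seed=42))


@pytest.fixture(scope="session")
def wales_sunsets(small_study):
    cfg = small_study.config
    days = sorted(pd.to_datetime(small_study.covariates["date"]).dt.date)
    return {d: solarwind.sun_events(cfg.lat, cfg.lon, d).sunset_utc for d in days}


@pytest.fixture(scope="session")
def small_designs(small_study, wales_sunsets):
    """(design_without_efl, design_with_efl, efl_model) from the small study."""
    study = small_study
    profiles = build_fuel_profiles(study.birds, study.masses, wales_sunsets)
    efl_long = evening_fuel_loads(study.birds, study.masses, wales_sunsets)
    with_efl = set(efl_long["ring_id"])
    enc = study.encounters
    d1 = build_design(
        enc[~enc["ring_id"].isin(with_efl)], study.birds, profiles, study.covariates
    )
    d2 = build_design(
        enc[enc["ring_id"].isin(with_efl)], study.birds, profiles,
        study.covariates, efl=efl_long,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        completed, efl_model = impute_efl(d2.efl, d2.history.first)
    active = np.arange(d2.efl.shape[1]) >= d2.history.first[:, None]
    d2.efl = np.nan_to_num(np.where(active, completed, 0.0))
    return d1, d2, efl_model
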