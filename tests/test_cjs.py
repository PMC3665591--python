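import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import enumerate_loglik
from wheatear_stopover.cjs import (
    CoefficientSet,
    CovariateGapError,
    JoinError,
    MCMCConfig,
    NormalPriors,
    build_design,
    detection_probability,
    encounter_loglik,
    fit_model,
    forward_loglik,
    impute_efl,
    resight_probability,
    staging_probability,
)

#: Published posterior means of the evening-fuel-load staging model and its
#: detection submodel, used here as a reference coefficient set.
EFL_MODEL_MEANS = CoefficientSet(
    alpha=[4.500, -0.474, -0.108, 0.787, -0.118, 0.236, -0.830, -3.915, 0.328],
    beta=[2.946, 30.796, -0.143],
)


def _toy_tables(n_days=5):
    dates = pd.date_range("2010-08-11", periods=n_days).date
    birds = pd.DataFrame(
        {
            "ring_id": ["A", "B"],
            "first_capture_date": [dates[0].isoformat(), dates[2].isoformat()],
            "radio_tagged": [True, False],
        }
    )
    rows = []
    Y = {"A": [1, 0, 1, 0, 0], "B": [0, 0, 1, 1, 1]}
    for r, ys in Y.items():
        for d, y in zip(dates, ys):
            rows.append({"ring_id": r, "date": d.isoformat(), "detected": y})
    enc = pd.DataFrame(rows)
    fp = pd.DataFrame({"ring_id": ["A", "B"], "afl": [0.15, 0.30]})
    cov = pd.DataFrame(
        {
            "date": [d.isoformat() for d in dates],
            "temp_surface_C": [5.0, 6.0, 7.0, 6.5, 4.0],
            "wind_surface_ms": [3.0, 8.0, 2.0, 5.0, 6.0],
            "twc_midnight_ms": [1.0, -2.0, 0.5, 3.0, -1.0],
        }
    )
    return enc, birds, fp, cov


class TestBuildDesign:
    def test_arrival_day_coding(self):
        enc, birds, fp, cov = _toy_tables()
        d = build_design(enc, birds, fp, cov)
        i = d.history.ring_ids.index("B")
        f = d.history.first[i]
        assert d.daysa[i, f] == 1 and d.indfirst[i, f] == 1
        assert d.indfirst[i].sum() == 1
        assert d.daysa[i, f + 1] == 2

    def test_zero_variance_covariate_warns_and_zeroes(self):
        enc, birds, fp, cov = _toy_tables()
        cov["temp_surface_C"] = 5.0
        with pytest.warns(UserWarning, match="zero variance"):
            d = build_design(enc, birds, fp, cov)
        assert np.all(d.temp_z == 0)

    def test_day_centering_spans_study(self):
        dates = pd.date_range("2010-08-11", periods=21).date
        enc = pd.DataFrame(
            {"ring_id": "A", "date": [d.isoformat() for d in dates], "detected": 1}
        )
        birds = pd.DataFrame(
            {"ring_id": ["A"], "first_capture_date": [dates[0].isoformat()],
             "radio_tagged": [False]}
        )
        fp = pd.DataFrame({"ring_id": ["A"], "afl": [0.2]})
        rng = np.random.default_rng(0)
        cov = pd.DataFrame(
            {"date": [d.isoformat() for d in dates],
             "temp_surface_C": rng.normal(6, 2, 21),
             "wind_surface_ms": rng.gamma(2, 2, 21),
             "twc_midnight_ms": rng.normal(0, 2, 21)}
        )
        d = build_design(enc, birds, fp, cov)
        assert d.day_c[0] == -10 and d.day_c[-1] == 10
        assert abs(d.temp_z.mean()) < 1e-9 and d.temp_z.std() == pytest.approx(1.0)

    def test_covariate_gap_and_unknown_ring_errors(self):
        enc, birds, fp, cov = _toy_tables()
        with pytest.raises(CovariateGapError):
            build_design(enc, birds, fp, cov.iloc[:3])
        enc2 = pd.concat([enc, pd.DataFrame([{"ring_id": "ZZ", "date": "2010-08-11", "detected": 1}])])
        with pytest.raises(JoinError):
            build_design(enc2, birds, fp, cov)


class TestProbabilityModels:
    def test_high_fuel_bird_departs_with_published_coefficients(self):
        # staying odds on day 5 since arrival with a full fuel store: about
        # four in five birds leave that night
        phi = staging_probability(
            EFL_MODEL_MEANS, {"daysa": 5, "efl": 1.0}, model="with_efl"
        )
        assert 1.0 - phi == pytest.approx(0.86, abs=0.01)

    def test_null_coefficients_give_half(self):
        null = CoefficientSet(alpha=np.zeros(9), beta=np.zeros(3))
        assert staging_probability(null, {"daysa": 3, "efl": 0.5}, "with_efl") == 0.5
        assert detection_probability(null, True, 1.2) == 0.5

    def test_staging_signs_match_reported_effects(self):
        base = {"daysa": 5, "efl": 0.5, "temp.z": 0.0}
        phi0 = staging_probability(EFL_MODEL_MEANS, base, "with_efl")
        assert staging_probability(EFL_MODEL_MEANS, {**base, "efl": 0.8}, "with_efl") < phi0
        assert staging_probability(EFL_MODEL_MEANS, {**base, "daysa": 8}, "with_efl") < phi0
        assert staging_probability(EFL_MODEL_MEANS, {**base, "temp.z": 1.0}, "with_efl") > phi0

    def test_detection_probabilities(self):
        assert detection_probability(EFL_MODEL_MEANS, True) > 0.99
        # colour-ringed detection from the arrival-fuel-load model step
        afl_step = CoefficientSet(alpha=np.zeros(9), beta=[2.133, 27.680, -1.712])
        assert detection_probability(afl_step, False) == pytest.approx(0.894, abs=1e-3)


class TestForwardLikelihood:
    def test_all_detected_history(self):
        Y, first = np.array([[1, 1, 1]]), np.array([0])
        phi, p = np.full((1, 3), 0.7), np.full((1, 3), 0.8)
        L = float(np.exp(forward_loglik(Y, first, phi, p))[0])
        assert L == pytest.approx(0.7**2 * 0.8**2, abs=1e-12)

    def test_capture_only_history(self):
        Y, first = np.array([[1, 0, 0]]), np.array([0])
        phi, p = np.full((1, 3), 0.7), np.full((1, 3), 0.8)
        L = float(np.exp(forward_loglik(Y, first, phi, p))[0])
        expect = 0.3 + 0.7 * 0.2 * 0.3 + 0.7**2 * 0.2**2
        assert L == pytest.approx(expect, abs=1e-12)

    def test_deterministic_limit(self):
        phi, p = np.ones((1, 4)), np.ones((1, 4))
        ok = forward_loglik(np.array([[1, 1, 1, 1]]), np.array([0]), phi, p)
        missed = forward_loglik(np.array([[1, 1, 0, 1]]), np.array([0]), phi, p)
        assert float(ok[0]) == pytest.approx(0.0)
        assert np.isneginf(missed[0])

    @settings(max_examples=40, deadline=None)
    @given(data=st.data())
    def test_matches_brute_force_enumeration(self, data):
        T = data.draw(st.integers(2, 8))
        N = data.draw(st.integers(1, 3))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        first = rng.integers(0, T - 1, size=N)
        Y = (rng.random((N, T)) < 0.5).astype(int)
        for i in range(N):
            Y[i, : first[i]] = 0
            Y[i, first[i]] = 1
        phi = rng.uniform(0.05, 0.95, size=(N, T))
        p = rng.uniform(0.05, 0.95, size=(N, T))
        ll = float(np.sum(forward_loglik(Y, first, phi, p)))
        oracle = enumerate_loglik(Y, first, phi, p)
        if np.isneginf(oracle):
            assert np.isneginf(ll)
        else:
            assert ll == pytest.approx(oracle, abs=1e-10)


class TestImputation:
    def test_toy_trajectory_interpolated(self):
        efl = np.full((1, 5), np.nan)
        efl[0, [0, 1, 3]] = [0.20, 0.25, 0.35]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, model = impute_efl(efl, np.array([0]))
        assert model.slope == pytest.approx(0.05, abs=1e-9)
        assert out[0, 2] == pytest.approx(0.30, abs=1e-9)

    def test_complete_series_unchanged(self):
        efl = np.array([[0.2, 0.3, 0.4]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, _ = impute_efl(efl, np.array([0]))
        np.testing.assert_allclose(out, efl)

    def test_recovers_population_slope(self):
        rng = np.random.default_rng(1)
        N, T, slope = 30, 12, 0.04
        first = rng.integers(0, 4, size=N)
        efl = np.full((N, T), np.nan)
        for i in range(N):
            icpt = rng.normal(0.2, 0.05)
            for t in range(first[i], T):
                if rng.random() < 0.7:
                    efl[i, t] = icpt + slope * (t - first[i] + 1) + rng.normal(0, 0.02)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, model = impute_efl(efl, first)
        assert model.slope == pytest.approx(slope, abs=0.01)

    def test_bird_without_observations_warns(self):
        efl = np.full((2, 4), np.nan)
        efl[0] = [0.2, 0.25, 0.3, 0.35]
        with pytest.warns(UserWarning, match="no evening fuel loads"):
            out, _ = impute_efl(efl, np.array([0, 0]))
        assert np.all(np.isnan(out[1]))


class TestResight:
    @pytest.mark.parametrize("obs,dur,expected", [(5, 5, 1.0), (3, 4, 0.75), (0, 3, 0.0)])
    def test_ratio(self, obs, dur, expected):
        assert resight_probability(obs, dur) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            resight_probability(5, 4)


class TestFitting:
    def test_fit_reproducible_and_well_formed(self, small_designs):
        d1, _, _ = small_designs
        cfg = MCMCConfig(n_walkers=16, n_steps=250, n_burn=100, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_a = fit_model(d1, "with_afl", config=cfg)
            fit_b = fit_model(d1, "with_afl", config=cfg)
        np.testing.assert_array_equal(fit_a.draws, fit_b.draws)
        pd.testing.assert_frame_equal(fit_a.summary, fit_b.summary)
        s = fit_a.summary
        assert ((s["q2.5"] <= s["mean"]) & (s["mean"] <= s["q97.5"])).all()
        assert (s["rhat"] >= 1.0).all()

    def test_flat_histories_push_staging_intercept_up(self):
        # birds that never depart and are always seen: posterior mass of the
        # staging intercept sits on large positive values
        T, N = 8, 12
        dates = pd.date_range("2010-08-11", periods=T).date
        enc = pd.DataFrame(
            [
                {"ring_id": f"b{i}", "date": d.isoformat(), "detected": 1}
                for i in range(N)
                for d in dates
            ]
        )
        birds = pd.DataFrame(
            {
                "ring_id": [f"b{i}" for i in range(N)],
                "first_capture_date": dates[0].isoformat(),
                "radio_tagged": False,
            }
        )
        fp = pd.DataFrame({"ring_id": [f"b{i}" for i in range(N)],
                           "afl": np.linspace(0.1, 0.4, N)})
        rng = np.random.default_rng(2)
        cov = pd.DataFrame(
            {"date": [d.isoformat() for d in dates],
             "temp_surface_C": rng.normal(6, 2, T),
             "wind_surface_ms": rng.gamma(2, 2, T),
             "twc_midnight_ms": rng.normal(0, 2, T)}
        )
        design = build_design(enc, birds, fp, cov)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_model(
                design, "with_afl",
                config=MCMCConfig(n_walkers=16, n_steps=400, n_burn=200, seed=5),
            )
        assert fit.summary.loc["phi:intercept", "mean"] > 1.0

    def test_encounter_loglik_consistent_with_forward(self, small_designs):
        d1, _, _ = small_designs
        coeffs = CoefficientSet(alpha=np.full(9, 0.3), beta=np.full(3, 0.2))
        ll = encounter_loglik(coeffs, d1, "with_afl")
        assert np.isfinite(ll) and ll < 0
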