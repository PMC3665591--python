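import numpy as np
import pandas as pd
import pytest
from scipy.special import i0e, i1e

from wheatear_stopover.cjs import CoefficientSet, _sigmoid
from wheatear_stopover.synthdata import (
    SimulationConfig,
    generate_covariates,
    simulate_study,
    table1_fixture,
    vonmises_kappa_from_R,
)


class TestCovariates:
    def test_same_seed_identical_tables(self):
        a = generate_covariates(15, seed=9)
        b = generate_covariates(15, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_white_noise_temperature_when_ar_zero(self):
        df = generate_covariates(1000, seed=2, ar1=0.0)
        x = df["temp_surface_C"].to_numpy()
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.08

    def test_calm_days_have_zero_tailwind(self):
        df = generate_covariates(10, seed=3, wind_scale=0.0)
        assert np.allclose(df["twc_midnight_ms"], 0.0)


class TestKappaInversion:
    def test_uniform_limit(self):
        assert vonmises_kappa_from_R(0.0) == 0.0

    def test_bessel_ratio_round_trip(self):
        kappa = vonmises_kappa_from_R(0.87)
        assert i1e(kappa) / i0e(kappa) == pytest.approx(0.87, abs=1e-6)

    def test_sampling_round_trip(self):
        kappa = vonmises_kappa_from_R(0.87)
        rng = np.random.default_rng(0)
        ang = rng.vonmises(0.0, kappa, size=100_000)
        R = np.hypot(np.cos(ang).mean(), np.sin(ang).mean())
        assert R == pytest.approx(0.87, abs=0.005)

    def test_invalid_R_rejected(self):
        with pytest.raises(ValueError):
            vonmises_kappa_from_R(1.0)


class TestSimulateStudy:
    def test_deterministic_given_seed(self):
        a = simulate_study(SimulationConfig(n_birds=20, n_days=10, seed=8))
        b = simulate_study(SimulationConfig(n_birds=20, n_days=10, seed=8))
        for x, y in [(a.birds, b.birds), (a.encounters, b.encounters),
                     (a.masses, b.masses), (a.departures, b.departures)]:
            pd.testing.assert_frame_equal(x, y)
        np.testing.assert_array_equal(a.truth.z, b.truth.z)

    def test_presence_absorbing_and_detections_imply_presence(self, small_study):
        z, Y = small_study.truth.z, None
        # z never goes 0 -> 1 after arrival
        diffs = np.diff(z, axis=1)
        arrival = small_study.truth.arrival_day
        for i in range(z.shape[0]):
            assert np.all(diffs[i, arrival[i]:] <= 0)
        enc = small_study.encounters
        T = small_study.config.n_days
        Y = enc["detected"].to_numpy().reshape(z.shape[0], T)
        assert np.all(z[Y == 1] == 1)

    def test_no_departures_when_staying_is_certain(self):
        coeffs = CoefficientSet(alpha=[50, 0, 0, 0, 0, 0, 0, 0, 0], beta=[2.9, 30.8, 0])
        study = simulate_study(
            SimulationConfig(n_birds=25, n_days=12, seed=4, coeffs=coeffs)
        )
        assert (study.truth.departure_night == -1).all()
        assert study.departures.empty

    def test_perfect_detection_fills_matrix_after_capture(self):
        coeffs = CoefficientSet(alpha=[50, 0, 0, 0, 0, 0, 0, 0, 0], beta=[50, 0, 0])
        study = simulate_study(
            SimulationConfig(n_birds=15, n_days=10, seed=4, coeffs=coeffs)
        )
        T = study.config.n_days
        Y = study.encounters["detected"].to_numpy().reshape(15, T)
        for i, f in enumerate(study.truth.arrival_day):
            assert np.all(Y[i, f:] == 1) and np.all(Y[i, :f] == 0)

    def test_staging_frequency_matches_true_probability(self):
        # intercept-only truth: each night a present bird stays with
        # probability sigmoid(alpha1); empirical frequency within binomial CI
        a1 = 1.2
        coeffs = CoefficientSet(alpha=[a1, 0, 0, 0, 0, 0, 0, 0, 0], beta=[2.9, 30.8, 0])
        study = simulate_study(
            SimulationConfig(n_birds=1500, n_days=10, seed=10, coeffs=coeffs,
                             efl_noise_sd=0.0, fdr_sd=0.0)
        )
        z, arrival = study.truth.z, study.truth.arrival_day
        stays = trials = 0
        for i in range(z.shape[0]):
            for t in range(arrival[i], study.config.n_days - 1):
                if z[i, t] == 1 and t != arrival[i]:  # skip transient night
                    trials += 1
                    stays += z[i, t + 1]
        phat = stays / trials
        se = np.sqrt(_sigmoid(a1) * (1 - _sigmoid(a1)) / trials)
        assert phat == pytest.approx(_sigmoid(a1), abs=3 * se)

    def test_departure_phenology_matches_configuration(self):
        study = simulate_study(
            SimulationConfig(n_birds=300, n_days=21, seed=12, tag_fraction=1.0)
        )
        t = study.departures["minutes_after_sunset"].to_numpy()
        assert len(t) > 30
        assert t.mean() == pytest.approx(85, abs=2 * 29 / np.sqrt(len(t)) + 2)
        d = study.departures["direction_deg"].to_numpy()
        rad = np.radians(d)
        mean_dir = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360
        assert mean_dir == pytest.approx(233, abs=10)

    def test_tables_round_trip_through_writers(self, tmp_path, small_study):
        small_study.write(tmp_path)
        for name in ("birds", "encounters", "masses", "covariates", "departures"):
            assert (tmp_path / f"{name}.csv").exists()
        enc = pd.read_csv(tmp_path / "encounters.csv")
        pd.testing.assert_series_equal(
            enc["detected"], small_study.encounters["detected"].reset_index(drop=True)
        )
        assert (tmp_path / "truth.json").stat().st_size > 0


class TestTable1Fixture:
    def test_counts_match_field_season(self):
        t1 = table1_fixture()
        assert len(t1) == 30
        assert t1["has_departure_time"].sum() == 16
        assert t1["has_direction"].sum() == 15

    def test_individual_row_values(self):
        t1 = table1_fixture().set_index("ring_id")
        row = t1.loc["179106212"]
        assert row["departure_date"] == "2010-08-17"  # night of 17/18 Aug
        assert row["minutes_after_sunset"] == 114
        assert row["sun_elevation_deg"] == -8.33
        assert row["direction_deg"] == 204
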