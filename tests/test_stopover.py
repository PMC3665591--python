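import warnings

import numpy as np
import pytest
from scipy.stats import chisquare, geom

from wheatear_stopover.cjs import EflImputationModel
from wheatear_stopover.stopover import (
    minimum_stopover,
    simulate_stopover,
    summarize_stopover,
)


class TestMinimumStopover:
    @pytest.mark.parametrize(
        "row,days",
        [
            ([0, 0, 1, 1, 1, 1, 1, 0], 5),  # captured day 3, last seen day 7
            ([0, 1, 0, 0], 1),  # seen only at capture
            ([0, 0, 1, 1, 0, 1, 0], 4),  # gap tolerated
        ],
    )
    def test_last_minus_first_plus_one(self, row, days):
        assert minimum_stopover(np.array(row)) == days

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            minimum_stopover(np.zeros(5))


def _alpha_draws(intercept, n=400):
    """Posterior 'draws' with constant staging logit = intercept."""
    theta = np.zeros((n, 12))
    theta[:, 0] = intercept
    return theta


def _dummy_efl_model():
    return EflImputationModel(slope=0.04, intercepts={}, global_intercept=0.2,
                              method="fixed")


class TestSimulateStopover:
    def test_certain_departure_pins_duration_at_minimum(self, small_designs):
        _, d2, em = small_designs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dur, trunc = simulate_stopover(
                d2, _alpha_draws(-50.0), n_sim=50, efl_model=em, seed=1
            )
        mins = np.array([minimum_stopover(d2.history.Y[i]) for i in range(d2.history.n_birds)])
        np.testing.assert_array_equal(dur, np.tile(mins[:, None], (1, 50)))
        assert not trunc.any()

    def test_absorbing_stay_truncates_at_horizon(self, small_designs):
        _, d2, em = small_designs
        with pytest.warns(UserWarning, match="truncated"):
            dur, trunc = simulate_stopover(
                d2, _alpha_draws(50.0), n_sim=20, horizon_days=15, efl_model=em, seed=1
            )
        assert trunc.all()
        np.testing.assert_array_equal(dur, np.full_like(dur, 15.0))

    def test_draws_dominate_minimum_stopover(self, small_designs):
        _, d2, em = small_designs
        rng_draws = np.random.default_rng(3).normal(0, 0.5, size=(300, 12))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dur, _ = simulate_stopover(d2, rng_draws, n_sim=300, efl_model=em, seed=2)
        mins = np.array([minimum_stopover(d2.history.Y[i]) for i in range(d2.history.n_birds)])
        assert np.all(dur >= mins[:, None])

    def test_constant_half_staying_gives_geometric_extra_days(self, small_designs):
        # with Phi = 1/2 each night the extra days beyond the last observation
        # are Geometric(1/2): mean 1, chi-square GOF in at least 9 of 10 seeds
        _, d2, em = small_designs
        i = 0
        n_ok = 0
        for seed in range(10):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dur, _ = simulate_stopover(
                    d2, _alpha_draws(0.0), n_sim=100_000, efl_model=em, seed=seed
                )
            extra = dur[i] - dur[i].min()
            kmax = 10
            obs = np.array([(extra == k).sum() for k in range(kmax)] + [(extra >= kmax).sum()])
            pmf = geom.pmf(np.arange(1, kmax + 1), 0.5)
            expected = np.append(pmf, 1 - pmf.sum()) * extra.size
            p = chisquare(obs, expected).pvalue
            n_ok += p > 0.01
        assert n_ok >= 9

    def test_fatter_birds_leave_sooner(self, small_designs):
        # the negative evening-fuel-load coefficient shortens stopovers for
        # birds on steeper fuel trajectories
        _, d2, _ = small_designs
        theta = np.zeros((200, 12))
        theta[:, 0] = 2.0
        theta[:, 7] = -3.9  # efl coefficient in the efl model layout
        slow = EflImputationModel(slope=0.0, intercepts={}, global_intercept=0.2, method="f")
        fast = EflImputationModel(slope=0.10, intercepts={}, global_intercept=0.2, method="f")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d_slow, _ = simulate_stopover(d2, theta, n_sim=2000, efl_model=slow, seed=4)
            d_fast, _ = simulate_stopover(d2, theta, n_sim=2000, efl_model=fast, seed=4)
        assert d_fast.mean() < d_slow.mean()


class TestSummaries:
    def test_degenerate_draws(self):
        Y = np.array([[1, 1, 1, 1, 0]])
        est = summarize_stopover(np.full((1, 3), 4.0), Y, ["a"])
        row = est.per_bird.iloc[0]
        assert row["mean"] == 4.0 and row["se"] == 0.0
        assert est.population_mean == 4.0

    def test_population_mean_is_midpoint_of_symmetric_birds(self):
        Y = np.array([[1, 1, 0, 0], [1, 1, 1, 1]])
        draws = np.array([[3.0, 4.0, 5.0], [7.0, 8.0, 9.0]])
        est = summarize_stopover(draws, Y, ["a", "b"])
        assert est.population_mean == pytest.approx(6.0)

    def test_recovers_known_mean_duration(self, small_study, small_designs):
        # simulate from the data-generating truth and check the population
        # estimate sits near the realized mean stopover of the study's birds
        _, d2, em = small_designs
        truth = small_study.truth
        ids = d2.history.ring_ids
        idx = [small_study.birds["ring_id"].tolist().index(r) for r in ids]
        alpha = np.tile(np.concatenate([truth.coeffs.alpha, truth.coeffs.beta]), (500, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dur, trunc = simulate_stopover(d2, alpha, n_sim=500, efl_model=em, seed=6)
        est = summarize_stopover(dur, d2.history.Y, ids, trunc)
        true_dur = []
        for k in idx:
            ln = truth.departure_night[k]
            if ln >= 0:
                true_dur.append(ln - truth.arrival_day[k] + 1)
        # generous envelope: the estimate conditions on detections, the truth
        # does not, but both live on the same few-day scale
        assert abs(est.population_mean - np.mean(true_dur)) < 2.5
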