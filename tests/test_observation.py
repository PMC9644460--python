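"""Observation model: data container, expected counts, NB likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import distressdyn as dd
from distressdyn import ObservationSet, negbin_logpmf, observation_means
from distressdyn.observation import expected_means, observation_time


def make_obs(rows):
    return ObservationSet.from_dataframe(
        pd.DataFrame(rows, columns=["stream", "year", "value"])
    )


class TestObservationSet:
    def test_valid_set(self):
        obs = make_obs([("distress", 2009, 100), ("population", 2009, 1000)])
        assert len(obs) == 2

    def test_unknown_stream_rejected(self):
        with pytest.raises(ValueError, match="unknown stream"):
            make_obs([("Population", 2009, 100)])

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_obs([("distress", 2009, -5)])

    def test_non_integer_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            make_obs([("distress", 2009, 1.5)])

    def test_duplicate_record_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_obs([("distress", 2009, 1), ("distress", 2009, 2)])

    def test_midyear_evaluation_times(self):
        obs = make_obs([("distress", 2009, 1), ("population", 2008, 2)])
        np.testing.assert_allclose(obs.times, [1.5, 0.5])


class TestObservationMeans:
    def test_population_record_2008(self, truth):
        traj = dd.simulate_trajectory(truth, 12.5)
        obs = make_obs([("population", 2008, 1)])
        assert observation_means(traj, obs)[0] == pytest.approx(
            16_167_328 + 0.5 * 308_538
        )

    def test_mortality_record_2019(self, truth):
        traj = dd.simulate_trajectory(truth, 12.5)
        obs = make_obs([("mortality", 2019, 1)])
        assert observation_means(traj, obs)[0] == pytest.approx(
            136_840 + 11.5 * 2228.7
        )

    def test_constant_trajectory_any_year(self):
        p = dd.default_truth().replace(g=0.0, h=0.0, u=0.0, delta_i=0.0)
        traj = dd.simulate_trajectory(p, 12.5)
        obs = make_obs([("population", y, 1) for y in (2008, 2013, 2019)])
        np.testing.assert_allclose(observation_means(traj, obs), p.P0)

    def test_outside_trajectory_raises(self, truth):
        traj = dd.simulate_trajectory(truth, 5.0)
        obs = make_obs([("population", 2019, 1)])
        with pytest.raises(ValueError, match="outside"):
            observation_means(traj, obs)

    def test_fast_path_matches_trajectory_path(self, truth, obs_default):
        traj = dd.simulate_trajectory(truth, 12.5, dt_store=1 / 48)
        via_traj = observation_means(traj, obs_default)
        fast = expected_means(truth, obs_default)
        np.testing.assert_allclose(fast, via_traj, rtol=1e-5)


class TestNegbinLogpmf:
    def test_normalises_to_one(self):
        ys = np.arange(0, 400)
        total = np.exp(negbin_logpmf(ys, 5.0, 2.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_poisson_limit(self):
        nb = negbin_logpmf(3, 5.0, 1e8)
        pois = stats.poisson.logpmf(3, 5.0)
        assert nb == pytest.approx(pois, abs=1e-4)

    def test_matches_scipy_nbinom(self):
        y = np.array([0, 2, 7, 40])
        for mean, beta in [(5.0, 2.0), (100.0, 4.0), (17.0, 0.3)]:
            ref = stats.nbinom.logpmf(y, beta * mean, beta / (1.0 + beta))
            np.testing.assert_allclose(negbin_logpmf(y, mean, beta), ref,
                                       rtol=1e-10)

    def test_monte_carlo_variance(self, rng):
        mean, beta, n = 100.0, 4.0, 1_000_000
        lam = rng.gamma(shape=beta * mean, scale=1.0 / beta, size=n)
        draws = rng.poisson(lam)
        assert draws.mean() == pytest.approx(mean, rel=0.005)
        assert draws.var() == pytest.approx(mean * (1 + 1 / beta), rel=0.02)

    def test_stable_at_extreme_dispersion(self):
        # near-Poisson regime that overflows the naive gammaln difference
        val = negbin_logpmf(16_000_000, 1.6e7, 1e15)
        pois = stats.poisson.logpmf(16_000_000, 1.6e7)
        assert val == pytest.approx(pois, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            negbin_logpmf(-1, 5.0, 2.0)
        with pytest.raises(ValueError):
            negbin_logpmf(2.5, 5.0, 2.0)
        with pytest.raises(ValueError):
            negbin_logpmf(3, 0.0, 2.0)
        with pytest.raises(ValueError):
            negbin_logpmf(3, 5.0, 0.0)


class TestTotalLogLikelihood:
    def test_record_by_record_oracle(self, truth, obs_default):
        total = dd.total_log_likelihood(truth, obs_default)
        # independent per-record accumulation
        acc = 0.0
        means = expected_means(truth, obs_default)
        for (_, row), m in zip(obs_default.records.iterrows(), means):
            acc += float(negbin_logpmf(row["value"], m, truth.beta[row["stream"]]))
        assert total == pytest.approx(acc, rel=1e-12)

    def test_additive_over_disjoint_subsets(self, truth, obs_default):
        # independence: the total likelihood is the product over records,
        # so disjoint subsets contribute additively on the log scale
        rec = obs_default.records
        a = ObservationSet.from_dataframe(rec.iloc[: len(rec) // 2])
        b = ObservationSet.from_dataframe(rec.iloc[len(rec) // 2:])
        assert dd.total_log_likelihood(truth, a) + dd.total_log_likelihood(
            truth, b
        ) == pytest.approx(dd.total_log_likelihood(truth, obs_default), rel=1e-12)

    def test_order_invariance(self, truth, obs_default):
        base = dd.total_log_likelihood(truth, obs_default)
        scrambled = ObservationSet.from_dataframe(
            obs_default.records.sample(frac=1.0, random_state=1)
        )
        assert dd.total_log_likelihood(truth, scrambled) == pytest.approx(
            base, rel=1e-12
        )

    def test_poisson_mode_single_record(self, truth):
        p = truth.replace(beta={s: 1e8 for s in dd.STREAMS})
        mean = p.P0 + p.g * observation_time(2010)
        obs = make_obs([("population", 2010, int(round(mean)))])
        ll = dd.total_log_likelihood(p, obs)
        assert ll == pytest.approx(
            float(stats.poisson.logpmf(int(round(mean)), mean)), abs=1e-3
        )

    def test_nonpositive_mean_gives_minus_inf(self, obs_default):
        p = dd.default_truth().replace(h=-40_000.0)  # mortality negative by 2019
        assert dd.total_log_likelihood(p, obs_default) == -math.inf

    def test_empty_set_raises(self, truth):
        with pytest.raises(ValueError):
            dd.total_log_likelihood(truth, ObservationSet.empty())

    def test_monotone_in_mean_below_observation(self, truth):
        # with y above the expected count, increasing the mean increases
        # the record's log-likelihood
        obs_y = 2_600_000
        lls = []
        for prev0 in (0.12, 0.14, 0.15):
            p = truth.replace(prev0=prev0)
            m = expected_means(p, make_obs([("distress", 2009, obs_y)]))[0]
            assert m < obs_y
            lls.append(float(negbin_logpmf(obs_y, m, p.beta["distress"])))
        assert lls[0] < lls[1] < lls[2]

    def test_cached_path_matches_reference(self, truth, obs_default):
        from distressdyn.model import _LikelihoodCache

        cache = _LikelihoodCache(obs_default, dt=1 / 52)
        assert cache.loglike(truth.to_vector()) == pytest.approx(
            dd.total_log_likelihood(truth, obs_default, dt=1 / 52), rel=1e-12
        )
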