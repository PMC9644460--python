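"""Posterior post-processing: intervals, counterfactuals, bands, PPC."""

import numpy as np
import pandas as pd
import pytest

import distressdyn as dd
from distressdyn import credible_interval, posterior_probability
from distressdyn.analysis import chi2_discrepancy, counterfactual_prevalence
from distressdyn.sampling import PosteriorSamples


def samples_from_vectors(vectors):
    draws = np.asarray(vectors)[None, :, :].repeat(2, axis=0)
    return PosteriorSamples(
        names=dd.PARAM_NAMES, draws=draws, meta={},
        diagnostics=pd.DataFrame(
            {"rhat": np.nan, "ess_bulk": np.nan}, index=list(dd.PARAM_NAMES)
        ),
    )


class TestCredibleInterval:
    def test_documented_quantile_rule(self):
        lo, hi = credible_interval(np.arange(1, 101), 0.95)
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_constant_input(self):
        assert credible_interval([4.2] * 10, 0.95) == (4.2, 4.2)

    def test_nesting(self, rng):
        x = rng.standard_normal(500)
        lo50, hi50 = credible_interval(x, 0.50)
        lo95, hi95 = credible_interval(x, 0.95)
        assert lo95 <= lo50 <= hi50 <= hi95

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            credible_interval([], 0.95)
        with pytest.raises(ValueError):
            credible_interval([1.0, 2.0], 1.5)


class TestPosteriorProbability:
    def test_always_true(self, fitted):
        _, res = fitted
        assert res.posterior_probability("P0 > 0") == 1.0

    def test_counting(self, truth):
        vecs = []
        for di in (-1.0, 1.0, 2.0, 3.0):
            vecs.append(truth.replace(delta_i=di).to_vector())
        s = samples_from_vectors(vecs)
        assert posterior_probability(s, "delta_i > 0") == 0.75

    def test_complement_sums_to_one(self, fitted):
        _, res = fitted
        p = res.posterior_probability("delta_r < 0")
        q = res.posterior_probability("delta_r >= 0")
        assert p + q == pytest.approx(1.0)

    def test_callable_predicate(self, fitted):
        _, res = fitted
        p1 = res.posterior_probability("delta_i > 0")
        p2 = res.posterior_probability(lambda df: df["delta_i"] > 0)
        assert p1 == p2


class TestTrajectoryBands:
    def test_identical_draws_collapse(self, truth):
        s = samples_from_vectors([truth.to_vector()] * 5)
        bands = dd.trajectory_bands(s, n_draws=10, quantities=("prevalence",))
        df = bands["prevalence"]
        np.testing.assert_allclose(df["q2.5"], df["q97.5"], rtol=1e-12)

    def test_band_nesting(self, fitted):
        _, res = fitted
        bands = res.trajectory_bands(n_draws=200, quantities=("prevalence", "i"))
        for df in bands.values():
            assert np.all(df["q2.5"] <= df["q25"] + 1e-15)
            assert np.all(df["q25"] <= df["q50"] + 1e-15)
            assert np.all(df["q50"] <= df["q75"] + 1e-15)
            assert np.all(df["q75"] <= df["q97.5"] + 1e-15)

    def test_envelope_contains_quantile_band(self, fitted):
        _, res = fitted
        bands = res.trajectory_bands(n_draws=100, quantities=("prevalence",),
                                     seed=4)
        # min/max envelope over the same draws is at least as wide
        thetas = res.samples.flat
        rng = np.random.default_rng(4)
        idx = rng.choice(thetas.shape[0], size=100, replace=False)
        trajs = [dd.simulate_trajectory(dd.ModelParameters.from_vector(v), 12.0,
                                        0.25, method="rk4")
                 for v in thetas[idx]]
        stack = np.stack([t.prevalence for t in trajs])
        df = bands["prevalence"]
        assert np.all(stack.min(0) <= df["q2.5"] + 1e-15)
        assert np.all(stack.max(0) >= df["q97.5"] - 1e-15)

    def test_too_many_draws_rejected(self, fitted):
        _, res = fitted
        with pytest.raises(ValueError, match="exceeds"):
            res.trajectory_bands(n_draws=10**9)


class TestCounterfactual:
    def test_no_trend_draws_equal_factual_bitwise(self, truth):
        # delta_i already 0: the counterfactual IS the factual simulation
        p = truth.replace(delta_i=0.0)
        s = samples_from_vectors([p.to_vector()] * 4)
        cf = counterfactual_prevalence(s, n_draws=8, seed=0)
        np.testing.assert_array_equal(cf.factual, cf.counterfactual)
        assert np.all(cf.alt_difference == 0.0)
        # difference degenerates to the factual 2008 -> end-2019 change
        expected = cf.factual[:, 0] - cf.factual[:, -1]
        np.testing.assert_array_equal(cf.difference, expected)

    def test_persons_averted_identity(self, fitted):
        _, res = fitted
        cf = res.counterfactual(n_draws=100, seed=1)
        flat = res.samples.flat
        # recompute P(end of 2019) per sampled draw independently
        rng = np.random.default_rng(1)
        idx = rng.choice(flat.shape[0], size=100, replace=False)
        jP0 = res.samples.names.index("P0")
        jg = res.samples.names.index("g")
        P_end = flat[idx, jP0] + flat[idx, jg] * 12.0
        np.testing.assert_allclose(cf.persons_averted, cf.difference * P_end,
                                   rtol=1e-12)

    def test_relative_reduction_identity(self, fitted):
        _, res = fitted
        cf = res.counterfactual(n_draws=50, seed=2)
        np.testing.assert_allclose(
            cf.relative_reduction * cf.factual[:, 0], cf.difference, rtol=1e-12
        )

    def test_positive_median_under_rising_incidence(self, fitted):
        # the generator truth has delta_i = 0.02 > 0, so removing the trend
        # must lower end-of-period prevalence for most draws
        _, res = fitted
        cf = res.counterfactual(n_draws=300, seed=3)
        assert np.median(cf.difference) > 0

    def test_summaries_are_quantiles_of_draws(self, fitted):
        _, res = fitted
        cf = res.counterfactual(n_draws=100, seed=4)
        s = cf.summaries()
        assert s["prevalence_difference"]["median"] == pytest.approx(
            float(np.median(cf.difference))
        )
        lo, hi = s["persons_averted"]["ci95"]
        qlo, qhi = np.quantile(cf.persons_averted, [0.025, 0.975])
        assert (lo, hi) == (pytest.approx(qlo), pytest.approx(qhi))


class TestPosteriorPredictiveCheck:
    def test_discrepancy_matches_loop_oracle(self, rng):
        y = rng.integers(0, 100, size=12).astype(float)
        m = rng.uniform(10, 90, size=12)
        beta = 4.0
        acc = 0.0
        for yi, mi in zip(y, m):
            acc += (yi - mi) ** 2 / (mi * (1 + 1 / beta))
        assert chi2_discrepancy(y, m, beta) == pytest.approx(acc, rel=1e-12)
        acc_p = sum((yi - mi) ** 2 / mi for yi, mi in zip(y, m))
        assert chi2_discrepancy(y, m, beta, "pearson") == pytest.approx(
            acc_p, rel=1e-12
        )

    def test_well_specified_p_value_moderate(self, fitted):
        _, res = fitted
        r = res.ppc("distress", n_draws=400, seed=5)
        assert 0.05 < r.p_value < 0.95
        assert not r.flagged

    def test_gross_misfit_detected(self, fitted, obs_default):
        model, res = fitted
        rec = obs_default.records.copy()
        j = rec.index[rec.stream == "distress"][2]
        rec.loc[j, "value"] = int(rec.loc[j, "value"] * 100)
        corrupted = dd.ObservationSet.from_dataframe(rec)
        r = dd.posterior_predictive_check(res.samples, corrupted, "distress",
                                          n_draws=200, seed=6)
        assert r.p_value < 0.05
        assert r.flagged

    def test_unknown_stream_rejected(self, fitted):
        _, res = fitted
        with pytest.raises(ValueError):
            res.ppc("nonexistent")


class TestStreamLogLikelihoods:
    def test_table_shape_and_finiteness(self, fitted):
        _, res = fitted
        tab = res.stream_log_likelihoods(n_draws=50, seed=0)
        assert set(tab["stream"]) == set(dd.STREAMS)
        assert np.all(np.isfinite(tab["mean_loglik"]))
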