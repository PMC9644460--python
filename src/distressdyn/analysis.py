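"""Posterior post-processing.

Credible trajectory bands, the constant-incidence counterfactual, posterior
probabilities of parameter statements, and posterior predictive checks with
a chi-square discrepancy.

The headline counterfactual re-simulates every posterior draw with the
incidence trend removed (``delta_i := 0``, all other components of the draw
unchanged) and summarises, per draw,

* the prevalence difference: counterfactual prevalence at the start of the
  reference period minus at its end (positive = prevalence would have
  fallen had individual-level risk stayed constant),
* persons averted: that difference times the population at the end of the
  period,
* the relative reduction: the difference divided by prevalence at the start
  of the period.

An alternative difference definition (factual minus counterfactual
prevalence at the end of the period) is computed and reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import TIME_ORIGIN, ModelParameters, distress_stock_at
from .observation import ObservationSet, observation_time
from .sampling import PosteriorSamples

__all__ = [
    "credible_interval",
    "posterior_probability",
    "trajectory_bands",
    "counterfactual_prevalence",
    "CounterfactualResult",
    "posterior_predictive_check",
    "PpcResult",
    "stream_log_likelihoods",
]

logger = logging.getLogger(__name__)

BAND_PERCENTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


def credible_interval(values, level: float = 0.95):
    """Equal-tailed quantile interval at the given level.

    Quantiles use the default linear-interpolation rule, so e.g. the 95%
    interval of 1..100 is (3.475, 97.525).
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("credible_interval requires non-empty input")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [tail, 1.0 - tail])
    return float(lo), float(hi)


def posterior_probability(samples: PosteriorSamples, predicate) -> float:
    """Fraction of posterior draws satisfying a predicate.

    ``predicate`` is either a pandas query-style string over parameter
    names (e.g. ``"delta_i > 0"``) or a callable mapping the draws
    DataFrame to a boolean array.
    """
    if samples.n_draws == 0:
        raise ValueError("no posterior draws")
    df = pd.DataFrame(samples.flat, columns=list(samples.names))
    mask = df.eval(predicate) if isinstance(predicate, str) else predicate(df)
    mask = np.asarray(mask, bool)
    if mask.shape != (len(df),):
        raise ValueError("predicate must return one boolean per draw")
    return float(mask.mean())


def _select_draws(samples: PosteriorSamples, n_draws: int, rng) -> np.ndarray:
    flat = samples.flat
    if n_draws > flat.shape[0]:
        raise ValueError(
            f"n_draws={n_draws} exceeds available draws ({flat.shape[0]})"
        )
    if n_draws == flat.shape[0]:
        return flat
    idx = rng.choice(flat.shape[0], size=n_draws, replace=False)
    return flat[idx]


def _prevalence_on_grid(params: ModelParameters, times: np.ndarray) -> np.ndarray:
    M, _ = distress_stock_at(params, times)
    P = params.P0 + params.g * times
    return M / P


def trajectory_bands(samples: PosteriorSamples, n_draws: int = 1000,
                     quantities=("prevalence",), t_end: float = 12.0,
                     dt_store: float = 1.0 / 4.0, seed: int = 0) -> dict:
    """Pointwise credible bands of trajectory quantities.

    Simulates ``n_draws`` randomly selected posterior parameter vectors and
    returns, per quantity, a DataFrame of the 2.5/25/50/75/97.5 pointwise
    percentiles on the stored grid. Draws whose simulation fails are
    skipped with a logged count.
    """
    from .dynamics import simulate_trajectory

    rng = np.random.default_rng(seed)
    thetas = _select_draws(samples, n_draws, rng)
    trajs = []
    skipped = 0
    for vec in thetas:
        try:
            params = ModelParameters.from_vector(vec)
            trajs.append(simulate_trajectory(params, t_end, dt_store, method="rk4"))
        except (ValueError, FloatingPointError, RuntimeError):
            skipped += 1
    if skipped:
        logger.warning("trajectory_bands: skipped %d failed simulations", skipped)
    if not trajs:
        raise RuntimeError("all trajectory simulations failed")
    times = trajs[0].times
    out = {}
    for q in quantities:
        stack = np.stack([getattr(tr, q) for tr in trajs])
        pct = np.percentile(stack, BAND_PERCENTILES, axis=0)
        df = pd.DataFrame({"time": times})
        for p, row in zip(BAND_PERCENTILES, pct):
            df[f"q{p:g}"] = row
        out[q] = df
    return out


@dataclass
class CounterfactualResult:
    """Per-draw factual/counterfactual prevalence and derived quantities."""

    times: np.ndarray
    factual: np.ndarray          # (n_draws, n_times) prevalence
    counterfactual: np.ndarray   # (n_draws, n_times) prevalence
    difference: np.ndarray       # cf prevalence at t0 minus at t1, per draw
    alt_difference: np.ndarray   # factual minus cf prevalence at t1, per draw
    persons_averted: np.ndarray
    relative_reduction: np.ndarray
    reference_years: tuple

    def summaries(self) -> dict:
        def summarise(x):
            return {
                "median": float(np.median(x)),
                "ci50": credible_interval(x, 0.50),
                "ci95": credible_interval(x, 0.95),
            }

        return {
            "prevalence_difference": summarise(self.difference),
            "alt_prevalence_difference": summarise(self.alt_difference),
            "persons_averted": summarise(self.persons_averted),
            "relative_reduction": summarise(self.relative_reduction),
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "difference": self.difference,
                "alt_difference": self.alt_difference,
                "persons_averted": self.persons_averted,
                "relative_reduction": self.relative_reduction,
            }
        )


def counterfactual_prevalence(samples: PosteriorSamples,
                              reference_years=(2008, 2019),
                              n_draws: int = 1000, seed: int = 0,
                              dt_store: float = 0.25) -> CounterfactualResult:
    """Constant-incidence counterfactual over the posterior.

    For each selected draw the model is re-simulated with ``delta_i`` set
    to 0 (all other components unchanged). The reference period runs from
    the start of its first year to the end of its last (2008-2019 spans
    t = 0 to t = 12).
    """
    y0, y1 = reference_years
    t0 = float(y0 - TIME_ORIGIN)
    t1 = float(y1 - TIME_ORIGIN + 1.0)
    if not 0.0 <= t0 < t1:
        raise ValueError("reference years must be ordered and >= 2008")
    rng = np.random.default_rng(seed)
    thetas = _select_draws(samples, n_draws, rng)
    j_di = samples.names.index("delta_i")

    n_grid = int(round((t1 - t0) / dt_store))
    times = np.concatenate(([t0], t0 + dt_store * np.arange(1, n_grid + 1)))
    times[-1] = t1
    i0_idx, i1_idx = 0, len(times) - 1

    fact = np.empty((len(thetas), len(times)))
    cf = np.empty_like(fact)
    P_end = np.empty(len(thetas))
    for d, vec in enumerate(thetas):
        params = ModelParameters.from_vector(vec)
        fact[d] = _prevalence_on_grid(params, times)
        cf_vec = vec.copy()
        cf_vec[j_di] = 0.0
        cf[d] = _prevalence_on_grid(ModelParameters.from_vector(cf_vec), times)
        P_end[d] = params.P0 + params.g * t1

    difference = cf[:, i0_idx] - cf[:, i1_idx]
    alt_difference = fact[:, i1_idx] - cf[:, i1_idx]
    persons_averted = difference * P_end
    relative_reduction = difference / fact[:, i0_idx]
    return CounterfactualResult(
        times=times, factual=fact, counterfactual=cf,
        difference=difference, alt_difference=alt_difference,
        persons_averted=persons_averted,
        relative_reduction=relative_reduction,
        reference_years=(y0, y1),
    )


@dataclass
class PpcResult:
    """Posterior predictive check via a chi-square discrepancy."""

    stream: str
    p_value: float
    t_observed: np.ndarray
    t_replicated: np.ndarray
    variance: str

    @property
    def flagged(self) -> bool:
        """Extreme Bayesian p-value signals misfit."""
        return not 0.05 < self.p_value < 0.95


def chi2_discrepancy(y, means, beta, variance: str = "negbin") -> float:
    """T(y) = sum_t (y_t - m_t)^2 / Var_t.

    ``variance="negbin"`` uses the model variance m (1 + 1/beta);
    ``variance="pearson"`` uses m.
    """
    y = np.asarray(y, float)
    means = np.asarray(means, float)
    if variance == "negbin":
        var = means * (1.0 + 1.0 / beta)
    elif variance == "pearson":
        var = means
    else:
        raise ValueError(f"unknown variance form {variance!r}")
    return float(np.sum((y - means) ** 2 / var))


def posterior_predictive_check(samples: PosteriorSamples, obs: ObservationSet,
                               stream: str, n_draws: int = 1000, seed: int = 0,
                               variance: str = "negbin") -> PpcResult:
    """Bayesian p-value: P(T(y_rep) >= T(y_obs)) over posterior draws.

    For each draw, expected counts are computed at the stream's record
    times, replicate counts are drawn from the negative binomial
    (gamma-Poisson), and the chi-square discrepancies of the observed and
    replicated data are compared.
    """
    from .observation import expected_means

    records = obs.stream(stream)
    if records.empty:
        raise ValueError(f"no records for stream {stream!r}")
    sub = ObservationSet.from_dataframe(records)
    y = sub.records["value"].to_numpy()
    rng = np.random.default_rng(seed)
    thetas = _select_draws(samples, n_draws, rng)
    j_beta = samples.names.index(f"beta_{stream}")

    t_obs = np.empty(len(thetas))
    t_rep = np.empty(len(thetas))
    for d, vec in enumerate(thetas):
        params = ModelParameters.from_vector(vec)
        means = expected_means(params, sub)
        beta = vec[j_beta]
        lam = rng.gamma(shape=beta * means, scale=1.0 / beta)
        y_rep = rng.poisson(lam)
        t_obs[d] = chi2_discrepancy(y, means, beta, variance)
        t_rep[d] = chi2_discrepancy(y_rep, means, beta, variance)
    p = float(np.mean(t_rep >= t_obs))
    return PpcResult(stream=stream, p_value=p, t_observed=t_obs,
                     t_replicated=t_rep, variance=variance)


def stream_log_likelihoods(samples: PosteriorSamples, obs: ObservationSet,
                           n_draws: int = 200, seed: int = 0) -> pd.DataFrame:
    """Posterior-mean log-likelihood per stream (model-comparison table)."""
    from .observation import expected_means, negbin_logpmf

    rng = np.random.default_rng(seed)
    thetas = _select_draws(samples, n_draws, rng)
    streams = obs.records["stream"].to_numpy()
    y = obs.records["value"].to_numpy()
    totals = {s: np.zeros(len(thetas)) for s in np.unique(streams)}
    for d, vec in enumerate(thetas):
        params = ModelParameters.from_vector(vec)
        means = expected_means(params, obs)
        beta = np.array([params.beta[s] for s in streams])
        ll = negbin_logpmf(y, means, beta)
        for s in totals:
            totals[s][d] = ll[streams == s].sum()
    return pd.DataFrame(
        {
            "stream": list(totals),
            "mean_loglik": [float(v.mean()) for v in totals.values()],
            "sd_loglik": [float(v.std(ddof=1)) for v in totals.values()],
        }
    )
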