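"""The fitted object surface: `PsychDistressModel.fit()` -> results.

The model couples the stock-and-flow dynamics (:mod:`distressdyn.dynamics`)
with the negative-binomial observation model (:mod:`distressdyn.observation`)
and the prior set (:mod:`distressdyn.priors`), and samples the posterior

    p(theta | y)  propto  exp( log_likelihood(theta) + log_prior(theta) )

on an unconstrained reparameterisation (log / logit / log(gamma - 1)) with
the corresponding Jacobian terms. Constrained variants pin chosen
parameters (typically ``delta_i = 0`` or ``delta_r = 0``) to fixed values,
excluding them from the sampled vector.
"""

from __future__ import annotations

import math

import numpy as np

from .dynamics import (
    DYNAMIC_PARAM_NAMES,
    PARAM_NAMES,
    STREAMS,
    ModelParameters,
    _rk4_at_times,
    simulate_trajectory,
)
from .initialization import data_informed_center, laplace_initialization
from .observation import ObservationSet, total_log_likelihood
from .priors import PriorSpec, default_priors
from .sampling import (
    McmcConfig,
    PosteriorSamples,
    run_adaptive_metropolis,
    run_ensemble,
)
from .transforms import ParameterTransform

__all__ = ["PsychDistressModel", "sample_posterior", "fit_constrained"]

_N_DYN = len(DYNAMIC_PARAM_NAMES)


class _LikelihoodCache:
    """Precomputed arrays for fast repeated likelihood evaluation.

    Semantically identical to :func:`total_log_likelihood` (the test suite
    asserts agreement); avoids per-call DataFrame work inside MCMC.
    """

    def __init__(self, obs: ObservationSet, dt: float):
        self.dt = dt
        rec = obs.records
        self.y = rec["value"].to_numpy(float)
        t = obs.times
        streams = rec["stream"].to_numpy()
        self.beta_col = np.array([PARAM_NAMES.index(f"beta_{s}") for s in streams])
        self.lin_masks = []  # (mask, level index, slope index) per linear stream
        for stream, level, slope in (
            ("population", "P0", "g"), ("mortality", "D0", "h"),
            ("services", "C0", "u"),
        ):
            mask = streams == stream
            self.lin_masks.append(
                (mask, t[mask], PARAM_NAMES.index(level), PARAM_NAMES.index(slope))
            )
        dmask = streams == "distress"
        self.dmask = dmask
        td = t[dmask]
        self.d_order = np.argsort(td)
        self.d_times = td[self.d_order]

    def loglike(self, vec: np.ndarray) -> float:
        means = np.empty(self.y.size)
        for mask, tm, jl, js in self.lin_masks:
            means[mask] = vec[jl] + vec[js] * tm
        if self.dmask.any():
            M, _ = _rk4_at_times(vec[:_N_DYN], self.d_times, self.dt)
            vals = np.empty_like(M)
            vals[self.d_order] = M
            means[self.dmask] = vals
        if not np.all(np.isfinite(means)) or np.any(means <= 0):
            return -math.inf
        from .observation import _negbin_core

        beta = vec[self.beta_col]
        with np.errstate(over="ignore", invalid="ignore"):
            total = float(np.sum(_negbin_core(self.y, means, beta)))
        return total if math.isfinite(total) else -math.inf


class PsychDistressModel:
    """Bayesian one-stock model of high/very-high psychological distress.

    Parameters
    ----------
    observations : ObservationSet or pandas.DataFrame
        The four count streams (distress, population, mortality, services).
        An empty set yields the prior as the sampling target.
    priors : PriorSpec, optional
        Defaults to the shipped prior set.
    likelihood_dt : float
        Step bound (years) of the fixed-step RK4 likelihood path. The
        default weekly step keeps the integration error around 1e-12
        relative — many orders below the observation noise — at a fifth
        of the daily-step cost.
    """

    def __init__(self, observations, priors: PriorSpec | None = None,
                 likelihood_dt: float = 1.0 / 52.0):
        if not isinstance(observations, ObservationSet):
            observations = ObservationSet.from_dataframe(observations)
        self.observations = observations
        self.priors = priors if priors is not None else default_priors()
        self.priors.validate_complete()
        self.likelihood_dt = likelihood_dt

    @classmethod
    def from_csv(cls, path, priors=None, **kwargs) -> "PsychDistressModel":
        from .io import read_observations

        return cls(read_observations(path), priors=priors, **kwargs)

    # -- densities ------------------------------------------------------------

    def loglike(self, params: ModelParameters) -> float:
        """Total negative-binomial log-likelihood (0 for an empty data set)."""
        if len(self.observations) == 0:
            return 0.0
        return total_log_likelihood(params, self.observations, dt=self.likelihood_dt)

    def logprior(self, params: ModelParameters) -> float:
        return self.priors.log_prior(params)

    def logposterior(self, params: ModelParameters) -> float:
        lp = self.logprior(params)
        if not math.isfinite(lp):
            return -math.inf
        return lp + self.loglike(params)

    def simulate(self, params: ModelParameters, t_end: float = 12.0,
                 dt_store: float = 1.0 / 12.0, **kwargs):
        """Forward-simulate a trajectory (years since 2008.0)."""
        return simulate_trajectory(params, t_end, dt_store, **kwargs)

    # -- sampling -------------------------------------------------------------

    def _build_target(self, constrained: dict):
        """Log-posterior over the unconstrained sampled subvector."""
        sampled = [n for n in PARAM_NAMES if n not in constrained]
        if not sampled:
            raise ValueError("cannot pin every parameter")
        transform = ParameterTransform(
            [self.priors[n].low for n in sampled],
            [self.priors[n].high for n in sampled],
        )
        full = np.empty(len(PARAM_NAMES))
        pinned_idx = [PARAM_NAMES.index(n) for n in constrained]
        for j, n in zip(pinned_idx, constrained):
            full[j] = constrained[n]
        sampled_idx = np.array([PARAM_NAMES.index(n) for n in sampled])
        empty = len(self.observations) == 0
        priors = self.priors
        cache = None if empty else _LikelihoodCache(self.observations,
                                                    self.likelihood_dt)

        def log_post(z):
            theta = transform.to_constrained(z)
            vec = full.copy()
            vec[sampled_idx] = theta
            lp = priors.log_prior(vec)
            if not math.isfinite(lp):
                return -math.inf
            lp += transform.log_jacobian(z)
            if cache is not None:
                ll = cache.loglike(vec)
                if not math.isfinite(ll):
                    return -math.inf
                lp += ll
            return lp

        def draw_init(rng):
            theta0 = np.array([priors[n].rvs(rng) for n in sampled])
            return transform.to_unconstrained(theta0)

        return sampled, sampled_idx, full, transform, log_post, draw_init

    def fit(self, chains: int = 4, iterations: int = 4000,
            warmup_fraction: float = 0.5, seed: int = 0,
            sampler: str = "ensemble",
            pinned: dict | None = None):
        """Sample the posterior; returns :class:`PsychDistressResults`.

        ``pinned`` maps parameter names to fixed values (constrained fit);
        pinned parameters appear verbatim in every stored draw.
        """
        cfg = McmcConfig(
            chains=chains, iterations=iterations,
            warmup_fraction=warmup_fraction, seed=seed, sampler=sampler,
            constrained=dict(pinned or {}),
        )
        samples = sample_posterior(self.observations, self.priors, cfg,
                                   likelihood_dt=self.likelihood_dt)
        from .results import PsychDistressResults

        return PsychDistressResults(self, samples)


def sample_posterior(obs: ObservationSet, priors: PriorSpec, cfg: McmcConfig,
                     likelihood_dt: float = 1.0 / 52.0) -> PosteriorSamples:
    """Draw posterior samples for the model defined by (obs, priors).

    Deterministic given ``cfg.seed``. Returns post-warmup draws on the
    natural scale with pinned parameters included at their fixed values.
    """
    model = PsychDistressModel(obs, priors, likelihood_dt=likelihood_dt)
    sampled, sampled_idx, full, transform, log_post, draw_init = (
        model._build_target(cfg.constrained)
    )
    runner = {
        "adaptive-metropolis": run_adaptive_metropolis,
        "ensemble": run_ensemble,
    }.get(cfg.sampler)
    if runner is None:
        raise ValueError(f"unknown sampler {cfg.sampler!r}")

    init = None
    if len(obs) > 0:
        rng0 = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
        prior_sd = np.stack([draw_init(rng0) for _ in range(512)]).std(0)
        center = data_informed_center(obs, priors)
        for name, value in cfg.constrained.items():
            center.pop(name, None)
        z0 = transform.to_unconstrained(np.array([center[n] for n in sampled]))
        init = laplace_initialization(log_post, z0, sampled, prior_sd)

    draws_z, accept = runner(log_post, draw_init, transform.ndim, cfg, init=init)

    nchain, kept, _ = draws_z.shape
    out = np.empty((nchain, kept, len(PARAM_NAMES)))
    out[:, :, :] = full  # pinned values everywhere; sampled columns overwritten
    flat_theta = np.apply_along_axis(transform.to_constrained, 2, draws_z)
    out[:, :, sampled_idx] = flat_theta
    meta = {
        "chains": cfg.chains,
        "iterations": cfg.iterations,
        "warmup_fraction": cfg.warmup_fraction,
        "seed": cfg.seed,
        "sampler": cfg.sampler,
        "constrained": dict(cfg.constrained),
        "acceptance_rates": [float(a) for a in accept],
    }
    return PosteriorSamples(names=PARAM_NAMES, draws=out, meta=meta)


def fit_constrained(obs: ObservationSet, priors: PriorSpec, cfg: McmcConfig,
                    pinned: dict, **kwargs) -> PosteriorSamples:
    """Constrained fit: pin named parameters (e.g. {'delta_i': 0.0})."""
    unknown = set(pinned) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"cannot pin unknown parameters: {sorted(unknown)}")
    cfg = McmcConfig(
        chains=cfg.chains, iterations=cfg.iterations,
        warmup_fraction=cfg.warmup_fraction, seed=cfg.seed,
        sampler=cfg.sampler, constrained=dict(pinned),
    )
    return sample_posterior(obs, priors, cfg, **kwargs)
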