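"""Posterior sampling backends and convergence diagnostics.

Two samplers, both working on the unconstrained scale and both started
from the Laplace initialisation of :mod:`distressdyn.initialization` when
data are present (from prior draws for a prior-only target):

* ``"ensemble"`` (default) — emcee's affine-invariant ensemble. Affine
  invariance deals with the posterior's extreme anisotropy (administrative
  streams pin their parameters four orders of magnitude tighter than the
  prior). ``chains`` sets the number of walker groups used for the chain
  axis of the stored draws (and hence split R-hat); ``iterations`` counts
  ensemble moves, of which the warmup fraction is discarded.
* ``"adaptive-metropolis"`` — independent Haario-style adaptive
  random-walk Metropolis chains: proposal covariance blends the
  initialisation covariance with the empirical warmup covariance, and a
  global scale is tuned toward 23.4% acceptance during the discarded
  warmup only.

Chains are deterministically seeded from one master seed. Convergence is
summarised per parameter with rank-normalised split R-hat and bulk ESS
(arviz); any R-hat above 1.01 flags the run (non-fatally).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import PARAM_NAMES, ModelParameters
from .initialization import SamplerInit

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "run_adaptive_metropolis",
    "run_ensemble",
    "convergence_diagnostics",
]

RHAT_FLAG_THRESHOLD = 1.01
TARGET_ACCEPTANCE = 0.234


@dataclass
class McmcConfig:
    """MCMC run configuration.

    Defaults mirror the study configuration: four chains of 4000 iterations
    with the first half discarded as warmup. ``constrained`` maps parameter
    names to pinned fixed values that are excluded from sampling.
    """

    chains: int = 4
    iterations: int = 4000
    warmup_fraction: float = 0.5
    seed: int = 0
    sampler: str = "ensemble"
    constrained: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must lie in (0, 1)")
        if self.iterations < 2:
            raise ValueError("iterations must be >= 2")
        unknown = set(self.constrained) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"cannot pin unknown parameters: {sorted(unknown)}")

    @property
    def warmup(self) -> int:
        return int(round(self.iterations * self.warmup_fraction))


@dataclass
class PosteriorSamples:
    """Labelled posterior draws with chain structure and diagnostics.

    ``draws`` has shape (chains, retained_iterations, n_parameters) on the
    constrained (natural) scale, pinned parameters included at their fixed
    values. ``meta`` records the configuration, seed and acceptance rates;
    ``diagnostics`` is a per-parameter table of split R-hat and bulk ESS
    (NaN for pinned parameters).
    """

    names: tuple
    draws: np.ndarray
    meta: dict
    diagnostics: pd.DataFrame | None = None

    def __post_init__(self):
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must have shape (chains, iterations, n_params)")
        if self.diagnostics is None:
            self.diagnostics = convergence_diagnostics(self)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        """Total retained draws across chains."""
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, len(self.names))

    def to_dataframe(self) -> pd.DataFrame:
        nchain, nit, _ = self.draws.shape
        df = pd.DataFrame(self.flat, columns=list(self.names))
        df.insert(0, "iteration", np.tile(np.arange(nit), nchain))
        df.insert(0, "chain", np.repeat(np.arange(nchain), nit))
        return df

    def parameters_at(self, index: int) -> ModelParameters:
        """ModelParameters for one flattened draw."""
        return ModelParameters.from_vector(self.flat[index])

    def marginal(self, name: str) -> np.ndarray:
        return self.flat[:, self.names.index(name)]

    @property
    def rhat_flagged(self) -> bool:
        r = self.diagnostics["rhat"].dropna()
        return bool((r > RHAT_FLAG_THRESHOLD).any())

    # -- persistence ----------------------------------------------------------

    def to_csv(self, path, runlog_path=None) -> None:
        """Write draws as chain,iteration,<names...>; optional JSON run-log."""
        self.to_dataframe().to_csv(path, index=False)
        if runlog_path is not None:
            log = {
                "meta": {k: v for k, v in self.meta.items()},
                "diagnostics": {
                    name: {
                        "rhat": _json_float(row["rhat"]),
                        "ess_bulk": _json_float(row["ess_bulk"]),
                    }
                    for name, row in self.diagnostics.iterrows()
                },
                "rhat_flagged": self.rhat_flagged,
            }
            Path(runlog_path).write_text(json.dumps(log, indent=2))

    @classmethod
    def from_csv(cls, path, meta=None) -> "PosteriorSamples":
        df = pd.read_csv(path)
        names = tuple(c for c in df.columns if c not in ("chain", "iteration"))
        nchain = df["chain"].nunique()
        nit = df["iteration"].nunique()
        draws = (
            df.sort_values(["chain", "iteration"])[list(names)]
            .to_numpy()
            .reshape(nchain, nit, len(names))
        )
        return cls(names=names, draws=draws, meta=meta or {})


def _json_float(x):
    x = float(x)
    return None if math.isnan(x) else x


def convergence_diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """Rank-normalised split R-hat and bulk ESS per parameter.

    Degenerate (constant) parameters — e.g. pinned during a constrained
    fit — get NaN R-hat and are excluded from the convergence flag.
    """
    if samples.draws.shape[0] < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    import arviz as az

    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(samples.names):
            x = samples.draws[:, :, j]
            if np.allclose(x, x.flat[0]):
                rows[name] = {"rhat": math.nan, "ess_bulk": math.nan}
                continue
            rows[name] = {
                "rhat": float(az.rhat(x.copy())),
                "ess_bulk": float(az.ess(x.copy())),
            }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("parameter")


def _start_points(log_post, init, draw_init, rng, n, max_tries: int = 100):
    """n finite-log-posterior starting points.

    From the Laplace initialisation when available (scatter shrinking until
    the log posterior is finite), otherwise from prior draws.
    """
    pts = np.empty((n, init.z_center.size if init is not None else draw_init(rng).size))
    for i in range(n):
        ok = False
        if init is not None:
            factor = 1.0
            for _ in range(max_tries):
                cand = init.z_center + factor * (init.chol @ rng.standard_normal(pts.shape[1]))
                if math.isfinite(log_post(cand)):
                    pts[i] = cand
                    ok = True
                    break
                factor *= 0.7
        else:
            for _ in range(max_tries):
                cand = draw_init(rng)
                if math.isfinite(log_post(cand)):
                    pts[i] = cand
                    ok = True
                    break
        if not ok:
            raise RuntimeError(
                f"failed to find a finite starting point after {max_tries} attempts"
            )
    return pts


def run_adaptive_metropolis(log_post, draw_init, ndim: int, cfg: McmcConfig,
                            init: SamplerInit | None = None):
    """Independent adaptive-Metropolis chains; returns (draws_z, accept_rates)."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains + 1)
    warmup = cfg.warmup
    kept = cfg.iterations - warmup
    out = np.empty((cfg.chains, kept, ndim))
    accept_rates = []

    rng0 = np.random.default_rng(seeds[-1])
    if init is not None:
        cov0 = init.cov
    else:
        prior_z = np.stack([draw_init(rng0) for _ in range(512)])
        cov0 = np.cov(prior_z, rowvar=False) + 1e-10 * np.eye(ndim)

    for c in range(cfg.chains):
        rng = np.random.default_rng(seeds[c])
        z = _start_points(log_post, init, draw_init, rng, 1)[0]
        lp = log_post(z)
        mean = z.copy()
        cov = cov0.copy()
        chol = np.linalg.cholesky(cov0)
        log_scale = math.log(2.38 / math.sqrt(ndim))
        n_hist = 1
        accepted = 0

        for it in range(cfg.iterations):
            step = math.exp(log_scale) * (chol @ rng.standard_normal(ndim))
            z_prop = z + step
            lp_prop = log_post(z_prop)
            log_alpha = lp_prop - lp
            if math.log(rng.uniform()) < log_alpha:
                z, lp = z_prop, lp_prop
                if it >= warmup:
                    accepted += 1
            if it < warmup:
                # Robbins-Monro scale tuning toward 23.4% acceptance
                if log_alpha >= 0.0:
                    alpha = 1.0
                elif math.isfinite(log_alpha):
                    alpha = math.exp(log_alpha)
                else:
                    alpha = 0.0
                log_scale += 2.0 * (alpha - TARGET_ACCEPTANCE) / (10.0 + it) ** 0.6
                # recursive empirical covariance blended with the initial one
                n_hist += 1
                delta = z - mean
                mean += delta / n_hist
                cov += (np.outer(delta, z - mean) - cov) / n_hist
                if it >= max(100, 2 * ndim) and it % 50 == 0:
                    w = min(1.0, n_hist / (n_hist + 200.0))
                    blended = w * cov + (1.0 - w) * cov0 + 1e-12 * np.eye(ndim)
                    try:
                        chol = np.linalg.cholesky(blended)
                    except np.linalg.LinAlgError:  # pragma: no cover
                        pass
            else:
                out[c, it - warmup] = z
        accept_rates.append(accepted / max(kept, 1))
    return out, accept_rates


def run_ensemble(log_post, draw_init, ndim: int, cfg: McmcConfig,
                 init: SamplerInit | None = None):
    """Affine-invariant ensemble backend (emcee).

    Walkers are split into ``cfg.chains`` groups for the chain axis of the
    returned draws; ``cfg.iterations`` counts ensemble moves and the warmup
    fraction of moves is discarded.
    """
    import emcee

    seed32 = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] // 2)
    rng = np.random.default_rng(seed32)
    walkers_per_group = max(1, math.ceil((2 * ndim + 2) / cfg.chains))
    nwalkers = cfg.chains * walkers_per_group
    p0 = _start_points(log_post, init, draw_init, rng, nwalkers)

    # differential-evolution moves mix far better than the default stretch
    # move on this strongly correlated, highly anisotropic posterior
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_post, moves=moves)
    sampler._random = np.random.RandomState(seed32)
    state = sampler.run_mcmc(p0, max(cfg.warmup, 1), progress=False)

    # Re-seat walkers trapped in negligible-mass local basins (e.g. the
    # heavy-tail beta -> 0 regime) onto cloned good positions before the
    # retained phase; only warmup draws are affected.
    lp = np.asarray(state.log_prob)
    stuck = lp < np.median(lp) - 30.0
    if stuck.any():
        good = np.flatnonzero(~stuck)
        coords = state.coords.copy()
        for w in np.flatnonzero(stuck):
            donor = good[rng.integers(good.size)]
            coords[w] = coords[donor] + 1e-3 * rng.standard_normal(ndim) * (
                np.abs(coords[donor]) + 1e-8
            )
            if not math.isfinite(log_post(coords[w])):
                coords[w] = coords[donor]
        state = emcee.State(coords, random_state=state.random_state)

    sampler.reset()
    sampler.run_mcmc(state, cfg.iterations - cfg.warmup, progress=False)
    chain = sampler.get_chain()  # (steps, walkers, ndim)
    kept_steps = chain.shape[0]
    grouped = chain.reshape(kept_steps, cfg.chains, walkers_per_group, ndim)
    draws = np.moveaxis(grouped, 1, 0).reshape(
        cfg.chains, kept_steps * walkers_per_group, ndim
    )
    accept = [float(a) for a in
              np.mean(sampler.acceptance_fraction.reshape(cfg.chains, -1), axis=1)]
    return draws, accept
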