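"""Prior distributions for the dynamic-model parameters.

Three families cover every parameter:

* truncated normal (possibly one-sided, possibly unbounded = plain normal),
* shifted lognormal (lognormal on ``x - shift``; shift 1 for the mortality
  hazard ratio gamma, shift 0 otherwise),
* plain normal (a truncated normal with infinite bounds).

Densities are written directly in terms of ``scipy.special`` primitives
(log_ndtr for stable truncation constants) so a prior evaluation costs
microseconds inside the MCMC loop; the test suite cross-checks every family
against the corresponding scipy.stats distribution.

The default prior set encodes, per parameter: the initial prevalence as the
midpoint of the 2007/2009 survey estimates (normal(0.1464, 0.0293) on
[0, 1]); linear-regression level and slope priors for population, mortality
and services provision with 20%-of-mean scales; a shifted lognormal for
gamma - 1 with mode 0.37 and 95th percentile 1; a lognormal for the natural
recovery rate s with mode 0.31 and 95th percentile 0.45; non-informative
normal(0, 0.5) priors for the initial incidence (truncated at 0) and its
trend; normal(0.1845, 0.0369) on [0, 1] for initial treatment effectiveness;
and normal(0, 0.0125) for the effectiveness trend (absolute value about
3.75%/yr at three standard deviations). Dispersions beta get a weakly
informative normal(1, 1) prior on log10(beta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri

from .dynamics import PARAM_NAMES, STREAMS

__all__ = [
    "Prior",
    "TruncatedNormal",
    "LogNormal",
    "Log10Normal",
    "PriorSpec",
    "default_priors",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class Prior:
    """Abstract univariate prior with logpdf/ppf/rvs and support bounds."""

    low: float
    high: float

    def logpdf(self, x: float) -> float:
        raise NotImplementedError

    def ppf(self, q: float) -> float:
        raise NotImplementedError

    def rvs(self, rng: np.random.Generator) -> float:
        return self.ppf(rng.uniform())

    @property
    def mean(self) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class TruncatedNormal(Prior):
    """Normal(loc, scale) truncated to [low, high]; density renormalised."""

    loc: float
    scale: float
    low: float = -math.inf
    high: float = math.inf

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not self.low < self.high:
            raise ValueError("bounds must be ordered low < high")

    def _alpha_beta(self):
        return ((self.low - self.loc) / self.scale,
                (self.high - self.loc) / self.scale)

    @property
    def _log_mass(self) -> float:
        a, b = self._alpha_beta()
        if not math.isfinite(a) and math.isfinite(b):
            return log_ndtr(b)
        if math.isfinite(a) and not math.isfinite(b):
            return log_ndtr(-a)
        if not math.isfinite(a) and not math.isfinite(b):
            return 0.0
        return math.log(ndtr(b) - ndtr(a))

    def logpdf(self, x: float) -> float:
        if x < self.low or x > self.high:
            return -math.inf
        z = (x - self.loc) / self.scale
        return -0.5 * z * z - _LOG_SQRT_2PI - math.log(self.scale) - self._log_mass

    def ppf(self, q: float) -> float:
        a, b = self._alpha_beta()
        Fa = ndtr(a) if math.isfinite(a) else 0.0
        Fb = ndtr(b) if math.isfinite(b) else 1.0
        return self.loc + self.scale * ndtri(Fa + q * (Fb - Fa))

    @property
    def mean(self) -> float:
        a, b = self._alpha_beta()
        phi = lambda z: math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
        pa = phi(a) if math.isfinite(a) else 0.0
        pb = phi(b) if math.isfinite(b) else 0.0
        mass = math.exp(self._log_mass)
        return self.loc + self.scale * (pa - pb) / mass

    @property
    def mode(self) -> float:
        return min(max(self.loc, self.low), self.high)


@dataclass(frozen=True)
class LogNormal(Prior):
    """lognormal(mu, sigma) applied to x - shift (support x > shift)."""

    mu: float
    sigma: float
    shift: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def low(self) -> float:
        return self.shift

    @property
    def high(self) -> float:
        return math.inf

    def logpdf(self, x: float) -> float:
        y = x - self.shift
        if y <= 0:
            return -math.inf
        ly = math.log(y)
        z = (ly - self.mu) / self.sigma
        return -0.5 * z * z - _LOG_SQRT_2PI - math.log(self.sigma) - ly

    def ppf(self, q: float) -> float:
        return self.shift + math.exp(self.mu + self.sigma * ndtri(q))

    @property
    def mean(self) -> float:
        return self.shift + math.exp(self.mu + 0.5 * self.sigma**2)

    @property
    def mode(self) -> float:
        return self.shift + math.exp(self.mu - self.sigma**2)


@dataclass(frozen=True)
class Log10Normal(Prior):
    """Normal(loc, scale) on log10(x); support x > 0."""

    loc: float
    scale: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    low: float = 0.0
    high: float = math.inf

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        z = (math.log10(x) - self.loc) / self.scale
        # includes the Jacobian d(log10 x)/dx = 1/(x ln 10)
        return (-0.5 * z * z - _LOG_SQRT_2PI - math.log(self.scale)
                - math.log(x) - math.log(math.log(10.0)))

    def ppf(self, q: float) -> float:
        return 10.0 ** (self.loc + self.scale * ndtri(q))

    @property
    def mean(self) -> float:
        ln10 = math.log(10.0)
        return math.exp(self.loc * ln10 + 0.5 * (self.scale * ln10) ** 2)

    @property
    def mode(self) -> float:
        ln10 = math.log(10.0)
        return math.exp(self.loc * ln10 - (self.scale * ln10) ** 2)


class PriorSpec:
    """Mapping of parameter name -> :class:`Prior` covering the sampled vector."""

    def __init__(self, priors: dict):
        unknown = set(priors) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"priors given for unknown parameters: {sorted(unknown)}")
        self._priors = dict(priors)

    def __getitem__(self, name: str) -> Prior:
        try:
            return self._priors[name]
        except KeyError:
            raise KeyError(f"no prior specified for parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._priors

    def __iter__(self):
        return iter(self._priors)

    def items(self):
        return self._priors.items()

    def validate_complete(self, names=PARAM_NAMES) -> None:
        missing = [n for n in names if n not in self._priors]
        if missing:
            raise ValueError(f"parameters lacking a prior: {missing}")

    def log_prior(self, params) -> float:
        """Sum of log prior densities over all sampled parameters.

        ``params`` may be a ModelParameters instance or a vector in
        canonical order. gamma's prior is the shifted lognormal on
        gamma - 1; returns -inf outside any truncation bound.
        """
        vec = params.to_vector() if hasattr(params, "to_vector") else np.asarray(params, float)
        self.validate_complete()
        total = 0.0
        for name, x in zip(PARAM_NAMES, vec):
            lp = self._priors[name].logpdf(float(x))
            if not math.isfinite(lp):
                return -math.inf
            total += lp
        return total

    # -- serialisation --------------------------------------------------------

    def to_toml(self, path) -> None:
        lines = []
        for name, p in self._priors.items():
            lines.append(f"[{name}]")
            if isinstance(p, TruncatedNormal):
                lines.append('family = "truncated-normal"')
                lines.append(f"loc = {p.loc!r}")
                lines.append(f"scale = {p.scale!r}")
                if math.isfinite(p.low):
                    lines.append(f"low = {p.low!r}")
                if math.isfinite(p.high):
                    lines.append(f"high = {p.high!r}")
            elif isinstance(p, LogNormal):
                lines.append('family = "shifted-lognormal"')
                lines.append(f"mu = {p.mu!r}")
                lines.append(f"sigma = {p.sigma!r}")
                lines.append(f"shift = {p.shift!r}")
            elif isinstance(p, Log10Normal):
                lines.append('family = "log10-normal"')
                lines.append(f"loc = {p.loc!r}")
                lines.append(f"scale = {p.scale!r}")
            else:  # pragma: no cover
                raise TypeError(f"cannot serialise prior family {type(p).__name__}")
            lines.append("")
        Path(path).write_text("\n".join(lines))

    @classmethod
    def from_toml(cls, path) -> "PriorSpec":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        priors = {}
        for name, entry in data.items():
            family = entry.get("family")
            if family == "truncated-normal":
                priors[name] = TruncatedNormal(
                    loc=float(entry["loc"]), scale=float(entry["scale"]),
                    low=float(entry.get("low", -math.inf)),
                    high=float(entry.get("high", math.inf)),
                )
            elif family == "shifted-lognormal":
                priors[name] = LogNormal(
                    mu=float(entry["mu"]), sigma=float(entry["sigma"]),
                    shift=float(entry.get("shift", 0.0)),
                )
            elif family == "log10-normal":
                priors[name] = Log10Normal(
                    loc=float(entry["loc"]), scale=float(entry["scale"]),
                )
            else:
                raise ValueError(f"unknown prior family {family!r} for {name!r}")
        return cls(priors)


def default_priors_path() -> Path:
    """Path of the shipped TOML prior configuration (same content as
    :func:`default_priors`)."""
    return Path(__file__).with_name("priors_default.toml")


def default_priors() -> PriorSpec:
    """The shipped prior set (see module docstring for the rationale)."""
    priors = {
        "prev0": TruncatedNormal(0.1464, 0.0293, 0.0, 1.0),
        "P0": TruncatedNormal(16167328.0, 3233466.0, 0.0, math.inf),
        "g": TruncatedNormal(308538.0, 61708.0),
        "D0": TruncatedNormal(136840.0, 27368.0, 0.0, math.inf),
        "h": TruncatedNormal(2228.7, 445.7),
        "gamma": LogNormal(-0.7733, 0.4701, shift=1.0),
        "i0": TruncatedNormal(0.0, 0.5, 0.0, math.inf),
        "delta_i": TruncatedNormal(0.0, 0.5),
        "s": LogNormal(-1.1315, 0.2024),
        "C0": TruncatedNormal(305315.0, 61063.0, 0.0, math.inf),
        "u": TruncatedNormal(43696.0, 8739.0),
        "r0": TruncatedNormal(0.1845, 0.0369, 0.0, 1.0),
        "delta_r": TruncatedNormal(0.0, 0.0125),
    }
    for stream in STREAMS:
        priors[f"beta_{stream}"] = Log10Normal(1.0, 1.0)
    return PriorSpec(priors)
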