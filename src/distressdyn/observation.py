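"""Observed count streams and the negative-binomial observation model.

Four yearly count streams drive the fit:

* ``distress`` — adults with high/very-high psychological distress at the
  survey years (sparse, biennial),
* ``population`` — mid-year adult population,
* ``mortality`` — total adult deaths per year,
* ``services`` — adults with high/very-high distress receiving subsidised
  mental-health care per year.

Each observed count ``y`` is modelled as negative binomial with mean equal
to the corresponding model output and inverse-scale dispersion ``beta``
(gamma-Poisson with shape ``beta * mean`` and inverse scale ``beta``), so
``E[y] = mean`` and ``Var[y] = mean * (1 + 1/beta)``. Streams and time
points are conditionally independent given the parameters, so the total
log-likelihood is a sum over records.

Records are evaluated at mid-year: a record for calendar year ``Y`` is
compared with the model at ``t = (Y - 2008) + 0.5``. The population stream
is a 30-June snapshot, and yearly flow totals are approximated by the
mid-year instantaneous rate, which is exact for linear trends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dynamics import (
    STREAMS,
    TIME_ORIGIN,
    ModelParameters,
    Trajectory,
    distress_stock_at,
)

__all__ = [
    "ObservationSet",
    "observation_time",
    "observation_means",
    "negbin_logpmf",
    "total_log_likelihood",
]


def observation_time(year) -> np.ndarray:
    """Model time (years since 2008.0) at which a calendar-year record is evaluated."""
    return np.asarray(year, float) - TIME_ORIGIN + 0.5


@dataclass(frozen=True)
class ObservationSet:
    """The observed count streams as a validated (stream, year, value) table."""

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        required = {"stream", "year", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"records must have columns {sorted(required)}")
        unknown = set(df["stream"]) - set(STREAMS)
        if unknown:
            raise ValueError(
                f"unknown stream names {sorted(unknown)}; allowed: {list(STREAMS)}"
            )
        values = df["value"].to_numpy()
        if np.any(values < 0):
            raise ValueError("observed counts must be non-negative")
        if not np.all(np.equal(np.mod(values, 1), 0)):
            raise ValueError("observed counts must be integers")
        if df.duplicated(subset=["stream", "year"]).any():
            dups = df[df.duplicated(subset=["stream", "year"], keep=False)]
            raise ValueError(
                f"duplicate (stream, year) records:\n{dups.to_string(index=False)}"
            )
        object.__setattr__(
            self, "records", df.astype({"year": int, "value": np.int64}).reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ObservationSet":
        return cls(df[["stream", "year", "value"]].copy())

    @classmethod
    def empty(cls) -> "ObservationSet":
        return cls(pd.DataFrame({"stream": [], "year": [], "value": []}))

    def stream(self, name: str) -> pd.DataFrame:
        if name not in STREAMS:
            raise ValueError(f"unknown stream {name!r}; allowed: {list(STREAMS)}")
        return self.records[self.records["stream"] == name]

    @property
    def times(self) -> np.ndarray:
        """Evaluation times of all records, in record order."""
        return observation_time(self.records["year"].to_numpy())

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def observation_means(traj: Trajectory, obs: ObservationSet) -> np.ndarray:
    """Expected count for every record, in record order.

    distress -> M, population -> P, mortality -> D, services -> C, each
    read from the trajectory at the record's mid-year evaluation time.
    Raises ValueError if any record's time falls outside the trajectory.
    """
    field_of = {"distress": "M", "population": "P", "mortality": "D", "services": "C"}
    t = obs.times
    out = np.empty(len(obs))
    for stream, fieldname in field_of.items():
        mask = (obs.records["stream"] == stream).to_numpy()
        if mask.any():
            out[mask] = traj.at(t[mask], fieldname)
    return out


def _negbin_core(y, mean, beta):
    """Vectorised NB log-pmf on validated float inputs.

    For extreme dispersions (``alpha = beta * mean`` so large that the
    gammaln difference loses double precision) the Poisson limit is exact
    to working precision and is used instead.
    """
    y, mean, beta = np.broadcast_arrays(y, mean, beta)
    alpha = beta * mean
    out = np.empty(y.shape)
    extreme = (alpha > 1e12) | (beta > 1e10)
    if np.any(~extreme):
        ys, ms, bs, al = (a[~extreme] for a in (y, mean, beta, alpha))
        out[~extreme] = (
            gammaln(ys + al) - gammaln(al) - gammaln(ys + 1.0)
            - al * np.log1p(1.0 / bs)
            - ys * np.log1p(bs)
        )
    if np.any(extreme):
        ys, ms = y[extreme], mean[extreme]
        out[extreme] = ys * np.log(ms) - ms - gammaln(ys + 1.0)
    return out


def negbin_logpmf(y, mean, beta):
    """Log-pmf of the negative binomial in mean/inverse-scale form.

    Gamma-Poisson mixture with shape ``alpha = beta * mean`` and inverse
    scale ``beta``: E[y] = mean, Var[y] = mean * (1 + 1/beta). Vectorised
    over broadcastable inputs.
    """
    y = np.asarray(y)
    mean = np.asarray(mean, float)
    beta = np.asarray(beta, float)
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("y must be a non-negative integer")
    if np.any(mean <= 0):
        raise ValueError("mean must be positive")
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    out = _negbin_core(y.astype(float), mean, beta)
    return float(out) if out.ndim == 0 else out


def expected_means(params: ModelParameters, obs: ObservationSet,
                   dt: float = 1.0 / 365.0) -> np.ndarray:
    """Expected count per record straight from the parameters (fast path).

    The exogenous streams are closed-form; the distress stream requires one
    fixed-step RK4 solve up to the last distress record.
    """
    t = obs.times
    streams = obs.records["stream"].to_numpy()
    out = np.empty(len(obs))
    for stream, expr in (
        ("population", lambda tt: params.P0 + params.g * tt),
        ("mortality", lambda tt: params.D0 + params.h * tt),
        ("services", lambda tt: params.C0 + params.u * tt),
    ):
        mask = streams == stream
        if mask.any():
            out[mask] = expr(t[mask])
    mask = streams == "distress"
    if mask.any():
        td = t[mask]
        order = np.argsort(td)
        M, _ = distress_stock_at(params, td[order], dt=dt)
        vals = np.empty_like(M)
        vals[order] = M
        out[mask] = vals
    return out


def total_log_likelihood(params: ModelParameters, obs: ObservationSet,
                         dt: float = 1.0 / 365.0) -> float:
    """Sum of negative-binomial log-pmfs over all records.

    Deterministic given ``params``. Returns -inf (without raising) if any
    expected mean is non-positive. Each stream uses its own dispersion
    ``params.beta[stream]``; a missing dispersion raises KeyError.
    """
    if len(obs) == 0:
        raise ValueError("observation set is empty")
    try:
        means = expected_means(params, obs, dt=dt)
    except FloatingPointError:
        return -math.inf
    if np.any(means <= 0) or not np.all(np.isfinite(means)):
        return -math.inf
    streams = obs.records["stream"].to_numpy()
    beta = np.array([params.beta[s] for s in streams])
    y = obs.records["value"].to_numpy()
    with np.errstate(over="ignore", invalid="ignore"):
        total = float(np.sum(negbin_logpmf(y, means, beta)))
    return total if math.isfinite(total) else -math.inf
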