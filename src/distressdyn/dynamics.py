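"""Stock-and-flow dynamics of high/very-high psychological distress.

The model tracks a single stock ``M(t)``: the number of adults currently
experiencing high to very high psychological distress (K10 score >= 22).
People with lower distress develop high/very-high distress at a per-capita
rate ``i(t)``, die at a background rate ``k(t)`` (multiplied by the hazard
ratio ``gamma`` while in the stock), recover spontaneously at rate ``s``,
and recover through treatment at an absolute rate ``r(t) * C(t)`` where
``C(t)`` is the number of patients treated per year and ``r(t)`` the
proportion of treated patients who recover.

Exogenous drivers:

* total population ``P(t) = P0 + g t`` (linear),
* total deaths per year ``D(t) = D0 + h t`` (linear),
* treatment provision ``C(t) = C0 + u t`` (linear),
* per-capita incidence ``i(t) = i0 exp(delta_i t)`` (constant fractional
  rate of change),
* treatment effectiveness ``r(t) = r0 exp(delta_r t)``, clipped at 1.

The background mortality rate ``k(t)`` is defined implicitly by the total
mortality identity ``k (P - M) + gamma k M = D`` and is recomputed from the
instantaneous state inside the derivative, so the identity holds exactly at
every integrator evaluation.

Time is measured in years since the start of 2008 (t = 0 at 2008.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp

__all__ = [
    "STREAMS",
    "DYNAMIC_PARAM_NAMES",
    "PARAM_NAMES",
    "TIME_ORIGIN",
    "ModelParameters",
    "Trajectory",
    "exogenous_drivers",
    "background_mortality_rate",
    "simulate_trajectory",
    "distress_stock_at",
]

#: Calendar year at simulation time t = 0.
TIME_ORIGIN = 2008.0

#: Observation streams, in canonical order.
STREAMS = ("distress", "population", "mortality", "services")

#: Dynamic (ODE) parameters, in canonical vector order.
DYNAMIC_PARAM_NAMES = (
    "prev0", "P0", "g", "D0", "h", "gamma", "i0", "delta_i",
    "s", "C0", "u", "r0", "delta_r",
)

#: Full sampled parameter vector: dynamics plus one dispersion per stream.
PARAM_NAMES = DYNAMIC_PARAM_NAMES + tuple(f"beta_{s}" for s in STREAMS)


@dataclass
class ModelParameters:
    """Full parameter vector of the dynamic model plus observation dispersions.

    Parameters
    ----------
    prev0 : float
        Initial prevalence M(0)/P(0), in [0, 1].
    P0, g : float
        Initial adult population (persons) and its yearly increase
        (persons/year).
    D0, h : float
        Initial total adult mortality (deaths/year) and its yearly increase
        (deaths/year^2).
    gamma : float
        Mortality hazard ratio for the distressed stock (>= 1).
    i0, delta_i : float
        Initial per-capita incidence rate (1/year) and its fractional
        yearly rate of change.
    s : float
        Natural (spontaneous) per-capita recovery rate (1/year).
    C0, u : float
        Initial treatment provision (patients/year) and its yearly increase
        (patients/year^2).
    r0, delta_r : float
        Initial treatment effectiveness (proportion of treated patients
        recovering per year, in [0, 1]) and its fractional yearly rate of
        change.
    beta : dict
        Negative-binomial inverse-scale dispersion per observation stream;
        observation variance is mean * (1 + 1/beta).
    """

    prev0: float
    P0: float
    g: float
    D0: float
    h: float
    gamma: float
    i0: float
    delta_i: float
    s: float
    C0: float
    u: float
    r0: float
    delta_r: float
    beta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.prev0 <= 1.0:
            raise ValueError(f"prev0 must lie in [0, 1], got {self.prev0}")
        for name in ("P0", "D0", "s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        # i0 = 0 (no incidence) and C0 = 0 (no treatment) are valid
        # degenerate configurations; the priors exclude them during inference
        for name in ("C0", "i0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.gamma < 1.0:
            raise ValueError(f"gamma must be >= 1, got {self.gamma}")
        if not 0.0 <= self.r0 <= 1.0:
            raise ValueError(f"r0 must lie in [0, 1], got {self.r0}")
        for stream, b in self.beta.items():
            if b <= 0:
                raise ValueError(f"beta[{stream!r}] must be positive, got {b}")

    @property
    def M0(self) -> float:
        """Initial stock size, prev0 * P0 (persons)."""
        return self.prev0 * self.P0

    # -- vector interface used by the sampler ---------------------------------

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical order of :data:`PARAM_NAMES`."""
        dyn = [getattr(self, n) for n in DYNAMIC_PARAM_NAMES]
        disp = [self.beta[s] for s in STREAMS]
        return np.asarray(dyn + disp, dtype=float)

    @classmethod
    def from_vector(cls, values) -> "ModelParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(
                f"expected {len(PARAM_NAMES)} values, got shape {values.shape}"
            )
        dyn = dict(zip(DYNAMIC_PARAM_NAMES, values[: len(DYNAMIC_PARAM_NAMES)]))
        beta = dict(zip(STREAMS, values[len(DYNAMIC_PARAM_NAMES):]))
        return cls(**dyn, beta=beta)

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)

    def _dyn_array(self) -> np.ndarray:
        return np.asarray([getattr(self, n) for n in DYNAMIC_PARAM_NAMES], float)


@dataclass
class Trajectory:
    """Time-indexed model state and auxiliaries on a stored grid.

    ``times`` are years since 2008.0. ``prevalence`` is M/P exactly at every
    stored point, and the mortality identity k (P - M) + gamma k M = D holds
    at every stored point by construction of k.
    """

    times: np.ndarray
    M: np.ndarray
    P: np.ndarray
    D: np.ndarray
    C: np.ndarray
    i: np.ndarray
    r: np.ndarray
    k: np.ndarray
    prevalence: np.ndarray
    negative_stock_guard: bool = False
    r_clipped: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "M": self.M,
                "P": self.P,
                "D": self.D,
                "C": self.C,
                "i": self.i,
                "r": self.r,
                "k": self.k,
                "prevalence": self.prevalence,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def at(self, t, field: str = "M"):
        """Linear interpolation of a stored quantity at time(s) ``t``."""
        t = np.asarray(t, float)
        if np.any(t < self.times[0] - 1e-12) or np.any(t > self.times[-1] + 1e-12):
            raise ValueError(
                f"time outside trajectory range [{self.times[0]}, {self.times[-1]}]"
            )
        return np.interp(t, self.times, getattr(self, field))


def exogenous_drivers(params: ModelParameters, t):
    """Exogenous inputs (P, D, C, i, r) at time(s) ``t`` (years since 2008).

    P, D and C follow linear trends; i and r change at constant fractional
    rates (exponential in time). r is clipped at 1; a UserWarning is emitted
    when clipping occurs.

    Raises
    ------
    ValueError
        If any t < 0, or the linear drivers leave their physical range
        (P <= 0, D <= 0, or C < 0).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    P = params.P0 + params.g * t
    D = params.D0 + params.h * t
    C = params.C0 + params.u * t
    if np.any(P <= 0):
        raise ValueError("population P(t) <= 0 at requested time")
    if np.any(D <= 0):
        raise ValueError("total mortality D(t) <= 0 at requested time")
    if np.any(C < 0):
        raise ValueError("treatment provision C(t) < 0 at requested time")
    i = params.i0 * np.exp(params.delta_i * t)
    r = params.r0 * np.exp(params.delta_r * t)
    if np.any(r > 1.0):
        warnings.warn(
            "treatment effectiveness r(t) exceeded 1 and was clipped", UserWarning
        )
        r = np.minimum(r, 1.0)
    return P, D, C, i, r


def background_mortality_rate(P, M, D, gamma):
    """Background per-capita mortality rate k from the total-mortality identity.

    k is defined by inverting D = k (P - M) + gamma k M, i.e.
    k = D / (P - M + gamma M). Substituting back reproduces D exactly.
    """
    P = np.asarray(P, float)
    M = np.asarray(M, float)
    D = np.asarray(D, float)
    if np.any(M < 0) or np.any(M > P):
        raise ValueError("require 0 <= M <= P")
    if np.any(D <= 0):
        raise ValueError("require D > 0")
    if np.any(np.asarray(gamma) < 1):
        raise ValueError("require gamma >= 1")
    denom = P - M + gamma * M
    if np.any(denom <= 0):
        raise ValueError("denominator P - M + gamma M must be positive")
    out = D / denom
    return float(out) if out.ndim == 0 else out


# -- compiled fixed-step core -------------------------------------------------
#
# The same right-hand side as the adaptive path, integrated with classical
# RK4 on a fixed fine grid. Used as the fast likelihood path (thousands of
# solves per MCMC run) and as the fallback integrator. The per-step
# negative-stock guard caps the treatment-recovery outflow at the remaining
# stock: after each step M is clamped at 0 and the guard flag is raised.

@njit(cache=True)
def _deriv(M, t, P0, g, D0, h, gamma, i0, delta_i, s, C0, u, r0, delta_r):
    P = P0 + g * t
    D = D0 + h * t
    C = C0 + u * t
    i = i0 * np.exp(delta_i * t)
    r = r0 * np.exp(delta_r * t)
    if r > 1.0:
        r = 1.0
    denom = P - M + gamma * M
    if denom <= 0.0 or P <= 0.0 or D <= 0.0 or C < 0.0:
        return np.nan
    k = D / denom
    rc = r * C
    if M <= 0.0:
        rc = 0.0
    return i * (P - M) - gamma * k * M - s * M - rc


@njit(cache=True)
def _rk4_at_times(dyn, t_eval, dt):
    """Integrate M with fixed-step RK4, landing exactly on each t_eval.

    dyn is the 13-vector of dynamic parameters in canonical order.
    Returns (M at t_eval, guard_flag). Steps within each inter-evaluation
    segment are equal and no larger than dt.
    """
    prev0 = dyn[0]
    P0, g, D0, h, gamma = dyn[1], dyn[2], dyn[3], dyn[4], dyn[5]
    i0, delta_i, s = dyn[6], dyn[7], dyn[8]
    C0, u, r0, delta_r = dyn[9], dyn[10], dyn[11], dyn[12]

    M = prev0 * P0
    t = 0.0
    guard = False
    out = np.empty(t_eval.shape[0])
    for j in range(t_eval.shape[0]):
        t_target = t_eval[j]
        span = t_target - t
        if span > 1e-14:
            n_steps = int(np.ceil(span / dt))
            hstep = span / n_steps
            for _ in range(n_steps):
                k1 = _deriv(M, t, P0, g, D0, h, gamma, i0, delta_i, s, C0, u, r0, delta_r)
                k2 = _deriv(M + 0.5 * hstep * k1, t + 0.5 * hstep, P0, g, D0, h, gamma,
                            i0, delta_i, s, C0, u, r0, delta_r)
                k3 = _deriv(M + 0.5 * hstep * k2, t + 0.5 * hstep, P0, g, D0, h, gamma,
                            i0, delta_i, s, C0, u, r0, delta_r)
                k4 = _deriv(M + hstep * k3, t + hstep, P0, g, D0, h, gamma,
                            i0, delta_i, s, C0, u, r0, delta_r)
                M = M + hstep * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
                t = t + hstep
                if not np.isfinite(M):
                    out[:] = np.nan
                    return out, guard
                if M < 0.0:
                    M = 0.0
                    guard = True
        out[j] = M
    return out, guard


def distress_stock_at(params: ModelParameters, times, dt: float = 1.0 / 365.0):
    """Fast evaluation of the distress stock M at sorted times >= 0.

    Fixed-step RK4 at step <= ``dt`` years (default one day). This is the
    likelihood path; :func:`simulate_trajectory` is the full-featured
    interface.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    M, guard = _rk4_at_times(params._dyn_array(), times, dt)
    if not np.all(np.isfinite(M)):
        raise FloatingPointError("non-finite state in RK4 integration")
    return M, guard


def simulate_trajectory(
    params: ModelParameters,
    t_end: float,
    dt_store: float = 1.0 / 12.0,
    method: str = "adaptive",
    rtol: float = 1e-8,
    atol: float = 1e-4,
) -> Trajectory:
    """Simulate the stock-and-flow model and return state plus auxiliaries.

    Parameters
    ----------
    params : ModelParameters
    t_end : float
        Simulation horizon in years since 2008.0.
    dt_store : float
        Spacing of the stored output grid (the grid always contains t_end).
    method : {"adaptive", "rk4"}
        "adaptive": explicit adaptive Runge-Kutta (RK45) at rtol/atol
        (atol in persons). "rk4": fixed-step classical RK4 at dt = 1/365 yr.

    Notes
    -----
    The derivative recomputes the background mortality rate k(t) from the
    instantaneous state, so the mortality identity holds exactly. If the
    treatment-recovery outflow would drive M below zero, M is capped at the
    remaining stock and ``negative_stock_guard`` is set; parameter regimes
    fitted to realistic data never trigger this guard.
    """
    params.validate()
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if not 0 < dt_store <= t_end:
        raise ValueError("require 0 < dt_store <= t_end")

    n = int(round(t_end / dt_store))
    times = np.linspace(0.0, n * dt_store, n + 1)
    if times[-1] < t_end - 1e-12:
        times = np.append(times, t_end)
    times[-1] = min(times[-1], t_end)

    dyn = params._dyn_array()
    if method == "rk4":
        M, guard = _rk4_at_times(dyn, times, 1.0 / 365.0)
    elif method == "adaptive":
        guard_box = [False]

        def rhs(t, y):
            M = y[0]
            if M < 0.0:
                guard_box[0] = True
            return [_deriv(M, t, *dyn[1:])]

        sol = solve_ivp(
            rhs, (0.0, float(times[-1])), [params.M0],
            method="RK45", t_eval=times, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        M = sol.y[0]
        guard = guard_box[0] or bool(np.any(M < 0))
        M = np.maximum(M, 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    if not np.all(np.isfinite(M)):
        raise FloatingPointError("non-finite state in trajectory")

    P, D, C, i, r_raw = (params.P0 + params.g * times,
                         params.D0 + params.h * times,
                         params.C0 + params.u * times,
                         params.i0 * np.exp(params.delta_i * times),
                         params.r0 * np.exp(params.delta_r * times))
    r_clipped = bool(np.any(r_raw > 1.0))
    if r_clipped:
        warnings.warn(
            "treatment effectiveness r(t) exceeded 1 and was clipped", UserWarning
        )
    r = np.minimum(r_raw, 1.0)
    if np.any(P <= 0) or np.any(D <= 0) or np.any(C < 0):
        raise ValueError("exogenous driver left its physical range on the grid")

    tol = 1e-6 * np.maximum(P, 1.0)
    if np.any(M > P + tol):
        raise FloatingPointError("stock M exceeded population P beyond tolerance")
    M = np.minimum(M, P)
    k = D / (P - M + params.gamma * M)
    return Trajectory(
        times=times, M=M, P=P, D=D, C=C, i=i, r=r, k=k,
        prevalence=M / P,
        negative_stock_guard=bool(guard),
        r_clipped=r_clipped,
    )
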