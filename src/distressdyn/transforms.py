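"""Unconstrained reparameterisation for posterior sampling.

Each parameter is mapped to the real line according to the support of its
prior: identity for unbounded parameters (the linear-trend slopes and the
fractional rates), ``log(x - low)`` for one-sided supports (positive rates
and levels; ``log(gamma - 1)`` for the hazard ratio), and a scaled logit
for doubly bounded supports (the two proportions). The sampler works in z;
densities pick up the usual log-Jacobian terms ``log |d theta / d z|``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["ParameterTransform"]


class ParameterTransform:
    """Bijection between a constrained parameter block and R^n.

    Built from per-parameter support bounds (typically the prior supports).
    """

    def __init__(self, lows, highs):
        self.lows = np.asarray(lows, float)
        self.highs = np.asarray(highs, float)
        self._lower_only = np.isfinite(self.lows) & ~np.isfinite(self.highs)
        self._both = np.isfinite(self.lows) & np.isfinite(self.highs)
        self._ident = ~np.isfinite(self.lows) & ~np.isfinite(self.highs)
        if not np.all(self._lower_only | self._both | self._ident):
            raise ValueError("upper-bounded-only supports are not used here")
        self._width = np.where(self._both, self.highs - self.lows, 1.0)

    @property
    def ndim(self) -> int:
        return self.lows.size

    def to_unconstrained(self, theta) -> np.ndarray:
        theta = np.asarray(theta, float)
        z = np.empty_like(theta)
        z[self._ident] = theta[self._ident]
        lo = self._lower_only
        z[lo] = np.log(theta[lo] - self.lows[lo])
        b = self._both
        p = (theta[b] - self.lows[b]) / self._width[b]
        z[b] = np.log(p) - np.log1p(-p)
        return z

    def to_constrained(self, z) -> np.ndarray:
        from scipy.special import expit

        z = np.asarray(z, float)
        theta = np.empty_like(z)
        theta[self._ident] = z[self._ident]
        lo = self._lower_only
        with np.errstate(over="ignore"):
            theta[lo] = self.lows[lo] + np.exp(z[lo])
        b = self._both
        theta[b] = self.lows[b] + self._width[b] * expit(z[b])
        return theta

    def log_jacobian(self, z) -> float:
        """log |d theta / d z| summed over components."""
        z = np.asarray(z, float)
        total = float(np.sum(z[self._lower_only]))
        zb = z[self._both]
        if zb.size:
            # log(width) + log sigmoid(z) + log sigmoid(-z), stable form
            total += float(
                np.sum(np.log(self._width[self._both]))
                - np.sum(np.logaddexp(0.0, -zb) + np.logaddexp(0.0, zb))
            )
        return total
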