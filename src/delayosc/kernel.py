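"""Gamma-distributed transcriptional delay kernel.

The delayed feedback in the oscillator model acts through a probability
distribution over lag times.  A gamma density ``g_{p,a}`` with shape ``p``
and rate ``a`` (per hour) is truncated at ``tau_max`` hours for computational
tractability and renormalized so the delayed integral of a constant history
returns that constant.  For dynamics (simulation, filtering) the kernel is
discretized to probability masses on a uniform lag grid; information-theoretic
and transform quantities (entropy, Laplace transform) are computed from the
continuous truncated density by adaptive quadrature so they do not depend on
the grid resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.stats import gamma as gamma_dist

__all__ = ["DelayKernel"]


def _validate_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class DelayKernel:
    """Truncated, discretized gamma delay density.

    Parameters
    ----------
    shape : float
        Gamma shape parameter ``p`` (> 0).
    rate : float
        Gamma rate parameter ``a`` in 1/hours (> 0).
    tau_max : float
        Truncation bound in hours; lags beyond ``tau_max`` carry no mass.
    grid_step : float
        Uniform lag-grid spacing in hours; must divide ``tau_max``.

    Attributes
    ----------
    lags : ndarray
        Grid of lag values ``0, h, 2h, ..., tau_max``.
    weights : ndarray
        Probability masses on ``lags``; non-negative, summing to 1.
        Cell ``j`` is centred on lag ``j*h`` and its mass is the truncated
        CDF increment over ``[(j-1/2)h, (j+1/2)h]``, renormalized.
    """

    shape: float
    rate: float
    tau_max: float = 24.0
    grid_step: float = 0.5
    lags: np.ndarray = field(init=False, repr=False, compare=False)
    weights: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        _validate_positive(shape=self.shape, rate=self.rate,
                           tau_max=self.tau_max, grid_step=self.grid_step)
        n_cells = self.tau_max / self.grid_step
        if abs(n_cells - round(n_cells)) > 1e-9:
            raise ValueError(
                f"grid_step={self.grid_step} does not divide tau_max={self.tau_max}")
        m = int(round(n_cells))
        lags = np.arange(m + 1) * self.grid_step
        edges = np.clip(np.concatenate([[0.0], lags + self.grid_step / 2.0]),
                        0.0, self.tau_max)
        cdf = gamma_dist.cdf(edges, a=self.shape, scale=1.0 / self.rate)
        w = np.diff(cdf)
        total = w.sum()
        if total <= 0:  # pathological: all mass beyond tau_max
            raise ValueError("delay density carries no mass on [0, tau_max]")
        w = w / total
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "weights", w)

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_mean_sd(cls, mean: float, sd: float, tau_max: float = 24.0,
                     grid_step: float = 0.5) -> "DelayKernel":
        """Build a kernel from the untruncated mean and SD (hours).

        Moment inversion: ``shape = mean^2/sd^2``, ``rate = mean/sd^2``.
        """
        _validate_positive(mean=mean, sd=sd, tau_max=tau_max, grid_step=grid_step)
        if tau_max < mean:
            raise ValueError(f"tau_max={tau_max} must be >= mean={mean}")
        return cls(shape=mean ** 2 / sd ** 2, rate=mean / sd ** 2,
                   tau_max=tau_max, grid_step=grid_step)

    # ------------------------------------------------------------------
    # moments of the untruncated density
    # ------------------------------------------------------------------
    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def sd(self) -> float:
        return np.sqrt(self.shape) / self.rate

    # ------------------------------------------------------------------
    # continuous truncated density
    # ------------------------------------------------------------------
    @property
    def _renorm(self) -> float:
        """Mass of the untruncated gamma on [0, tau_max]."""
        return float(gamma_dist.cdf(self.tau_max, a=self.shape, scale=1.0 / self.rate))

    def density(self, s: np.ndarray | float) -> np.ndarray | float:
        """Truncated renormalized density at lag ``s`` (0 outside [0, tau_max])."""
        s = np.asarray(s, dtype=float)
        out = gamma_dist.pdf(s, a=self.shape, scale=1.0 / self.rate) / self._renorm
        return np.where((s >= 0) & (s <= self.tau_max), out, 0.0)

    def entropy(self) -> float:
        """Differential entropy (nats) of the truncated renormalized density.

        Computed as ``-int_0^tau_max g log g ds`` by adaptive quadrature;
        density values (not grid masses) enter the logarithm.
        """
        z = self._renorm
        a, scale = self.shape, 1.0 / self.rate

        def integrand(s: float) -> float:
            g = gamma_dist.pdf(s, a=a, scale=scale) / z
            return -g * np.log(g) if g > 0 else 0.0

        pts = [p for p in (self.mean, self.mean + self.sd, max(self.mean - self.sd, 0.0))
               if 0 < p < self.tau_max]
        val, _ = integrate.quad(integrand, 0.0, self.tau_max,
                                points=pts or None, limit=200)
        return float(val)

    def laplace_transform(self, lam: complex) -> complex:
        """``int_0^tau_max exp(-lam*s) g(s) ds`` on the truncated density.

        Adaptive quadrature on real and imaginary parts; exact normalization
        gives 1 at ``lam = 0``.
        """
        z = self._renorm
        a, scale = self.shape, 1.0 / self.rate
        lam = complex(lam)
        pts = [p for p in (self.mean - self.sd, self.mean, self.mean + self.sd)
               if 0 < p < self.tau_max]

        def make(part):
            def f(s: float) -> float:
                return part(np.exp(-lam * s)) * gamma_dist.pdf(s, a=a, scale=scale) / z
            return f

        re, _ = integrate.quad(make(np.real), 0.0, self.tau_max,
                               points=pts or None, limit=200)
        im, _ = integrate.quad(make(np.imag), 0.0, self.tau_max,
                               points=pts or None, limit=200)
        return complex(re, im)

    def laplace_transform_grid(self, lam: np.ndarray | complex) -> np.ndarray | complex:
        """Discrete-weight transform ``sum_j w_j exp(-lam * j h)``.

        Vectorized over ``lam``; this is the transform of the kernel as the
        simulator and filter actually see it, used by the stability classifier
        so that the characteristic analysis matches the discretized dynamics.
        """
        lam = np.asarray(lam, dtype=complex)
        return np.exp(-np.multiply.outer(lam, self.lags)) @ self.weights

    def with_grid_step(self, grid_step: float) -> "DelayKernel":
        """Same continuous kernel on a different lag grid."""
        return DelayKernel(self.shape, self.rate, self.tau_max, grid_step)
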