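"""Single-cell transcription-degradation model with distributed delay.

mRNA abundance X(t) evolves by a birth-death process: transcription follows a
repressive Hill function of the delayed mRNA level (a proxy for the unobserved
protein transcription factor), degradation is linear with rate ``mu``.  The
chemical Langevin approximation has drift equal to the net propensity and
noise variance equal to the summed propensities.  The macroscopic rate
equation is the deterministic mean (Wiener term dropped); its unique positive
equilibrium ``x*`` anchors both the stability classification and the
inhibition profile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .kernel import DelayKernel

__all__ = [
    "OscillatorParams",
    "hill_rate",
    "hill_derivative",
    "equilibrium",
    "cle_drift_diffusion",
    "macroscopic_rhs",
    "TYPE_I",
    "TYPE_II",
]


@dataclass(frozen=True)
class OscillatorParams:
    """Parameters of one location's delayed-feedback oscillator.

    Units: ``R`` molecules/hour; ``K`` molecules; ``n`` dimensionless;
    ``mu`` 1/hour; ``kappa`` light units per molecule-hour; ``sigma_eta``
    light units (measurement noise SD).
    """

    R: float
    K: float
    n: float
    mu: float
    kernel: DelayKernel
    kappa: float = 2.5e-3
    sigma_eta: float = 0.07

    def __post_init__(self) -> None:
        for name in ("R", "K", "mu", "kappa", "sigma_eta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if not np.isfinite(self.n) or self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n!r}")

    def replace(self, **kwargs) -> "OscillatorParams":
        return replace(self, **kwargs)


def hill_rate(z: float | np.ndarray, params: OscillatorParams) -> float | np.ndarray:
    """Repressive Hill transcription rate ``R / (1 + (z/K)^n)`` (molecules/h)."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("delayed mRNA level must be non-negative")
    out = params.R / (1.0 + (z / params.K) ** params.n)
    return float(out) if out.ndim == 0 else out


def hill_derivative(z: float, params: OscillatorParams) -> float:
    """d/dz of the Hill rate; <= 0 for n > 0 (repression)."""
    if z < 0:
        raise ValueError("delayed mRNA level must be non-negative")
    if params.n == 0:
        return 0.0
    if z == 0:
        # (z/K)^(n-1) -> 0 for n > 1, -> 1 for n = 1, diverges for n < 1
        if params.n > 1:
            return 0.0
        if params.n == 1:
            return -params.R / params.K
        return -np.inf
    u = (z / params.K) ** params.n
    return -params.R * params.n * u / (z * (1.0 + u) ** 2)


def equilibrium(params: OscillatorParams, rtol: float = 1e-10) -> float:
    """Unique positive root of ``R/(1 + (x/K)^n) = mu x``.

    The left side is non-increasing in x and the right side strictly
    increasing, so a single bracketing/Brent solve suffices.  Under the
    renormalized delay kernel the delayed integral of a constant history is
    that constant, so x* is also the equilibrium of the delayed system.
    """
    hi = params.R / params.mu  # transcription <= R ⇒ x* <= R/mu

    def f(x: float) -> float:
        return params.R / (1.0 + (x / params.K) ** params.n) - params.mu * x

    if f(hi) == 0.0:
        return hi
    return float(brentq(f, 0.0, hi, rtol=rtol, xtol=1e-14))


def cle_drift_diffusion(x_now: float, z_delayed: float,
                        params: OscillatorParams) -> tuple[float, float]:
    """CLE drift and diffusion-variance rate at the current state.

    drift = hill(z) - mu*x (molecules/h); variance rate = hill(z) + mu*x
    (molecules^2/h), the sum of birth and death propensities.
    """
    if x_now < 0 or z_delayed < 0:
        raise ValueError("molecule counts must be non-negative")
    birth = hill_rate(z_delayed, params)
    death = params.mu * x_now
    return birth - death, birth + death


def macroscopic_rhs(history: Callable[[float], float], t: float,
                    params: OscillatorParams) -> float:
    """Right-hand side of the deterministic mean (macroscopic rate) equation.

    ``history`` must be defined on [t - tau_max, t]; the delayed integral is
    evaluated with the kernel's discrete lag weights.
    """
    k = params.kernel
    try:
        past = np.array([history(t - u) for u in k.lags])
    except Exception as exc:
        raise ValueError(
            f"history must cover [t - tau_max, t] = [{t - k.tau_max}, {t}]"
        ) from exc
    if np.any(~np.isfinite(past)):
        raise ValueError("history returned non-finite values over the delay window")
    z = float(past @ k.weights)
    return hill_rate(z, params) - params.mu * history(t)


def _fig_params(n: float, mean: float, sd: float) -> OscillatorParams:
    return OscillatorParams(R=50.0, K=100.0, n=n, mu=0.25,
                            kernel=DelayKernel.from_mean_sd(mean, sd),
                            kappa=2.5e-3, sigma_eta=0.07)


#: Prototypical dorsal-like oscillator: low Hill coefficient, narrow delay.
TYPE_I = _fig_params(n=3.82, mean=9.1, sd=2.2)

#: Prototypical central-like oscillator: high Hill coefficient, wide delay.
TYPE_II = _fig_params(n=5.57, mean=9.4, sd=4.2)
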