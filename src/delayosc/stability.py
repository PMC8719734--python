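"""Limit-cycle vs damped classification and posterior robustness.

Linearizing the macroscopic rate equation about its equilibrium x* gives the
characteristic function

    F(lambda) = lambda + mu - H'(x*) * ghat(lambda),

where H' is the Hill-rate derivative (<= 0) and ghat the Laplace transform of
the delay kernel.  The equilibrium is unstable — the deterministic mean shows
limit-cycle oscillations — exactly when F has a root with positive real part.
Because F(0) = mu - H'(x*) > 0, instability can only arise through complex
conjugate pairs (a Hopf-type mechanism), so roots are counted inside a
rectangle in the right half-plane by the argument principle.  The transform
is evaluated with the kernel's discrete lag weights so the criterion refers
to the same dynamics the simulator integrates.

The binary indicator D(theta) averaged over posterior draws is the
robustness estimate V-hat: the posterior probability that a location's
parameters imply self-sustained oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ttfl import OscillatorParams, equilibrium, hill_derivative
from .simulate import simulate_paths

__all__ = [
    "StabilityResult",
    "classify_stability",
    "classify_by_simulation",
    "stability_boundary",
    "robustness_estimate",
]


@dataclass(frozen=True)
class StabilityResult:
    is_limit_cycle: bool
    rightmost_root_real_part: Optional[float]
    method: str  # "characteristic_root" | "simulation_oracle"

    @property
    def D(self) -> int:
        return int(self.is_limit_cycle)


def _char_fn(lam: np.ndarray, mu: float, hprime: float,
             lags: np.ndarray, weights: np.ndarray) -> np.ndarray:
    ghat = np.exp(-np.multiply.outer(lam, lags)) @ weights
    return lam + mu - hprime * ghat


def _winding(mu: float, hprime: float, lags: np.ndarray, weights: np.ndarray,
             re_lo: float, re_hi: float, om_max: float,
             n0: int = 48, max_iter: int = 16) -> float:
    corners = [complex(re_lo, -om_max), complex(re_hi, -om_max),
               complex(re_hi, om_max), complex(re_lo, om_max),
               complex(re_lo, -om_max)]
    segs = []
    for a, b in zip(corners[:-1], corners[1:]):
        t = np.linspace(0.0, 1.0, n0, endpoint=False)
        segs.append(a + t * (b - a))
    lam = np.concatenate(segs + [np.array([corners[-1]])])

    for _ in range(max_iter):
        f = _char_fn(lam, mu, hprime, lags, weights)
        if np.any(f == 0):
            # a sample landed exactly on a root: nudge the whole contour
            lam = lam + 1e-9 * (1 + 1j)
            continue
        dphi = np.angle(f[1:] / f[:-1])
        bad = np.abs(dphi) > np.pi / 3
        if not bad.any():
            return float(dphi.sum() / (2.0 * np.pi))
        new = np.empty(len(lam) + bad.sum(), dtype=complex)
        k = 0
        for i in range(len(lam) - 1):
            new[k] = lam[i]
            k += 1
            if bad[i]:
                new[k] = 0.5 * (lam[i] + lam[i + 1])
                k += 1
        new[k] = lam[-1]
        lam = new
    raise RuntimeError("contour refinement did not converge")


def classify_stability(params: OscillatorParams,
                       boundary_tol: float = 1e-6,
                       compute_root: bool = False) -> StabilityResult:
    """Classify the deterministic mean dynamics: limit cycle (D=1) or damped.

    Counts right-half-plane roots of the characteristic function by the
    argument principle on the rectangle with Re in (boundary_tol, lam_max]
    and |Im| <= om_max, where lam_max = mu + |H'(x*)| bounds the modulus of
    any unstable root and om_max = max(4*pi/delay mean, 1.1*lam_max).  If the
    contour count fails numerically, or the contour passes within
    ``boundary_tol`` of a root (a neutral/boundary case), the deterministic
    simulation oracle decides.
    """
    xstar = equilibrium(params)
    hp = hill_derivative(xstar, params)
    if params.n == 0 or hp == 0.0:
        return StabilityResult(False, -params.mu, "characteristic_root")
    kern = params.kernel
    lam_max = params.mu + abs(hp) + 0.1
    om_max = max(4.0 * np.pi / kern.mean, 1.1 * lam_max)
    try:
        w = _winding(params.mu, hp, kern.lags, kern.weights,
                     boundary_tol, lam_max, om_max)
    except RuntimeError:
        return classify_by_simulation(params)
    if abs(w - round(w)) > 1e-6 or round(w) < 0:
        return classify_by_simulation(params)
    count = int(round(w))

    # guard the boundary: if F is tiny anywhere on the left contour edge the
    # rightmost root sits within tolerance of the imaginary axis
    om = np.linspace(0.0, om_max, 400)
    f_edge = _char_fn(boundary_tol + 1j * om, params.mu, hp,
                      kern.lags, kern.weights)
    if np.abs(f_edge).min() < 10 * boundary_tol:
        return classify_by_simulation(params)

    root = None
    if compute_root and count > 0:
        root = _refine_rightmost_root(params.mu, hp, kern.lags, kern.weights,
                                      lam_max, om_max)
    return StabilityResult(count > 0, root, "characteristic_root")


def _refine_rightmost_root(mu, hprime, lags, weights, lam_max, om_max):
    from scipy.optimize import root as _root

    re0 = np.linspace(1e-4, lam_max, 30)
    im0 = np.linspace(0.0, om_max, 60)
    grid = re0[:, None] + 1j * im0[None, :]
    f = _char_fn(grid.ravel(), mu, hprime, lags, weights).reshape(grid.shape)
    i, j = np.unravel_index(np.argmin(np.abs(f)), f.shape)
    lam0 = grid[i, j]

    def fun(x):
        val = _char_fn(np.array([complex(x[0], x[1])]), mu, hprime,
                       lags, weights)[0]
        return [val.real, val.imag]

    sol = _root(fun, [lam0.real, lam0.imag], tol=1e-12)
    return float(sol.x[0]) if sol.success else None


def classify_by_simulation(params: OscillatorParams, n_periods: int = 20,
                           period_guess: float = 24.0, dt: float = 0.1,
                           rel_perturb: float = 0.01) -> StabilityResult:
    """Brute-force oracle: integrate the deterministic mean equation.

    Starts from a constant history perturbed 1% off the equilibrium and
    integrates ``n_periods`` nominal periods.  Decision: if the late-window
    excursion from x* exceeds twice the initial perturbation, the deviation
    has grown into a macroscopic oscillation (limit cycle) — this also covers
    strongly unstable systems that saturate onto the cycle early, where a
    growth comparison between windows would be a coin flip; otherwise growth
    versus decay of the small-amplitude windows decides.
    """
    p = params if abs(params.kernel.grid_step - dt) < 1e-12 else \
        params.replace(kernel=params.kernel.with_grid_step(dt))
    xstar = equilibrium(p)
    horizon = n_periods * period_guess
    ens = simulate_paths(p, horizon=horizon, dt=dt, n_paths=1,
                         init=xstar * (1.0 + rel_perturb), noise=False)
    x = ens.forward_paths[0]
    nt = len(x)
    a_early = np.abs(x[nt // 4: nt // 2] - xstar).max()
    a_late = np.abs(x[3 * nt // 4:] - xstar).max()
    if a_late > 2.0 * rel_perturb * xstar:
        return StabilityResult(True, None, "simulation_oracle")
    if a_early == 0.0:
        return StabilityResult(False, None, "simulation_oracle")
    return StabilityResult(bool(a_late > a_early), None, "simulation_oracle")


def stability_boundary(params_base: OscillatorParams, n_range: np.ndarray,
                       sd_range: np.ndarray, **kwargs) -> np.ndarray:
    """D on an (n, delay SD) grid with the other parameters fixed.

    Returns a boolean matrix of shape (len(n_range), len(sd_range)); used to
    map the compensation ridge between cooperativity and delay dispersion.
    """
    kern = params_base.kernel
    out = np.zeros((len(n_range), len(sd_range)), dtype=bool)
    for i, n in enumerate(n_range):
        for j, sd in enumerate(sd_range):
            k = type(kern).from_mean_sd(kern.mean, float(sd), kern.tau_max,
                                        kern.grid_step)
            p = params_base.replace(n=float(n), kernel=k)
            out[i, j] = classify_stability(p, **kwargs).is_limit_cycle
    return out


def robustness_estimate(d_draws: np.ndarray,
                        ess: Optional[float] = None) -> tuple[float, float]:
    """Posterior-mean robustness V-hat and its Monte-Carlo standard error.

    ``d_draws`` are the binary stability indicators evaluated at post-burn-in
    posterior draws; the SE uses sqrt(V(1-V)/ESS) with ESS defaulting to the
    number of draws.
    """
    d = np.asarray(d_draws, dtype=float)
    if d.size == 0:
        raise ValueError("no post-burn-in draws")
    v = float(d.mean())
    n_eff = float(ess) if ess is not None else float(d.size)
    se = float(np.sqrt(max(v * (1.0 - v), 0.0) / max(n_eff, 1.0)))
    return v, se
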