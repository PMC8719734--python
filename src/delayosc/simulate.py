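"""Euler-Maruyama simulation of the delayed CLE and the measurement process.

Paths carry an explicit initial history segment on [-tau_max, 0] because the
feedback acts through lagged states.  The camera model integrates the path
over each exposure window, scales by ``kappa`` and adds Gaussian read noise.
The synthetic-dataset generator stacks the single-cell model under the
spatial multiplicative random-effects prior and returns ground truth for
recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .kernel import DelayKernel
from .ttfl import OscillatorParams, equilibrium, hill_rate

__all__ = [
    "Perturbation",
    "TrajectoryEnsemble",
    "LuminescenceRecord",
    "simulate_paths",
    "simulate_observation",
    "generate_synthetic_dataset",
    "history_from_series",
]


@dataclass(frozen=True)
class Perturbation:
    """Rectangular additive shock to the mRNA drift.

    ``mode='scaled'`` (default) injects ``amplitude`` molecules per hour over
    the window, so the total added mass is ``amplitude * duration`` and a
    longer shock is a bigger shock.  ``mode='total'`` injects
    ``amplitude / duration`` per hour, fixing the total at ``amplitude``.
    """

    onset: float
    duration: float
    amplitude: float
    shape: str = "rectangular"
    mode: str = "scaled"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("perturbation duration must be positive")
        if self.shape != "rectangular":
            raise ValueError("only rectangular perturbations are supported")
        if self.mode not in ("scaled", "total"):
            raise ValueError("mode must be 'scaled' or 'total'")

    @property
    def rate(self) -> float:
        """Added molecules per hour during the window."""
        if self.mode == "scaled":
            return self.amplitude
        return self.amplitude / self.duration


@dataclass
class TrajectoryEnsemble:
    """Simulated molecular paths on a uniform time grid.

    ``times`` spans ``[-tau_max, horizon]``; the first ``n_history`` columns
    of ``paths`` are the initial history segment, index ``n_history - 1``
    corresponds to t = 0.
    """

    times: np.ndarray
    paths: np.ndarray  # (n_paths, n_times)
    n_history: int
    dt: float
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.paths)):
            raise ValueError("paths contain non-finite values")

    @property
    def forward_times(self) -> np.ndarray:
        return self.times[self.n_history - 1:]

    @property
    def forward_paths(self) -> np.ndarray:
        return self.paths[:, self.n_history - 1:]


@dataclass
class LuminescenceRecord:
    """Observed light intensities, one row per location, one column per frame."""

    values: np.ndarray  # (n_locations, n_frames)
    exposure: float
    layout: tuple[int, int]  # lattice rows x cols

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValueError("record needs at least 2 frames")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")

    @property
    def n_locations(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return self.exposure * np.arange(1, self.n_frames + 1)


def history_from_series(y: np.ndarray, params: OscillatorParams, dt: float,
                        exposure: float) -> np.ndarray:
    """Initial history on the dt grid from an observed frame series.

    Frames are inverted through the noise-free measurement map,
    ``x ~ y / (kappa * exposure)``, and linearly interpolated onto the lag
    grid covering [-tau_max, 0] using the first ``tau_max`` hours of frames.
    """
    y = np.asarray(y, dtype=float)
    tau_max = params.kernel.tau_max
    n_hist = int(round(tau_max / dt)) + 1
    x_frames = np.maximum(y / (params.kappa * exposure), 0.0)
    frame_t = exposure * np.arange(1, len(y) + 1)
    grid_t = np.linspace(0.0, tau_max, n_hist)
    return np.interp(grid_t, frame_t, x_frames)


def _resolve_init(init: Union[str, float, np.ndarray, None],
                  params: OscillatorParams, n_paths: int,
                  n_hist: int) -> np.ndarray:
    if init is None or (isinstance(init, str) and init == "equilibrium"):
        return np.full((n_paths, n_hist), equilibrium(params))
    if np.isscalar(init):
        return np.full((n_paths, n_hist), float(init))
    init = np.asarray(init, dtype=float)
    if init.ndim == 1:
        if len(init) != n_hist:
            raise ValueError(f"history must have {n_hist} points, got {len(init)}")
        return np.tile(init, (n_paths, 1))
    if init.shape != (n_paths, n_hist):
        raise ValueError(f"history must have shape ({n_paths}, {n_hist})")
    return init.copy()


def simulate_paths(params: OscillatorParams, horizon: float, dt: float,
                   n_paths: int = 1,
                   init: Union[str, float, np.ndarray, None] = "equilibrium",
                   perturbation: Optional[Perturbation] = None,
                   seed: Optional[int] = None,
                   noise: bool = True) -> TrajectoryEnsemble:
    """Euler-Maruyama integration of the delayed CLE.

    ``dt`` must equal the kernel grid step so lagged states align with the
    stored path.  With ``noise=False`` the deterministic mean equation is
    integrated instead.  Negative excursions of the stochastic path are
    clamped to zero (molecule counts are non-negative).
    """
    kern = params.kernel
    if abs(dt - kern.grid_step) > 1e-12:
        raise ValueError(
            f"dt={dt} must equal the kernel grid_step={kern.grid_step}")
    if noise and seed is None:
        raise ValueError("stochastic simulation requires an explicit seed")

    m = len(kern.lags) - 1  # lags 0..m, history needs m+1 points
    n_hist = m + 1
    n_fwd = int(round(horizon / dt))
    if n_fwd < 1:
        raise ValueError("horizon too short")
    w_rev = kern.weights[::-1].copy()  # so z_t = P[:, t-m:t+1] @ w_rev

    paths = np.empty((n_paths, n_hist + n_fwd))
    paths[:, :n_hist] = _resolve_init(init, params, n_paths, n_hist)
    times = dt * np.arange(-m, n_fwd + 1)

    rng = np.random.default_rng(seed) if noise else None
    sqrt_dt = np.sqrt(dt)
    pert_rate = np.zeros(n_fwd)
    if perturbation is not None:
        t_mid = dt * np.arange(n_fwd) + dt / 2.0  # midpoint of each step
        window = ((t_mid >= perturbation.onset)
                  & (t_mid < perturbation.onset + perturbation.duration))
        pert_rate[window] = perturbation.rate

    for t in range(n_fwd):
        idx = n_hist - 1 + t
        x = paths[:, idx]
        z = paths[:, idx - m:idx + 1] @ w_rev
        birth = params.R / (1.0 + (z / params.K) ** params.n)
        drift = birth - params.mu * x + pert_rate[t]
        x_new = x + drift * dt
        if noise:
            x_new = x_new + np.sqrt((birth + params.mu * x) * dt) * \
                rng.standard_normal(n_paths)
        np.maximum(x_new, 0.0, out=x_new)
        paths[:, idx + 1] = x_new

    return TrajectoryEnsemble(times=times, paths=paths, n_history=n_hist,
                              dt=dt, rng_seed=seed)


def simulate_observation(ensemble: TrajectoryEnsemble, params: OscillatorParams,
                         exposure: float,
                         seed: Optional[int] = None) -> LuminescenceRecord:
    """Camera model: integrate each path over exposure windows, scale, add noise.

    ``Y_{t'} = kappa * int_{(t'-1)dt}^{t' dt} X(s) ds + eta`` with the
    integral evaluated by the trapezoid rule on the simulation grid and
    ``eta ~ N(0, sigma_eta^2)`` i.i.d. across frames and paths.
    """
    n_sub = exposure / ensemble.dt
    if abs(n_sub - round(n_sub)) > 1e-9:
        raise ValueError("exposure must be an integer multiple of dt")
    n_sub = int(round(n_sub))
    fwd = ensemble.forward_paths  # column 0 is t = 0
    n_frames = (fwd.shape[1] - 1) // n_sub
    if n_frames < 2:
        raise ValueError("horizon too short for 2 frames")

    # trapezoid weights within one window: dt * [1/2, 1, ..., 1, 1/2]
    w = np.full(n_sub + 1, ensemble.dt)
    w[0] = w[-1] = ensemble.dt / 2.0
    vals = np.empty((fwd.shape[0], n_frames))
    for f in range(n_frames):
        seg = fwd[:, f * n_sub:(f + 1) * n_sub + 1]
        vals[:, f] = params.kappa * (seg @ w)
    if params.sigma_eta > 0:
        rng = np.random.default_rng(seed)
        vals = vals + params.sigma_eta * rng.standard_normal(vals.shape)

    rows = fwd.shape[0]
    return LuminescenceRecord(values=vals, exposure=exposure, layout=(rows, 1))


def generate_synthetic_dataset(lattice: tuple[int, int],
                               global_params: OscillatorParams,
                               hyper_variances: dict[str, float],
                               horizon: float = 125.0,
                               exposure: float = 0.5,
                               dt: Optional[float] = None,
                               seed: int = 0,
                               burn_in: float = 24.0,
                               init: str = "limit_cycle"):
    """Sample a spatio-temporal dataset from the full hierarchical model.

    Random effects for R, K, n, delay mean and delay SD are drawn from the
    sum-to-zero-constrained intrinsic CAR prior on the lattice; per-location
    parameters are ``theta_i = theta * exp(eps_i)``.  One stochastic path is
    simulated per location and passed through the camera model.  With
    ``init='limit_cycle'`` (default) each path starts from its location's
    developed deterministic cycle — tissue that has been oscillating long
    before the recording starts, which matters for weakly unstable
    parameter sets whose amplitude grows slowly from equilibrium;
    ``init='equilibrium'`` starts at the fixed point.  A ``burn_in``-hour
    stochastic transient is discarded either way.  Returns
    ``(record, field, ensembles)`` with ground truth.
    """
    from .spatial import SpatialField, sample_car_field

    rows, cols = lattice
    if rows < 2 or cols < 2:
        raise ValueError("lattice must be at least 2x2")
    for k, v in hyper_variances.items():
        if v < 0:
            raise ValueError(f"hyper-variance {k} must be >= 0")
    if dt is None:
        dt = global_params.kernel.grid_step

    rng = np.random.default_rng(seed)
    field = SpatialField.create(rows, cols,
                                global_means={
                                    "R": global_params.R,
                                    "K": global_params.K,
                                    "n": global_params.n,
                                    "delay_mean": global_params.kernel.mean,
                                    "delay_sd": global_params.kernel.sd,
                                },
                                hyper_variances=hyper_variances)
    for name in field.param_names:
        tau = field.hyper_variances[name]
        if tau > 0:
            field.random_effects[name] = sample_car_field(field, tau, rng)

    loc_params = field.location_params(
        tau_max=global_params.kernel.tau_max, grid_step=dt,
        mu=global_params.mu, kappa=global_params.kappa,
        sigma_eta=global_params.sigma_eta)

    ensembles = []
    records = []
    for i, p in enumerate(loc_params):
        if init == "limit_cycle":
            from .phase import limit_cycle_history

            init_i = limit_cycle_history(p, dt)
        else:
            init_i = init
        ens = simulate_paths(p, horizon=horizon + burn_in, dt=dt, n_paths=1,
                             init=init_i,
                             seed=int(rng.integers(2 ** 31)))
        # drop the transient, keep [burn_in, burn_in + horizon]
        n_skip = int(round(burn_in / dt))
        paths = ens.paths[:, n_skip:]
        ens = TrajectoryEnsemble(times=ens.times[n_skip:] - burn_in,
                                 n_history=ens.n_history, dt=dt,
                                 paths=paths, rng_seed=ens.rng_seed)
        rec = simulate_observation(ens, p, exposure,
                                   seed=int(rng.integers(2 ** 31)))
        ensembles.append(ens)
        records.append(rec.values[0])

    record = LuminescenceRecord(values=np.array(records), exposure=exposure,
                                layout=(rows, cols))
    return record, field, ensembles
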