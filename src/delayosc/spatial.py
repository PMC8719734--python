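"""Multiplicative random effects on a lattice with an intrinsic CAR prior.

Each TTFL parameter theta (R, K, n, delay mean, delay SD) varies over the
lattice as ``theta_i = theta * exp(eps_i)`` where the random-effect field
``eps`` carries a first-order Gaussian Markov random field prior: the
conditional distribution of ``eps_i`` given the rest is Normal with mean the
average of its 8 lattice neighbours and variance ``tau / w_{i,+}`` (``w_{i,+}``
the neighbour count).  The implied joint prior is improper (the constant field
is in its null space); a sum-to-zero constraint restores identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import sparse

from .kernel import DelayKernel
from .ttfl import OscillatorParams

__all__ = [
    "PARAM_NAMES",
    "SpatialField",
    "build_adjacency",
    "car_conditional",
    "car_logprior",
    "apply_random_effects",
    "sample_car_field",
]

#: Parameters that carry spatial random effects, in canonical order.
PARAM_NAMES = ("R", "K", "n", "delay_mean", "delay_sd")


def build_adjacency(rows: int, cols: int) -> sparse.csr_matrix:
    """8-neighbourhood (queen) adjacency on a rows x cols lattice, no wraparound.

    Locations are indexed row-major.  Interior cells have 8 neighbours,
    edges 5, corners 3.
    """
    if rows < 2 or cols < 2:
        raise ValueError("lattice must be at least 2x2")
    idx = np.arange(rows * cols).reshape(rows, cols)
    src, dst = [], []
    for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, -1)):
        r0, r1 = max(0, -dr), rows - max(0, dr)
        c0, c1 = max(0, -dc), cols - max(0, dc)
        a = idx[r0:r1, c0:c1].ravel()
        b = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        src.extend(a)
        dst.extend(b)
    data = np.ones(2 * len(src))
    w = sparse.coo_matrix((data, (src + dst, dst + src)),
                          shape=(rows * cols, rows * cols))
    return w.tocsr()


@dataclass
class SpatialField:
    """Lattice of locations with global means, random effects, hyper-variances."""

    rows: int
    cols: int
    adjacency: sparse.csr_matrix
    neighbor_counts: np.ndarray
    global_means: dict[str, float]
    random_effects: dict[str, np.ndarray]
    hyper_variances: dict[str, float]
    param_names: tuple[str, ...] = PARAM_NAMES

    @classmethod
    def create(cls, rows: int, cols: int, global_means: dict[str, float],
               hyper_variances: dict[str, float] | None = None) -> "SpatialField":
        adj = build_adjacency(rows, cols)
        counts = np.asarray(adj.sum(axis=1)).ravel()
        L = rows * cols
        eff = {name: np.zeros(L) for name in PARAM_NAMES}
        hv = {name: 0.0 for name in PARAM_NAMES}
        if hyper_variances:
            hv.update(hyper_variances)
        missing = set(PARAM_NAMES) - set(global_means)
        if missing:
            raise ValueError(f"global_means missing {sorted(missing)}")
        return cls(rows=rows, cols=cols, adjacency=adj, neighbor_counts=counts,
                   global_means=dict(global_means), random_effects=eff,
                   hyper_variances=hv)

    @property
    def n_locations(self) -> int:
        return self.rows * self.cols

    def location_params(self, tau_max: float, grid_step: float, mu: float,
                        kappa: float, sigma_eta: float) -> list[OscillatorParams]:
        """Per-location OscillatorParams from theta * exp(eps)."""
        theta = apply_random_effects(self.global_means, self.random_effects)
        out = []
        for i in range(self.n_locations):
            mean_i = theta["delay_mean"][i]
            if mean_i > tau_max:
                raise ValueError(
                    f"location {i}: delay mean {mean_i:.3f} exceeds tau_max")
            kern = DelayKernel.from_mean_sd(mean_i, theta["delay_sd"][i],
                                            tau_max=tau_max, grid_step=grid_step)
            out.append(OscillatorParams(R=theta["R"][i], K=theta["K"][i],
                                        n=theta["n"][i], mu=mu, kernel=kern,
                                        kappa=kappa, sigma_eta=sigma_eta))
        return out


def car_conditional(i: int, eps: np.ndarray, tau: float,
                    field: SpatialField) -> tuple[float, float]:
    """Conditional prior mean and variance of eps_i given all other effects.

    mean = neighbour average; variance = tau / (neighbour count).
    """
    w_plus = field.neighbor_counts[i]
    if w_plus == 0:
        raise ValueError(f"location {i} is isolated")
    row = field.adjacency.getrow(i)
    mean = float((row @ eps).item()) / w_plus
    return mean, tau / w_plus


def car_logprior(eps: np.ndarray, tau: float, field: SpatialField,
                 check_centered: bool = True) -> float:
    """Log of the intrinsic CAR prior, up to an additive constant.

    ``-(1/(2 tau)) sum_{i~j} (eps_i - eps_j)^2 - ((L-1)/2) log tau``; the
    pairwise sum runs over unordered neighbour pairs.  The precision matrix
    D - W has rank L-1 (the constant field is free), hence the L-1 in the
    normalizer.  Requires the sum-to-zero constraint.
    """
    eps = np.asarray(eps, dtype=float)
    if check_centered and abs(eps.sum()) > 1e-8 * max(1.0, np.abs(eps).max()):
        raise ValueError("random effects must satisfy the sum-to-zero constraint")
    if tau <= 0:
        raise ValueError("tau must be positive")
    L = len(eps)
    quad = float(eps @ (field.neighbor_counts * eps) - eps @ (field.adjacency @ eps))
    return -0.5 * quad / tau - 0.5 * (L - 1) * np.log(tau)


def apply_random_effects(theta: dict[str, float],
                         eps: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-location parameters ``theta_i = theta * exp(eps_i)`` per parameter."""
    return {name: theta[name] * np.exp(np.asarray(eps[name]))
            for name in theta}


def sample_car_field(field: SpatialField, tau: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw a random-effect field from the sum-to-zero constrained CAR prior.

    The improper joint is Gaussian with precision (D - W)/tau; restricted to
    the zero-sum subspace it is proper.  Sampled by eigendecomposition of
    D - W, skipping the null eigenvector (the constant field).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    Q = (sparse.diags(field.neighbor_counts) - field.adjacency).toarray()
    evals, evecs = np.linalg.eigh(Q)
    # first eigenvalue is 0 (connected lattice); remaining are positive
    pos = evals > 1e-10 * evals.max()
    z = rng.standard_normal(pos.sum())
    eps = evecs[:, pos] @ (z * np.sqrt(tau / evals[pos]))
    return eps - eps.mean()
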