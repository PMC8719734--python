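"""Shared oracle helpers for the test suite."""

import numpy as np

from delayosc.kernel import DelayKernel


def make_linear_params(sigma_eta=0.07):
    """n = 0: constant transcription R/2, a linear-Gaussian state space."""
    from delayosc.ttfl import OscillatorParams

    kern = DelayKernel.from_mean_sd(9.4, 4.2)
    return OscillatorParams(R=50.0, K=100.0, n=0.0, mu=0.25, kernel=kern,
                            kappa=2.5e-3, sigma_eta=sigma_eta)


def exact_linear_kalman(y, params, h=0.5, diffuse_factor=10.0):
    """Dense-matrix Kalman filter for the n=0 linear-Gaussian model.

    Independent oracle: builds the full transition/observation matrices and
    runs the textbook recursion, sharing only the model definition with the
    production filter (constant-history initialization, one substep per
    frame).
    """
    from delayosc.ttfl import equilibrium

    kern = params.kernel
    M1 = len(kern.lags)
    xs = equilibrium(params)
    A = np.zeros((M1, M1))
    A[1:, :-1] = np.eye(M1 - 1)
    A[0, 0] = 1.0 - params.mu * h
    b = np.zeros(M1)
    b[0] = (params.R / 2.0) * h
    C = np.zeros(M1)
    C[0] = C[1] = params.kappa * h * 0.5
    m = np.full(M1, y[0] / (params.kappa * h) if y[0] > 0 else xs)
    P = np.eye(M1) * xs * diffuse_factor
    ll = 0.0
    for t in range(len(y)):
        q = (params.R / 2.0 + params.mu * m[0]) * h
        m = A @ m + b
        P = A @ P @ A.T
        P[0, 0] += q
        S = C @ P @ C + params.sigma_eta ** 2
        innov = y[t] - C @ m
        ll += -0.5 * (np.log(2 * np.pi * S) + innov ** 2 / S)
        K = P @ C / S
        m = m + K * innov
        P = P - np.outer(K, C @ P)
        P = (P + P.T) / 2
    return ll
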