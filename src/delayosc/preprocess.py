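"""Imaging preprocessing, noise estimation, residual diagnostics and I/O.

The raw bioluminescence recording is a stack of grayscale frames.  Pixels
are aggregated into blocks matching roughly half a cell body ("locations"),
optionally thinned to alternate rows/columns to cut compute, and each
location's series is linearly detrended to remove substrate-consumption
decay.  Measurement noise can be estimated from two channels carrying the
same signal with independent read noise; the log-variance estimates across
locations yield a lognormal prior for the noise variance.  After a model
fit, one-step-ahead filter residuals are screened for Gaussianity
(Kolmogorov-Smirnov with Bonferroni correction) and for leftover
periodicity (periodogram peaks against a bootstrap envelope).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import LuminescenceRecord

__all__ = [
    "ImageStack",
    "ResidualReport",
    "read_tiff_stack",
    "aggregate_blocks",
    "subsample_alternate",
    "detrend_linear",
    "estimate_noise_variance",
    "fit_noise_prior",
    "residual_diagnostics",
    "write_record_csv",
    "read_record_csv",
]


@dataclass
class ImageStack:
    """Multi-frame grayscale recording: (n_frames, height, width) >= 0."""

    frames: np.ndarray
    frame_interval: float  # hours

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need a (n_frames, height, width) stack, >= 2 frames")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")


def read_tiff_stack(path: str | Path, frame_interval: float) -> ImageStack:
    import tifffile

    return ImageStack(frames=tifffile.imread(str(path)).astype(float),
                      frame_interval=frame_interval)


def aggregate_blocks(stack: ImageStack, block: int = 4) -> LuminescenceRecord:
    """Sum pixel intensities over block x block tiles per frame.

    Trailing rows/columns that do not fill a block are dropped with a
    warning.  The resulting lattice of locations is row-major.
    """
    if block <= 0:
        raise ValueError("block size must be positive")
    nf, h, w = stack.frames.shape
    rows, cols = h // block, w // block
    if rows == 0 or cols == 0:
        raise ValueError("frame smaller than one block")
    if h % block or w % block:
        warnings.warn(f"dropping {h % block} trailing rows and "
                      f"{w % block} trailing columns")
    trimmed = stack.frames[:, :rows * block, :cols * block]
    tiles = trimmed.reshape(nf, rows, block, cols, block).sum(axis=(2, 4))
    values = tiles.reshape(nf, rows * cols).T
    return LuminescenceRecord(values=values, exposure=stack.frame_interval,
                              layout=(rows, cols))


def subsample_alternate(record: LuminescenceRecord) -> LuminescenceRecord:
    """Keep alternate rows and columns of locations (even indices)."""
    rows, cols = record.layout
    if rows < 2 or cols < 2:
        raise ValueError("lattice must be at least 2x2")
    grid = record.values.reshape(rows, cols, -1)
    sub = grid[::2, ::2]
    new_rows, new_cols = sub.shape[:2]
    return LuminescenceRecord(values=sub.reshape(new_rows * new_cols, -1),
                              exposure=record.exposure,
                              layout=(new_rows, new_cols))


def detrend_linear(record: LuminescenceRecord
                   ) -> tuple[LuminescenceRecord, pd.DataFrame]:
    """Subtract a per-location least-squares line, preserving the mean level.

    Substrate consumption superimposes a slow (decreasing) linear trend on
    the oscillation; removing it while adding the mean back keeps the signal
    positive and the light-scaling interpretation of the level intact.
    Returns the detrended record and a table of slopes/intercepts.
    """
    y = record.values
    if y.shape[1] < 3:
        raise ValueError("need at least 3 frames to detrend")
    t = np.arange(y.shape[1], dtype=float)
    slope, intercept = np.polyfit(t, y.T, 1)
    fitted = slope[:, None] * t[None, :] + intercept[:, None]
    detrended = y - fitted + y.mean(axis=1, keepdims=True)
    table = pd.DataFrame({"location": np.arange(y.shape[0]),
                          "slope": slope, "intercept": intercept})
    out = LuminescenceRecord(values=detrended, exposure=record.exposure,
                             layout=record.layout)
    return out, table


def estimate_noise_variance(channel_a: np.ndarray,
                            channel_b: np.ndarray) -> float:
    """ML estimate of the read-noise variance from two same-signal channels.

    If both channels carry the same underlying signal corrupted by
    independent stationary Gaussian noise of variance sigma^2, the
    channel difference d_t has variance 2 sigma^2, giving the ML estimator
    sigma_hat^2 = (1/2T) * sum (d_t - d_bar)^2.
    """
    a = np.asarray(channel_a, dtype=float)
    b = np.asarray(channel_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("channels must be 1-D series of equal length")
    d = a - b
    return float(((d - d.mean()) ** 2).sum() / (2.0 * len(d)))


def fit_noise_prior(estimates: np.ndarray) -> tuple[float, float]:
    """Gaussian moment fit to log variance estimates across locations.

    Returns (mean, sd) of log sigma_eta^2 — a lognormal prior on the noise
    variance ready to plug into :class:`delayosc.mcmc.PriorSpec`.
    Non-positive estimates are dropped with a warning.
    """
    est = np.asarray(estimates, dtype=float)
    pos = est[est > 0]
    if len(pos) < len(est):
        warnings.warn(f"dropped {len(est) - len(pos)} non-positive estimates")
    if len(pos) < 10:
        raise ValueError("need at least 10 positive estimates")
    logs = np.log(pos)
    return float(logs.mean()), float(logs.std(ddof=0))


@dataclass
class ResidualReport:
    """Per-location residual diagnostics after a model fit."""

    ks_statistic: np.ndarray
    ks_pvalue: np.ndarray
    reject: np.ndarray           # Bonferroni-adjusted decisions
    alpha: float
    residual_periods: list[np.ndarray]  # detected periods (hours) per location

    @property
    def n_reject(self) -> int:
        return int(self.reject.sum())


def _bootstrap_periodogram_peaks(resid: np.ndarray, exposure: float,
                                 n_boot: int, rng: np.random.Generator,
                                 period_band: tuple[float, float],
                                 q: float) -> np.ndarray:
    """Periods whose periodogram peak exceeds the bootstrap envelope.

    Resampling the residuals i.i.d. destroys any serial structure; the
    pointwise ``q`` quantile of the resampled periodograms is the
    no-periodicity reference envelope.
    """
    n = len(resid)
    freqs = np.fft.rfftfreq(n, d=exposure)[1:]
    periods = 1.0 / freqs
    band = (periods >= period_band[0]) & (periods <= period_band[1])
    pgram = np.abs(np.fft.rfft(resid - resid.mean()))[1:] ** 2 / n
    boot = np.empty((n_boot, band.sum()))
    for b in range(n_boot):
        rs = rng.choice(resid, size=n, replace=True)
        boot[b] = (np.abs(np.fft.rfft(rs - rs.mean()))[1:] ** 2 / n)[band]
    envelope = np.quantile(boot, q, axis=0)
    hits = band.copy()
    hits[band] = pgram[band] > envelope
    return periods[hits]


def residual_diagnostics(record: LuminescenceRecord, pred_mean: np.ndarray,
                         pred_sd: np.ndarray, alpha: float = 0.05,
                         n_boot: int = 500, seed: int = 0,
                         period_band: tuple[float, float] = (1.0, 30.0),
                         envelope_q: float = 0.99) -> ResidualReport:
    """Standardized one-step-ahead residual screening.

    ``pred_mean``/``pred_sd`` are per-location predictive moments from the
    filter (shape matching ``record.values``).  Each location's standardized
    residuals are tested against N(0,1) by a KS test with Bonferroni
    correction at family level ``alpha``, and scanned for periodicity in
    ``period_band`` hours against a periodogram bootstrap envelope.
    """
    y = record.values
    if pred_mean.shape != y.shape or pred_sd.shape != y.shape:
        raise ValueError("predictive moments must match the record shape")
    L = y.shape[0]
    resid = (y - pred_mean) / pred_sd
    ks_stat = np.empty(L)
    ks_p = np.empty(L)
    rng = np.random.default_rng(seed)
    periods: list[np.ndarray] = []
    for i in range(L):
        res = stats.kstest(resid[i], "norm")
        ks_stat[i] = res.statistic
        ks_p[i] = res.pvalue
        periods.append(_bootstrap_periodogram_peaks(
            resid[i], record.exposure, n_boot, rng, period_band, envelope_q))
    reject = ks_p < alpha / L
    return ResidualReport(ks_statistic=ks_stat, ks_pvalue=ks_p, reject=reject,
                          alpha=alpha, residual_periods=periods)


# ---------------------------------------------------------------------------
# record I/O: CSV matrix + JSON sidecar with exposure/layout metadata
# ---------------------------------------------------------------------------
def write_record_csv(record: LuminescenceRecord, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(record.values)
    df.index.name = "location"
    df.to_csv(path)
    meta = {"exposure": record.exposure, "rows": record.layout[0],
            "cols": record.layout[1]}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_record_csv(path: str | Path) -> LuminescenceRecord:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return LuminescenceRecord(values=df.to_numpy(dtype=float),
                              exposure=float(meta["exposure"]),
                              layout=(int(meta["rows"]), int(meta["cols"])))
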