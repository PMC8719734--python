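"""Model/Results interface for fitting the spatial oscillator model.

`SpatialClockModel` wraps an observed luminescence record (locations x
frames on a lattice) together with priors and filter settings;
``fit()`` runs the blocked adaptive Metropolis sampler and returns a
`SpatialClockResults` carrying the posterior chain with summaries,
credible intervals, effective sample sizes, the robustness map V-hat, the
inhibition-profile entropy map and residual diagnostics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stability as _stab
from .filtering import filter_loglik
from .inhibition import compute_ip, ip_entropy
from .mcmc import (PosteriorChain, PriorSpec, default_priors,
                   effective_sample_size, initial_values, run_mcmc)
from .preprocess import ResidualReport, residual_diagnostics
from .simulate import LuminescenceRecord
from .spatial import PARAM_NAMES, SpatialField

__all__ = ["SpatialClockModel", "SpatialClockResults"]

_GLOBALS = ("mu", "kappa", "sigma_eta")


class SpatialClockModel:
    """Hierarchical distributed-delay oscillator model for a lattice of cells.

    Parameters
    ----------
    record : LuminescenceRecord
        Observed frame series per location, with exposure metadata and the
        lattice layout.
    priors : PriorSpec, optional
        Prior hyperparameters; defaults to :func:`delayosc.mcmc.default_priors`.
    tau_max : float
        Delay truncation bound in hours.
    h : float, optional
        Filter grid step; defaults to the exposure.
    hyper_variances_init : dict, optional
        Starting values for the CAR hyper-variances (default 0.01 each).
    """

    def __init__(self, record: LuminescenceRecord,
                 priors: PriorSpec | None = None, tau_max: float = 24.0,
                 h: float | None = None,
                 hyper_variances_init: dict[str, float] | None = None):
        self.record = record
        self.priors = priors or default_priors()
        self.tau_max = tau_max
        self.h = h if h is not None else record.exposure
        rows, cols = record.layout
        if rows * cols != record.n_locations:
            raise ValueError("layout does not match the number of locations")
        self._hv_init = {p: 0.01 for p in PARAM_NAMES}
        if hyper_variances_init:
            self._hv_init.update(hyper_variances_init)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, exposure: float,
                       layout: tuple[int, int], **kwargs) -> "SpatialClockModel":
        """Build from a locations x frames DataFrame."""
        rec = LuminescenceRecord(values=df.to_numpy(dtype=float),
                                 exposure=exposure, layout=layout)
        return cls(rec, **kwargs)

    def _field_init(self, init: dict) -> SpatialField:
        rows, cols = self.record.layout
        if rows >= 2 and cols >= 2:
            gm = {"R": init["R"], "K": init["K"], "n": init["n"],
                  "delay_mean": init["delay_mean"], "delay_sd": init["delay_sd"]}
            return SpatialField.create(rows, cols, global_means=gm,
                                       hyper_variances=self._hv_init)

        # degenerate lattice (single location / single row): no CAR structure
        class _Degenerate:
            pass

        f = _Degenerate()
        f.rows, f.cols = rows, cols
        f.random_effects = {p: np.zeros(self.record.n_locations)
                            for p in PARAM_NAMES}
        f.hyper_variances = dict(self._hv_init)
        return f

    def fit(self, n_iter: int = 5000, seed: int = 0,
            init: dict | None = None) -> "SpatialClockResults":
        """Run the sampler and wrap the chain in a results object."""
        if init is None:
            init = initial_values(self.record, self.priors)
        field = self._field_init(init)
        chain = run_mcmc(self.record, field, priors=self.priors,
                         n_iter=n_iter, seed=seed, tau_max=self.tau_max,
                         h=self.h, init=init)
        return SpatialClockResults(self, chain)


class SpatialClockResults:
    """Posterior summaries for a fitted spatial oscillator model."""

    def __init__(self, model: SpatialClockModel, chain: PosteriorChain):
        self.model = model
        self.chain = chain

    # -- draw access --------------------------------------------------------
    def _post(self, x: np.ndarray) -> np.ndarray:
        return self.chain.post_burn(x)

    def global_draws(self) -> pd.DataFrame:
        """Post-burn-in draws of the global parameters, natural scale."""
        th = self._post(self.chain.theta)
        return pd.DataFrame({
            "R": th[:, 0], "K": th[:, 1], "n": th[:, 2],
            "delay_mean": th[:, 3], "delay_sd": th[:, 4],
            "mu": self._post(self.chain.mu),
            "kappa": self._post(self.chain.kappa),
            "sigma_eta": self._post(self.chain.sigma_eta),
        })

    def location_draws(self, location: int) -> pd.DataFrame:
        """Post-burn-in per-location parameter draws theta*exp(eps)."""
        th = self._post(self.chain.theta)
        ep = self._post(self.chain.eps)[:, :, location]
        vals = th * np.exp(ep)
        return pd.DataFrame(vals, columns=list(PARAM_NAMES))

    # -- summaries ----------------------------------------------------------
    def posterior_mean(self) -> pd.Series:
        return self.global_draws().mean()

    def credible_interval(self, level: float = 0.9) -> pd.DataFrame:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        d = self.global_draws()
        return pd.DataFrame({"lower": d.quantile(lo), "upper": d.quantile(hi)})

    def ess(self) -> pd.Series:
        d = self.global_draws()
        return pd.Series({c: effective_sample_size(d[c].to_numpy())
                          for c in d.columns})

    def location_credible_interval(self, location: int,
                                   level: float = 0.9) -> pd.DataFrame:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        d = self.location_draws(location)
        return pd.DataFrame({"lower": d.quantile(lo), "upper": d.quantile(hi)})

    def summary(self, level: float = 0.9) -> str:
        """Text summary table of global parameters."""
        d = self.global_draws()
        ci = self.credible_interval(level)
        ess = self.ess()
        lines = [
            "Spatial distributed-delay oscillator model",
            "=" * 58,
            f"locations: {self.chain.n_locations}   "
            f"frames: {self.model.record.n_frames}   "
            f"iterations: {self.chain.n_iter} "
            f"(burn-in {self.chain.burn})",
            "-" * 58,
            f"{'param':>12} {'mean':>9} {'sd':>8} "
            f"{f'{level:.0%} CI':>19} {'ESS':>6}",
        ]
        for c in d.columns:
            lines.append(
                f"{c:>12} {d[c].mean():>9.4g} {d[c].std():>8.3g} "
                f"[{ci.loc[c, 'lower']:>8.4g},{ci.loc[c, 'upper']:>8.4g}] "
                f"{ess[c]:>6.0f}")
        lines.append("-" * 58)
        acc = {b: self.chain.acceptance_rate(b)
               for b in ("theta",) + _GLOBALS if b in self.chain.accepts}
        lines.append("acceptance (post burn-in): "
                     + "  ".join(f"{b}={r:.3f}" for b, r in acc.items()))
        return "\n".join(lines)

    # -- oscillator phenotypes ---------------------------------------------
    def stability_indicators(self, thin: int = 10) -> np.ndarray:
        """D(theta) per post-burn-in (thinned) draw per location."""
        if (self.chain.stability_D is not None
                and self.chain.stability_thin == thin):
            return self.chain.stability_D
        burn = self.chain.burn
        its = range(burn, self.chain.n_iter, thin)
        L = self.chain.n_locations
        D = np.zeros((len(list(its)), L), dtype=np.int8)
        for r, it in enumerate(range(burn, self.chain.n_iter, thin)):
            for loc in range(L):
                try:
                    p = self.chain.location_params(it, loc)
                    D[r, loc] = _stab.classify_stability(p).D
                except (ValueError, RuntimeError):
                    D[r, loc] = 0
        self.chain.stability_D = D
        self.chain.stability_thin = thin
        return D

    def robustness(self, thin: int = 10) -> pd.DataFrame:
        """Posterior robustness V-hat per location with Monte-Carlo SE."""
        D = self.stability_indicators(thin)
        out = []
        for loc in range(self.chain.n_locations):
            v, se = _stab.robustness_estimate(D[:, loc])
            out.append({"location": loc, "V": v, "se": se})
        return pd.DataFrame(out)

    def robustness_map(self, thin: int = 10) -> np.ndarray:
        v = self.robustness(thin)["V"].to_numpy()
        return v.reshape(self.chain.layout)

    def inhibition_entropy(self, thin: int = 10) -> np.ndarray:
        """Posterior-mean entropy of the standardized IP per location."""
        burn = self.chain.burn
        its = list(range(burn, self.chain.n_iter, thin))
        L = self.chain.n_locations
        ent = np.zeros((len(its), L))
        for r, it in enumerate(its):
            for loc in range(L):
                p = self.chain.location_params(it, loc)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ent[r, loc] = ip_entropy(compute_ip(p))
        return ent.mean(axis=0)

    # -- diagnostics --------------------------------------------------------
    def residual_diagnostics(self, alpha: float = 0.05, n_boot: int = 500,
                             seed: int = 0) -> ResidualReport:
        """KS + periodicity screening of one-step-ahead filter residuals.

        The filter is re-run at the posterior-mean parameters of each
        location to produce predictive moments.
        """
        rec = self.model.record
        pm = np.empty_like(rec.values)
        ps = np.empty_like(rec.values)
        means = self.posterior_mean()
        for loc in range(self.chain.n_locations):
            d = self.location_draws(loc).mean()
            from .kernel import DelayKernel
            from .ttfl import OscillatorParams
            kern = DelayKernel.from_mean_sd(
                min(d["delay_mean"], self.model.tau_max - 1e-6), d["delay_sd"],
                tau_max=self.model.tau_max, grid_step=self.model.h)
            p = OscillatorParams(R=d["R"], K=d["K"], n=d["n"],
                                 mu=means["mu"], kernel=kern,
                                 kappa=means["kappa"],
                                 sigma_eta=means["sigma_eta"])
            _, out = filter_loglik(rec.values[loc], p, rec.exposure,
                                   h=self.model.h)
            pm[loc] = out.pred_mean
            ps[loc] = out.pred_sd
        return residual_diagnostics(rec, pm, ps, alpha=alpha, n_boot=n_boot,
                                    seed=seed)

    # -- export -------------------------------------------------------------
    def to_csv(self, out_dir) -> None:
        """Posterior-mean maps and global summaries as CSV tables."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows, cols = self.chain.layout
        th = self._post(self.chain.theta)
        ep = self._post(self.chain.eps)
        for k, name in enumerate(PARAM_NAMES):
            loc_means = (th[:, k, None] * np.exp(ep[:, k, :])).mean(axis=0)
            pd.DataFrame(loc_means.reshape(rows, cols)).to_csv(
                out / f"map_{name}.csv", index=False)
        self.global_draws().describe().to_csv(out / "global_summary.csv")
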