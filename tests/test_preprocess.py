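import numpy as np
import pytest

from delayosc.preprocess import (ImageStack, aggregate_blocks, detrend_linear,
                                 estimate_noise_variance, fit_noise_prior,
                                 read_record_csv, residual_diagnostics,
                                 subsample_alternate, write_record_csv)
from delayosc.simulate import LuminescenceRecord


def make_stack(frames):
    return ImageStack(frames=frames, frame_interval=0.5)


class TestAggregateBlocks:
    def test_ones_sum_to_block_area(self):
        stack = make_stack(np.ones((3, 8, 8)))
        rec = aggregate_blocks(stack, block=4)
        assert rec.layout == (2, 2)
        assert np.all(rec.values == 16.0)

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(size=(4, 12, 8))
        rec = aggregate_blocks(make_stack(frames), block=4)
        assert rec.values.sum() == pytest.approx(frames.sum())

    def test_block_one_is_identity(self):
        frames = np.arange(2 * 3 * 4, dtype=float).reshape(2, 3, 4)
        rec = aggregate_blocks(make_stack(frames), block=1)
        assert np.allclose(rec.values, frames.reshape(2, 12).T)

    def test_trailing_pixels_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            rec = aggregate_blocks(make_stack(np.ones((2, 9, 10))), block=4)
        assert rec.layout == (2, 2)

    def test_invalid_block(self):
        with pytest.raises(ValueError):
            aggregate_blocks(make_stack(np.ones((2, 8, 8))), block=0)


class TestSubsampleAlternate:
    def test_even_sublattice_kept(self):
        vals = np.arange(16, dtype=float)[:, None] * np.ones((1, 5))
        rec = LuminescenceRecord(values=vals, exposure=0.5, layout=(4, 4))
        sub = subsample_alternate(rec)
        assert sub.layout == (2, 2)
        kept = sub.values[:, 0]
        assert np.allclose(kept, [0, 2, 8, 10])   # even rows, even cols

    def test_degenerate_lattice_rejected(self):
        rec = LuminescenceRecord(values=np.ones((2, 5)), exposure=0.5,
                                 layout=(1, 2))
        with pytest.raises(ValueError):
            subsample_alternate(rec)


class TestDetrendLinear:
    def test_ramp_becomes_flat_at_original_mean(self):
        t = np.arange(100, dtype=float)
        y = (3.0 + 0.25 * t)[None, :]
        rec = LuminescenceRecord(values=y, exposure=0.5, layout=(1, 1))
        out, table = detrend_linear(rec)
        assert np.allclose(out.values, y.mean(), atol=1e-10)
        assert table["slope"][0] == pytest.approx(0.25, abs=1e-12)
        assert out.values.mean() == pytest.approx(y.mean())

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(1, 2, size=(3, 80))
        rec = LuminescenceRecord(values=y, exposure=0.5, layout=(3, 1))
        once, _ = detrend_linear(rec)
        twice, _ = detrend_linear(once)
        assert np.allclose(once.values, twice.values, atol=1e-10)


class TestNoiseVarianceEstimator:
    def test_identical_channels_give_zero(self):
        y = np.random.default_rng(2).uniform(size=500)
        assert estimate_noise_variance(y, y) == 0.0

    def test_monte_carlo_consistency(self):
        rng = np.random.default_rng(3)
        signal = np.sin(np.linspace(0, 40, 100_000))
        a = signal + rng.normal(0, 2.0, 100_000)
        b = signal + rng.normal(0, 2.0, 100_000)
        assert estimate_noise_variance(a, b) == pytest.approx(4.0, abs=0.1)

    def test_shared_signal_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1.0, 5000)
        b = rng.normal(0, 1.0, 5000)
        shared = 50.0 * np.sin(np.arange(5000) / 100.0)
        assert estimate_noise_variance(a + shared, b + shared) == \
            pytest.approx(estimate_noise_variance(a, b), abs=1e-10)

    def test_finite_sample_bias_factor(self):
        # E[sigma_hat^2] = sigma^2 (T-1)/T because the channel-difference
        # mean is estimated
        rng = np.random.default_rng(5)
        T, reps, sig2 = 8, 40_000, 4.0
        ests = np.empty(reps)
        for r in range(reps):
            a = rng.normal(0, np.sqrt(sig2), T)
            b = rng.normal(0, np.sqrt(sig2), T)
            ests[r] = estimate_noise_variance(a, b)
        assert ests.mean() == pytest.approx(sig2 * (T - 1) / T, rel=0.02)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            estimate_noise_variance(np.ones(5), np.ones(6))


class TestFitNoisePrior:
    def test_equal_estimates(self):
        mean, sd = fit_noise_prior(np.full(20, 0.3))
        assert mean == pytest.approx(np.log(0.3))
        assert sd == 0.0

    def test_lognormal_recovery(self):
        rng = np.random.default_rng(6)
        est = np.exp(rng.normal(-5.3, 0.17, 4000))
        mean, sd = fit_noise_prior(est)
        assert mean == pytest.approx(-5.3, abs=0.02)
        assert sd == pytest.approx(0.17, abs=0.02)

    def test_non_positive_dropped_with_warning(self):
        est = np.concatenate([np.full(15, 0.2), [-1.0, 0.0]])
        with pytest.warns(UserWarning):
            mean, _ = fit_noise_prior(est)
        assert mean == pytest.approx(np.log(0.2))

    def test_too_few_estimates(self):
        with pytest.raises(ValueError):
            fit_noise_prior(np.full(5, 0.1))


class TestResidualDiagnostics:
    def _record(self, resid):
        L, T = resid.shape
        pred_mean = np.zeros((L, T))
        pred_sd = np.ones((L, T))
        rec = LuminescenceRecord(values=resid, exposure=0.5, layout=(L, 1))
        return rec, pred_mean, pred_sd

    def test_null_residuals_rarely_reject(self):
        rng = np.random.default_rng(7)
        rec, pm, ps = self._record(rng.standard_normal((10, 200)))
        rep = residual_diagnostics(rec, pm, ps, alpha=0.05, n_boot=100, seed=1)
        assert rep.n_reject == 0

    def test_constant_residuals_reject(self):
        rec, pm, ps = self._record(np.full((3, 200), 2.0))
        rep = residual_diagnostics(rec, pm, ps, alpha=0.05, n_boot=50, seed=2)
        assert rep.reject.all()

    def test_injected_periodicity_detected(self):
        rng = np.random.default_rng(8)
        t = np.arange(250) * 0.5
        resid = (rng.standard_normal((1, 250))
                 + 1.5 * np.sin(2 * np.pi * t / 12.0))
        rec, pm, ps = self._record(resid)
        rep = residual_diagnostics(rec, pm, ps, n_boot=300, seed=3)
        periods = rep.residual_periods[0]
        assert len(periods) > 0
        assert np.min(np.abs(periods - 12.0)) < 1.0


def test_tiff_stack_round_trip(tmp_path):
    import tifffile

    from delayosc.preprocess import read_tiff_stack

    rng = np.random.default_rng(10)
    frames = rng.integers(0, 4000, size=(5, 16, 12)).astype(np.uint16)
    path = tmp_path / "stack.tif"
    tifffile.imwrite(path, frames)
    stack = read_tiff_stack(path, frame_interval=0.5)
    assert stack.frames.shape == (5, 16, 12)
    rec = aggregate_blocks(stack, block=4)
    assert rec.layout == (4, 3)
    assert rec.values.sum() == pytest.approx(frames.sum())


def test_record_csv_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    rec = LuminescenceRecord(values=rng.uniform(size=(6, 40)), exposure=0.5,
                             layout=(2, 3))
    path = tmp_path / "record.csv"
    write_record_csv(rec, path)
    back = read_record_csv(path)
    assert np.allclose(back.values, rec.values)
    assert back.exposure == rec.exposure
    assert back.layout == rec.layout
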