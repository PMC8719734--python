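import numpy as np
import pytest

from delayosc.kernel import DelayKernel
from delayosc.simulate import (Perturbation, generate_synthetic_dataset,
                               simulate_observation, simulate_paths)
from delayosc.spatial import PARAM_NAMES
from delayosc.ttfl import TYPE_I, TYPE_II, OscillatorParams, equilibrium


class TestSimulatePaths:
    def test_deterministic_fixed_point(self):
        xs = equilibrium(TYPE_II)
        ens = simulate_paths(TYPE_II, horizon=48.0, dt=0.5, noise=False)
        assert np.allclose(ens.paths, xs, rtol=1e-8)

    def test_type_i_sustained_oscillation(self):
        # deterministic Type-I dynamics from a perturbed start reach a limit
        # cycle with stable amplitude over 6 simulated days
        p = TYPE_I.replace(kernel=TYPE_I.kernel.with_grid_step(0.1))
        ens = simulate_paths(p, horizon=288.0, dt=0.1, init=150.0, noise=False)
        x = ens.forward_paths[0]
        n = len(x)
        amp_mid = x[n // 2:3 * n // 4].max() - x[n // 2:3 * n // 4].min()
        amp_late = x[3 * n // 4:].max() - x[3 * n // 4:].min()
        assert amp_late > 50.0          # macroscopic oscillation
        assert amp_late == pytest.approx(amp_mid, rel=0.05)

    def test_seed_reproducibility(self):
        a = simulate_paths(TYPE_II, horizon=24.0, dt=0.5, n_paths=3, seed=9)
        b = simulate_paths(TYPE_II, horizon=24.0, dt=0.5, n_paths=3, seed=9)
        assert np.array_equal(a.paths, b.paths)

    def test_unseeded_stochastic_run_rejected(self):
        with pytest.raises(ValueError):
            simulate_paths(TYPE_II, horizon=24.0, dt=0.5)

    def test_dt_must_match_kernel_grid(self):
        with pytest.raises(ValueError):
            simulate_paths(TYPE_II, horizon=24.0, dt=0.25, seed=1)

    def test_paths_stay_non_negative(self):
        p = TYPE_II.replace(R=5.0, K=10.0)  # low copy numbers, frequent dips
        ens = simulate_paths(p, horizon=100.0, dt=0.5, n_paths=20, seed=4)
        assert ens.paths.min() >= 0.0

    def test_ensemble_mean_tracks_deterministic_at_high_copy_number(self):
        # rescaling R and K by 100 shrinks relative noise; the stochastic
        # ensemble mean must follow the macroscopic solution
        p = TYPE_II.replace(R=TYPE_II.R * 100, K=TYPE_II.K * 100)
        det = simulate_paths(p, horizon=72.0, dt=0.5, init=1.1 * equilibrium(p),
                             noise=False)
        sto = simulate_paths(p, horizon=72.0, dt=0.5, n_paths=400,
                             init=1.1 * equilibrium(p), seed=2)
        mean_path = sto.forward_paths.mean(axis=0)
        rel = np.abs(mean_path - det.forward_paths[0]) / det.forward_paths[0]
        assert rel.max() < 0.01

    def test_halving_dt_preserves_period(self):
        # weak-convergence sanity at the source protocol's step size
        from delayosc.phase import extract_peak_phases

        periods = {}
        for dt in (0.2, 0.1):
            p = TYPE_I.replace(kernel=TYPE_I.kernel.with_grid_step(dt))
            ens = simulate_paths(p, horizon=240.0, dt=dt, init=150.0,
                                 noise=False)
            pk = extract_peak_phases(ens.forward_paths[0], ens.forward_times)
            periods[dt] = np.median(np.diff(pk))
        assert periods[0.1] == pytest.approx(periods[0.2], rel=0.01)


class TestPerturbation:
    def test_total_mass_semantics(self):
        # linear system (n=0), negligible degradation: the path offset after
        # the shock equals the injected mass
        kern = DelayKernel.from_mean_sd(9.4, 4.2)
        p = OscillatorParams(R=50.0, K=100.0, n=0.0, mu=1e-6, kernel=kern)
        base = simulate_paths(p, horizon=24.0, dt=0.5, init=100.0, noise=False)
        for mode, expected in (("scaled", 130.0 * 2.0), ("total", 130.0)):
            pert = Perturbation(onset=4.0, duration=2.0, amplitude=130.0,
                                mode=mode)
            shocked = simulate_paths(p, horizon=24.0, dt=0.5, init=100.0,
                                     noise=False, perturbation=pert)
            added = shocked.forward_paths[0, -1] - base.forward_paths[0, -1]
            assert added == pytest.approx(expected, rel=1e-3)

    def test_identical_before_onset(self):
        pert = Perturbation(onset=24.0, duration=1.0, amplitude=130.0)
        a = simulate_paths(TYPE_II, horizon=48.0, dt=0.5, n_paths=5, seed=7)
        b = simulate_paths(TYPE_II, horizon=48.0, dt=0.5, n_paths=5, seed=7,
                           perturbation=pert)
        i_onset = np.searchsorted(a.forward_times, 24.0)
        fwd_a, fwd_b = a.forward_paths, b.forward_paths
        assert np.array_equal(fwd_a[:, :i_onset], fwd_b[:, :i_onset])
        assert not np.array_equal(fwd_a[:, i_onset + 2:], fwd_b[:, i_onset + 2:])

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            Perturbation(onset=0.0, duration=0.0, amplitude=10.0)


class TestSimulateObservation:
    def test_constant_path_noise_free(self):
        p = TYPE_II.replace(sigma_eta=1e-300)
        ens = simulate_paths(p, horizon=10.0, dt=0.5, noise=False, init=120.0)
        ens.paths[:] = 120.0
        rec = simulate_observation(ens, p, exposure=0.5, seed=0)
        assert np.allclose(rec.values, p.kappa * 120.0 * 0.5, rtol=1e-12)

    def test_exposure_must_be_multiple_of_dt(self):
        ens = simulate_paths(TYPE_II, horizon=10.0, dt=0.5, noise=False)
        with pytest.raises(ValueError):
            simulate_observation(ens, TYPE_II, exposure=0.7, seed=0)

    def test_noise_moments(self):
        ens = simulate_paths(TYPE_II, horizon=5000.0, dt=0.5, noise=False,
                             init=100.0)
        ens.paths[:] = 100.0
        rec = simulate_observation(ens, TYPE_II, exposure=0.5, seed=3)
        level = TYPE_II.kappa * 100.0 * 0.5
        resid = rec.values[0] - level
        assert resid.mean() == pytest.approx(0.0, abs=4 * 0.07 / 100)
        assert resid.std() == pytest.approx(TYPE_II.sigma_eta, rel=0.05)


class TestSyntheticDataset:
    def test_degenerate_hyper_variances_share_theta(self):
        rec, field, ens = generate_synthetic_dataset(
            (2, 2), TYPE_II, {p: 0.0 for p in PARAM_NAMES},
            horizon=30.0, seed=1)
        for p in PARAM_NAMES:
            assert np.allclose(field.random_effects[p], 0.0)

    def test_random_effects_sum_to_zero(self):
        rec, field, _ = generate_synthetic_dataset(
            (3, 3), TYPE_II, {p: 0.02 for p in PARAM_NAMES},
            horizon=30.0, seed=2)
        for p in PARAM_NAMES:
            assert field.random_effects[p].sum() == pytest.approx(0.0, abs=1e-10)

    def test_spatially_correlated_effects(self):
        # neighbouring random effects correlate positively under the CAR draw
        from delayosc.spatial import SpatialField, sample_car_field

        field = SpatialField.create(6, 6, global_means={
            p: 1.0 for p in PARAM_NAMES})
        rng = np.random.default_rng(5)
        corrs = []
        for _ in range(100):
            eps = sample_car_field(field, 0.02, rng).reshape(6, 6)
            a = np.concatenate([eps[:, :-1].ravel(), eps[:-1, :].ravel()])
            b = np.concatenate([eps[:, 1:].ravel(), eps[1:, :].ravel()])
            corrs.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(corrs) > 0.2

    def test_shapes_and_reproducibility(self):
        kwargs = dict(hyper_variances={p: 0.01 for p in PARAM_NAMES},
                      horizon=30.0, exposure=0.5, seed=7)
        rec1, _, _ = generate_synthetic_dataset((2, 3), TYPE_II, **kwargs)
        rec2, _, _ = generate_synthetic_dataset((2, 3), TYPE_II, **kwargs)
        assert rec1.values.shape == (6, 60)
        assert np.array_equal(rec1.values, rec2.values)

    def test_invalid_lattice_and_variances(self):
        with pytest.raises(ValueError):
            generate_synthetic_dataset((1, 5), TYPE_II,
                                       {p: 0.01 for p in PARAM_NAMES})
        with pytest.raises(ValueError):
            generate_synthetic_dataset((2, 2), TYPE_II,
                                       {p: -0.1 for p in PARAM_NAMES})
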