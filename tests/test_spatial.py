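import numpy as np
import pytest

from delayosc.spatial import (PARAM_NAMES, SpatialField, apply_random_effects,
                              build_adjacency, car_conditional, car_logprior,
                              sample_car_field)


@pytest.fixture
def field3():
    return SpatialField.create(3, 3, global_means={p: 1.0 for p in PARAM_NAMES})


class TestAdjacency:
    def test_neighbor_counts_on_3x3(self):
        w = build_adjacency(3, 3)
        counts = np.asarray(w.sum(axis=1)).ravel()
        assert counts[4] == 8            # center
        assert counts[0] == 3            # corner
        assert counts[1] == 5            # edge

    def test_symmetric_zero_diagonal(self):
        w = build_adjacency(4, 5)
        assert (w != w.T).nnz == 0
        assert w.diagonal().sum() == 0

    def test_handshake_identity(self):
        w = build_adjacency(4, 4)
        # 8-neighbour pair count on a 4x4 lattice: 3*4*2 horizontal+vertical
        # pairs each, plus 3*3*2 diagonal pairs
        n_pairs = 2 * (3 * 4) + 2 * (3 * 3)
        assert w.sum() == 2 * n_pairs

    def test_no_wraparound(self):
        w = build_adjacency(3, 3).toarray()
        assert w[0, 2] == 0 and w[0, 6] == 0   # opposite corners of row/col

    def test_degenerate_lattice_rejected(self):
        with pytest.raises(ValueError):
            build_adjacency(1, 5)


class TestCarConditional:
    def test_neighbor_average(self, field3):
        eps = np.full(9, 0.2)
        mean, _ = car_conditional(4, eps, tau=0.1, field=field3)
        assert mean == pytest.approx(0.2)

    def test_interior_variance(self, field3):
        _, var = car_conditional(4, np.zeros(9), tau=0.8, field=field3)
        assert var == pytest.approx(0.8 / 8)

    def test_corner_variance(self, field3):
        _, var = car_conditional(0, np.zeros(9), tau=0.9, field=field3)
        assert var == pytest.approx(0.9 / 3)


class TestCarLogprior:
    def test_flat_field_is_maximal(self, field3):
        rng = np.random.default_rng(0)
        lp0 = car_logprior(np.zeros(9), 0.5, field3)
        for _ in range(10):
            e = rng.standard_normal(9)
            e -= e.mean()
            assert car_logprior(e, 0.5, field3) < lp0

    def test_tau_scales_quadratic_form(self, field3):
        rng = np.random.default_rng(1)
        e = rng.standard_normal(9)
        e -= e.mean()
        lp1 = car_logprior(e, 1.0, field3)
        lp2 = car_logprior(e, 2.0, field3)
        quad1 = lp1 - (-0.5 * 8 * np.log(1.0))
        quad2 = lp2 - (-0.5 * 8 * np.log(2.0))
        assert quad2 == pytest.approx(quad1 / 2.0)

    def test_gradient_matches_finite_differences(self, field3):
        rng = np.random.default_rng(2)
        e = rng.standard_normal(9)
        e -= e.mean()
        tau = 0.4
        # analytic gradient of the quadratic form: -(D - W) e / tau
        D = field3.neighbor_counts
        W = field3.adjacency
        grad = -(D * e - W @ e) / tau
        eps_fd = 1e-6
        for i in range(9):
            ep = e.copy()
            ep[i] += eps_fd
            fd = (car_logprior(ep, tau, field3, check_centered=False)
                  - car_logprior(e, tau, field3, check_centered=False)) / eps_fd
            assert fd == pytest.approx(grad[i], abs=1e-4)

    def test_non_centered_rejected(self, field3):
        with pytest.raises(ValueError):
            car_logprior(np.ones(9), 0.5, field3)

    @pytest.mark.parametrize("shape", [(2, 2), (3, 3)])
    def test_brook_consistency_with_conditionals(self, shape):
        # changing one coordinate: the joint log-density difference must
        # equal the conditional Gaussian log-density difference
        field = SpatialField.create(*shape,
                                    global_means={p: 1.0 for p in PARAM_NAMES})
        L = shape[0] * shape[1]
        rng = np.random.default_rng(3)
        tau = 0.6
        for _ in range(5):
            e = rng.standard_normal(L)
            i = int(rng.integers(L))
            e2 = e.copy()
            e2[i] += rng.standard_normal()
            d_joint = (car_logprior(e2, tau, field, check_centered=False)
                       - car_logprior(e, tau, field, check_centered=False))

            def cond_logpdf(eps):
                m, v = car_conditional(i, eps, tau, field)
                return -0.5 * np.log(2 * np.pi * v) - (eps[i] - m) ** 2 / (2 * v)

            assert d_joint == pytest.approx(cond_logpdf(e2) - cond_logpdf(e),
                                            abs=1e-10)


class TestApplyRandomEffects:
    def test_identity_and_doubling(self):
        theta = {"R": 50.0, "K": 100.0}
        assert apply_random_effects(theta, {"R": 0.0, "K": 0.0})["R"] == 50.0
        out = apply_random_effects(theta, {"R": np.log(2.0), "K": 0.0})
        assert out["R"] == pytest.approx(100.0)

    def test_geometric_mean_preserved(self):
        rng = np.random.default_rng(4)
        e = rng.standard_normal(12)
        e -= e.mean()
        vals = apply_random_effects({"R": 50.0}, {"R": e})["R"]
        assert np.exp(np.log(vals).mean()) == pytest.approx(50.0)


class TestSampleCarField:
    def test_sum_to_zero(self, field3):
        rng = np.random.default_rng(5)
        e = sample_car_field(field3, 0.3, rng)
        assert e.sum() == pytest.approx(0.0, abs=1e-12)

    def test_scale_grows_with_tau(self, field3):
        rng = np.random.default_rng(6)
        sd_small = np.std([sample_car_field(field3, 0.01, rng) for _ in range(100)])
        sd_large = np.std([sample_car_field(field3, 1.0, rng) for _ in range(100)])
        assert sd_large > 5 * sd_small

    def test_invalid_tau(self, field3):
        with pytest.raises(ValueError):
            sample_car_field(field3, 0.0, np.random.default_rng(0))


def test_location_params_validates_delay_bound(field3):
    field3.global_means.update(R=50.0, K=100.0, n=5.57,
                               delay_mean=23.0, delay_sd=4.2)
    field3.random_effects["delay_mean"] = np.full(9, 0.2)  # pushes past 24h
    with pytest.raises(ValueError):
        field3.location_params(tau_max=24.0, grid_step=0.5, mu=0.25,
                               kappa=2.5e-3, sigma_eta=0.07)
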