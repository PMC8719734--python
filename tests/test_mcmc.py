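import numpy as np
import pytest

from delayosc.mcmc import (PriorSpec, adapt_scale, default_priors,
                           effective_sample_size, initial_values, run_mcmc,
                           _equilibrium_fast)
from delayosc.spatial import PARAM_NAMES
from delayosc.ttfl import TYPE_II, equilibrium


class TestAdaptScale:
    def test_directions(self):
        g_up, _ = adapt_scale(1.0, 0.02, observed_rate=0.5, target_rate=0.234)
        g_dn, _ = adapt_scale(1.0, 0.02, observed_rate=0.1, target_rate=0.234)
        assert g_up == pytest.approx(1.02)
        assert g_dn == pytest.approx(0.98)

    def test_coefficient_decay(self):
        _, c2 = adapt_scale(1.0, 0.02, 0.5, 0.234)
        assert c2 == pytest.approx(0.019998)

    def test_geometric_decay_stays_positive(self):
        c = 0.02
        for k in range(10000):
            _, c = adapt_scale(1.0, c, 0.5, 0.234)
        assert c == pytest.approx(0.02 * (1 - 1e-4) ** 10000, rel=1e-9)
        assert c > 0

    def test_invalid_coefficient(self):
        with pytest.raises(ValueError):
            adapt_scale(1.0, 1.5, 0.5, 0.234)


class TestEffectiveSampleSize:
    def test_iid_chain(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        ess = effective_sample_size(x)
        assert 8_000 <= ess <= 12_000

    def test_ar1_chain(self):
        # integrated autocorrelation time of AR(1): (1+rho)/(1-rho)
        rng = np.random.default_rng(1)
        rho, n = 0.9, 200_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.3)

    def test_never_exceeds_n(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.standard_normal(500)
            assert effective_sample_size(x) <= 500

    def test_constant_chain_warns(self):
        with pytest.warns(UserWarning):
            assert effective_sample_size(np.ones(200)) == 0.0

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.arange(50.0))


class TestPriors:
    def test_defaults_match_stated_hyperparameters(self):
        pr = default_priors()
        assert pr.log_mu == (-0.55, 0.25)
        assert pr.log_R == (0.0, 10.0)          # variance 100
        assert pr.log_tau == (0.0, 5.0)         # variance 25
        assert pr.delay_mean_bounds == (0.0, 24.0)
        assert pr.delay_sd_bounds == (0.0, 20.0)

    def test_delay_mean_outside_support_is_rejected(self,
                                                    single_location_record):
        from delayosc.mcmc import _Sampler

        class F:
            rows = cols = 1
            random_effects = {p: np.zeros(1) for p in PARAM_NAMES}
            hyper_variances = {p: 0.01 for p in PARAM_NAMES}

        s = _Sampler(single_location_record.values, 0.5, F(), default_priors(),
                     tau_max=24.0, h=0.5, init=None)
        good = np.array([np.log(50), np.log(100), np.log(5.57), 9.4, 4.2])
        bad = good.copy()
        bad[3] = 25.0
        assert np.isfinite(s._lp_theta(good))
        assert s._lp_theta(bad) == -np.inf


def test_fast_equilibrium_matches_reference():
    rng = np.random.default_rng(3)
    from delayosc.kernel import DelayKernel
    from delayosc.ttfl import OscillatorParams

    kern = DelayKernel.from_mean_sd(9.4, 4.2)
    for _ in range(30):
        R, K = rng.uniform(5, 300), rng.uniform(10, 400)
        n, mu = rng.uniform(0, 8), rng.uniform(0.05, 1.5)
        p = OscillatorParams(R=R, K=K, n=n, mu=mu, kernel=kern)
        assert _equilibrium_fast(R, K, n, mu) == pytest.approx(
            equilibrium(p), rel=1e-8)


def test_initial_values_spectral_heuristics(single_location_record):
    init = initial_values(single_location_record)
    # a circadian series: dominant period near 24h puts the delay-mean start
    # near 0.4 * period
    assert 7.0 <= init["delay_mean"] <= 12.0
    # light scaling from the signal level at the reference molecular scale
    assert init["kappa"] == pytest.approx(2.5e-3, rel=0.8)
    assert init["mu"] == pytest.approx(np.exp(-0.55))


@pytest.fixture(scope="module")
def short_chain(single_location_record):
    return run_mcmc(single_location_record, _single_field(), n_iter=1200,
                    seed=8)


class TestRunMcmc:
    def test_chain_shapes_and_finiteness(self, short_chain,
                                         single_location_record):
        ch = short_chain
        assert ch.theta.shape == (1200, 5)
        assert np.isfinite(ch.theta).all()
        assert np.isfinite(ch.loglik).all()
        assert ch.n_locations == 1

    def test_acceptance_bookkeeping(self, short_chain):
        for b, acc in short_chain.accepts.items():
            assert acc.sum() <= short_chain.n_iter
            assert short_chain.gammas[b] > 0

    def test_noise_sd_recovered_within_factor(self, short_chain):
        # sigma_eta is strongly identified; even a short chain should land
        # near the generating value 0.07
        sig = short_chain.post_burn(short_chain.sigma_eta).mean()
        assert 0.75 * 0.07 <= sig <= 1.3 * 0.07

    def test_reproducible_given_seed(self, single_location_record):
        a = run_mcmc(single_location_record, _single_field(), n_iter=300,
                     seed=4)
        b = run_mcmc(single_location_record, _single_field(), n_iter=300,
                     seed=4)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.mu, b.mu)


def _single_field():
    class F:
        rows = cols = 1
        random_effects = {p: np.zeros(1) for p in PARAM_NAMES}
        hyper_variances = {p: 0.01 for p in PARAM_NAMES}

    return F()
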