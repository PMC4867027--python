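import numpy as np
import pytest

from quantalem import (
    ResponseDataset,
    SpikeTrain,
    SynapticParameters,
    dataset_log_likelihood,
    forward_backward,
    pair_posteriors,
    simulate_trial,
)
from quantalem.emission import emission_density
from quantalem.likelihood import (
    batched_log_likelihood,
    brute_force_log_likelihood,
    brute_force_pair_posteriors,
)
from tests.conftest import random_small_instance


class TestForwardBackward:
    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            params, spikes, resp = random_small_instance(rng)
            fb = forward_backward(resp, spikes, params)
            bf = brute_force_log_likelihood(resp, spikes, params)
            assert fb.log_likelihood == pytest.approx(bf, rel=1e-9)

    def test_initial_state_is_full_recovery(self, tiny_params):
        spikes = SpikeTrain([0, 60, 130])
        rng = np.random.default_rng(0)
        resp, _ = simulate_trial(tiny_params, spikes, rng)
        fb = forward_backward(resp, spikes, tiny_params)
        expected = np.zeros(tiny_params.N + 1)
        expected[tiny_params.N] = 1.0
        assert fb.alpha_minus[0] == pytest.approx(expected)

    def test_terminal_backward_condition(self, tiny_params):
        spikes = SpikeTrain([0, 60, 130])
        rng = np.random.default_rng(1)
        resp, _ = simulate_trial(tiny_params, spikes, rng)
        fb = forward_backward(resp, spikes, tiny_params)
        assert fb.beta_plus[-1] == pytest.approx(np.ones(tiny_params.N + 1))

    def test_forward_backward_identity_at_every_spike(self, tiny_params):
        # in scaled units sum_S alpha^-_k(S) beta^-_k(S) == 1 for all k
        spikes = SpikeTrain([0, 40, 90, 200])
        rng = np.random.default_rng(2)
        resp, _ = simulate_trial(tiny_params, spikes, rng)
        fb = forward_backward(resp, spikes, tiny_params)
        prods = (fb.alpha_minus * fb.beta_minus).sum(axis=1)
        assert prods == pytest.approx(np.ones(spikes.M), rel=1e-9)

    def test_backward_initialization_identity(self, tiny_params):
        # sum_S beta^-_1(S) P(S1=S) recovers the likelihood:
        # beta^-_1 at S=N (scaled) times prod of scalers == likelihood
        spikes = SpikeTrain([0, 40, 90])
        rng = np.random.default_rng(3)
        resp, _ = simulate_trial(tiny_params, spikes, rng)
        fb = forward_backward(resp, spikes, tiny_params)
        ll_from_beta = np.log(fb.beta_minus[0, tiny_params.N]) + fb.log_scalers.sum()
        assert ll_from_beta == pytest.approx(fb.log_likelihood, rel=1e-9)

    def test_two_identical_trials_double_loglik(self, tiny_params):
        spikes = SpikeTrain([0, 70])
        rng = np.random.default_rng(4)
        resp, _ = simulate_trial(tiny_params, spikes, rng)
        single = dataset_log_likelihood(ResponseDataset([(spikes, resp)]), tiny_params)
        double = dataset_log_likelihood(
            ResponseDataset([(spikes, resp), (spikes, resp.copy())]), tiny_params
        )
        assert double == pytest.approx(2 * single, rel=1e-12)


class TestPairPosteriors:
    def test_normalized_and_supported(self, tiny_params):
        spikes = SpikeTrain([0, 50, 140])
        rng = np.random.default_rng(5)
        resp, _ = simulate_trial(tiny_params, spikes, rng)
        post = pair_posteriors(resp, spikes, tiny_params)
        assert post.sum(axis=(1, 2)) == pytest.approx(np.ones(spikes.M), abs=1e-10)
        iu = np.triu_indices(tiny_params.N + 1, k=1)
        for k in range(spikes.M):
            # entries with S+ > S- (upper triangle in (S-, S+) indexing) vanish
            assert np.all(post[k][iu] == 0.0)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            params, spikes, resp = random_small_instance(rng, n_max=2, m_max=3)
            post = pair_posteriors(resp, spikes, params)
            ref = brute_force_pair_posteriors(resp, spikes, params)
            assert post == pytest.approx(ref, abs=1e-9)


class TestDatasetLikelihood:
    def test_trial_order_invariance_and_additivity(self, small_dataset, tiny_params):
        p = small_dataset.metadata["params"]
        params = SynapticParameters.from_dict(p)
        ll = dataset_log_likelihood(small_dataset, params)
        perm = small_dataset.subset(list(reversed(range(small_dataset.n_trials))))
        assert dataset_log_likelihood(perm, params) == pytest.approx(ll, rel=1e-12)
        a = small_dataset.subset(range(6))
        b = small_dataset.subset(range(6, small_dataset.n_trials))
        assert dataset_log_likelihood(a, params) + dataset_log_likelihood(
            b, params
        ) == pytest.approx(ll, rel=1e-12)

    def test_deterministic_release_closed_form(self):
        # N=1, U=1, docking certain: every spike releases exactly one vesicle
        p = SynapticParameters(N=1, q=0.2, sigma_q=0.05, U=1.0, tau_D=1e-9, tau_F=0.0)
        spikes = SpikeTrain([0, 500, 1000])
        resp = np.array([0.18, 0.22, 0.2])
        ll = dataset_log_likelihood(ResponseDataset([(spikes, resp)]), p)
        expected = sum(np.log(emission_density(r, 1, 0, 0.2, 0.05, 0.0)) for r in resp)
        assert ll == pytest.approx(expected, rel=1e-9)

    def test_batched_matches_sequential(self, tiny_params):
        spikes = SpikeTrain([0, 50, 120])
        rng = np.random.default_rng(7)
        resp = np.vstack([simulate_trial(tiny_params, spikes, rng)[0] for _ in range(6)])
        batched = batched_log_likelihood(resp, spikes, tiny_params)
        seq = [
            forward_backward(resp[i], spikes, tiny_params).log_likelihood
            for i in range(6)
        ]
        assert batched == pytest.approx(seq, rel=1e-12)


class TestBruteForce:
    def test_refuses_large_instances(self, tiny_params):
        big = tiny_params.replace(N=5)
        with pytest.raises(ValueError):
            brute_force_log_likelihood([0.1], SpikeTrain([0.0]), big)
        long_spikes = SpikeTrain(np.arange(5) * 50.0)
        with pytest.raises(ValueError):
            brute_force_log_likelihood(np.full(5, 0.1), long_spikes, tiny_params)

    def test_outlier_response_decreases_loglik(self, tiny_params):
        spikes = SpikeTrain([0, 50])
        resp = np.array([0.2, 0.2])
        base = brute_force_log_likelihood(resp, spikes, tiny_params)
        spikes3 = SpikeTrain([0, 50, 100])
        worse = brute_force_log_likelihood(np.append(resp, 50.0), spikes3, tiny_params)
        assert worse < base
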