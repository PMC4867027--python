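import numpy as np
import pytest

from quantalem import (
    SpikeTrain,
    StimulationProtocol,
    SynapticParameters,
    make_protocol,
    mean_response_sequence,
    simulate_dataset,
    simulate_trial,
)
from quantalem.simulate import (
    sample_docking,
    sample_inverse_gaussian,
    sample_release,
    sample_population_parameters,
)
from quantalem.likelihood import docking_matrix, release_matrix
from tests.conftest import DEPRESSING, FACILITATING


class TestElementarySampling:
    def test_release_degenerate(self):
        rng = np.random.default_rng(0)
        assert all(sample_release(3, 0.0, rng) == 3 for _ in range(5))
        assert all(sample_release(3, 1.0, rng) == 0 for _ in range(5))

    def test_release_matches_binomial_pmf(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_release(2, 0.5, rng) for _ in range(4000)])
        # S+ = 2 - Binom(2, 0.5): P(S+=1) = 0.5
        p1 = np.mean(draws == 1)
        assert p1 == pytest.approx(0.5, abs=4 * 0.5 / np.sqrt(4000))

    def test_docking_degenerate(self):
        rng = np.random.default_rng(2)
        assert all(sample_docking(1, 4, 0.0, rng) == 1 for _ in range(5))
        assert all(sample_docking(0, 4, 1.0 - 1e-15, rng) == 4 for _ in range(5))

    def test_docking_matches_binomial_pmf(self):
        rng = np.random.default_rng(3)
        draws = np.array([sample_docking(0, 2, 0.5, rng) for _ in range(4000)])
        assert np.mean(draws == 1) == pytest.approx(0.5, abs=4 * 0.5 / np.sqrt(4000))

    def test_transition_kernels_are_stochastic(self):
        # matrix counterparts of the sampling kernels sum to one on support
        for u in (0.0, 0.3, 1.0):
            assert release_matrix(4, u).sum(axis=1) == pytest.approx(np.ones(5))
        for l in (0.0, 0.6, 0.999):
            assert docking_matrix(4, l).sum(axis=1) == pytest.approx(np.ones(5))

    def test_inverse_gaussian_moments(self):
        rng = np.random.default_rng(4)
        mu, lam = 0.3, 0.3**3 / 0.05**2
        x = sample_inverse_gaussian(np.full(40000, mu), lam, rng)
        assert x.mean() == pytest.approx(mu, rel=0.02)
        assert x.var() == pytest.approx(mu**3 / lam, rel=0.1)
        assert np.all(x > 0)


class TestResponseSampling:
    def test_quantal_moments_with_noise(self):
        from quantalem.simulate import sample_response

        rng = np.random.default_rng(5)
        q, sq, sn = 0.15, 0.03, 0.02
        x1 = np.array([sample_response(1, q, sq, sn, rng) for _ in range(20000)])
        assert x1.mean() == pytest.approx(q, rel=0.02)
        assert x1.var() == pytest.approx(sq**2 + sn**2, rel=0.1)
        x3 = np.array([sample_response(3, q, sq, sn, rng) for _ in range(20000)])
        assert x3.mean() == pytest.approx(3 * q, rel=0.02)
        assert x3.var() == pytest.approx(3 * sq**2 + sn**2, rel=0.1)

    def test_zero_vesicles_zero_noise(self):
        from quantalem.simulate import sample_response

        rng = np.random.default_rng(6)
        assert sample_response(0, 0.15, 0.03, 0.0, rng) == 0.0


class TestSimulateTrial:
    def test_hidden_path_starts_full(self):
        rng = np.random.default_rng(7)
        spikes = SpikeTrain([0, 50, 100])
        for _ in range(10):
            _, path = simulate_trial(FACILITATING, spikes, rng)
            assert path.s_minus[0] == FACILITATING.N
            assert np.all(path.s_plus <= path.s_minus)
            assert np.all(path.s_minus[1:] >= path.s_plus[:-1])

    def test_failure_probability_single_spike(self):
        p = SynapticParameters(N=4, q=0.2, sigma_q=0.04, U=0.3, tau_D=300, tau_F=100)
        rng = np.random.default_rng(8)
        spikes = SpikeTrain([0.0])
        fails = np.array(
            [simulate_trial(p, spikes, rng)[0][0] == 0.0 for _ in range(6000)]
        )
        expected = (1 - p.U) ** p.N
        assert fails.mean() == pytest.approx(
            expected, abs=4 * np.sqrt(expected * (1 - expected) / 6000)
        )

    def test_trial_mean_matches_deterministic_skeleton(self):
        rng = np.random.default_rng(9)
        spikes = SpikeTrain(np.append(np.arange(8) * 50.0, 900.0))
        n = 4000
        acc = np.zeros(spikes.M)
        for _ in range(n):
            r, _ = simulate_trial(DEPRESSING, spikes, rng)
            acc += r
        mean = acc / n
        rbar = mean_response_sequence(DEPRESSING, spikes)
        assert mean == pytest.approx(rbar, abs=5 * 0.12 / np.sqrt(n) + 0.01)


class TestProtocols:
    def test_regular_times_and_recovery(self):
        proto = StimulationProtocol("regular", 50.0, 8, n_trials=3)
        trains = make_protocol(proto, seed=0)
        assert len(trains) == 3
        assert trains[0].times == pytest.approx(np.append(np.arange(8) * 50.0, 900.0))

    def test_default_recovery_interval(self):
        proto = StimulationProtocol("regular", 200.0, 5, n_trials=1)
        assert proto.T_rec == 700.0  # T + 500 ms

    def test_poisson_mean_interval(self):
        proto = StimulationProtocol("poisson", 120.0, 40, n_trials=30)
        trains = make_protocol(proto, seed=11)
        isis = np.concatenate([t.intervals[:-1] for t in trains])  # drop recovery
        assert isis.mean() == pytest.approx(120.0, rel=4 / np.sqrt(isis.size))

    def test_single_sweep_shares_boundary_spike(self):
        proto = StimulationProtocol("single_sweep", 200.0, 8, duration=118000.0)
        (train,) = make_protocol(proto, seed=12)
        # every block contributes exactly n_spikes responses: total = 1 + 8*k
        assert (train.M - 1) % 8 == 0
        assert train.times[-1] <= 118000.0

    def test_duration_too_short(self):
        with pytest.raises(ValueError):
            make_protocol(StimulationProtocol("single_sweep", 200.0, 8, duration=100.0), 0)

    def test_seed_reproducibility(self):
        proto = StimulationProtocol("poisson", 100.0, 5, n_trials=4)
        d1 = simulate_dataset(FACILITATING, proto, seed=99)
        d2 = simulate_dataset(FACILITATING, proto, seed=99)
        for (s1, r1), (s2, r2) in zip(d1.trials, d2.trials):
            assert np.array_equal(s1.times, s2.times)
            assert np.array_equal(r1, r2)


class TestPopulation:
    def test_samples_respect_ranges(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            p = sample_population_parameters(rng)
            assert 2 <= p.N <= 40
            assert 0.06 <= p.q <= 0.32
            assert 0.05 <= p.U <= 0.73
            assert p.tau_D > 0 and p.tau_F > 0
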