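import numpy as np
import pytest

from quantalem import (
    SpikeTrain,
    StimulationProtocol,
    SynapticParameters,
    simulate_dataset,
)

#: the standard experimental probe: 8 spikes at 20 Hz plus a recovery spike
#: 550 ms after the end of the train
REGULAR_20HZ = SpikeTrain(np.append(np.arange(8) * 50.0, 350.0 + 550.0))

#: facilitating example connection
FACILITATING = SynapticParameters(
    N=10, q=0.15, sigma_q=0.03, U=0.3, tau_D=195.0, tau_F=570.0, sigma_n=0.03
)

#: depressing example connection
DEPRESSING = SynapticParameters(
    N=10, q=0.15, sigma_q=0.03, U=0.25, tau_D=670.0, tau_F=15.0, sigma_n=0.03
)

#: worked-example connection used for uncertainty quantification
WORKED_EXAMPLE = SynapticParameters(
    N=17, q=0.18, sigma_q=0.06, U=0.27, tau_D=202.0, tau_F=449.0, sigma_n=0.03
)


@pytest.fixture
def regular_spikes():
    return REGULAR_20HZ


@pytest.fixture
def tiny_params():
    """Small-N parameters for enumeration-oracle comparisons."""
    return SynapticParameters(
        N=2, q=0.2, sigma_q=0.05, U=0.4, tau_D=300.0, tau_F=200.0, sigma_n=0.04
    )


@pytest.fixture
def small_dataset():
    """A quick 12-trial facilitating dataset on the 20 Hz probe."""
    proto = StimulationProtocol("regular", 50.0, 8, n_trials=12)
    return simulate_dataset(FACILITATING, proto, seed=7)


def random_small_instance(rng, n_max=3, m_max=4):
    """A random small (params, spikes, responses) triple for oracle checks."""
    N = int(rng.integers(1, n_max + 1))
    M = int(rng.integers(1, m_max + 1))
    params = SynapticParameters(
        N=N,
        q=float(rng.uniform(0.08, 0.3)),
        sigma_q=float(rng.uniform(0.02, 0.08)),
        U=float(rng.uniform(0.1, 0.9)),
        tau_D=float(rng.uniform(50, 900)),
        tau_F=float(rng.uniform(20, 900)),
        sigma_n=float(rng.uniform(0.01, 0.08)),
    )
    times = np.cumsum(rng.uniform(20, 300, size=M)) if M > 1 else np.array([0.0])
    spikes = SpikeTrain(times - (times[0] if M > 1 else 0.0))
    from quantalem import simulate_trial

    responses, _ = simulate_trial(params, spikes, rng)
    return params, spikes, responses
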