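"""Synthetic experiments under the stochastic TM generative model.

Generates hidden release-site paths and observable response trains for the
three stimulation protocols used throughout the package:

* ``regular`` — trains of ``n`` spikes at a fixed interval ``T`` plus a
  recovery spike ``T_rec`` after the last train spike, repeated over
  independent trials separated by a long inter-trial interval;
* ``poisson`` — the same skeleton with i.i.d. exponential within-train
  intervals of mean ``T`` (a different train on every trial);
* ``single_sweep`` — Poisson blocks concatenated into one uninterrupted
  train, the recovery spike of each block doubling as the first spike of
  the next block.

The simulator doubles as the fixture generator for the whole test suite:
identical seed and protocol yield a bit-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import SpikeTrain, SynapticParameters, release_probability_sequence, docking_probability

__all__ = [
    "HiddenPath",
    "ResponseDataset",
    "StimulationProtocol",
    "sample_release",
    "sample_docking",
    "sample_inverse_gaussian",
    "sample_response",
    "simulate_trial",
    "make_protocol",
    "simulate_dataset",
    "sample_population_parameters",
]


@dataclass(frozen=True)
class HiddenPath:
    """Release-competent site counts immediately before/after each spike."""

    s_minus: np.ndarray
    s_plus: np.ndarray


@dataclass
class ResponseDataset:
    """Per-trial response amplitudes aligned to presynaptic spikes.

    ``trials`` is a list of ``(SpikeTrain, responses)`` with one response
    amplitude (mV) per spike; trials are statistically independent.
    """

    trials: List[Tuple[SpikeTrain, np.ndarray]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, (spikes, resp) in enumerate(self.trials):
            resp = np.asarray(resp, dtype=float)
            if resp.shape != (spikes.M,):
                raise ValueError(
                    f"trial {i}: {resp.size} responses for {spikes.M} spikes"
                )
            self.trials[i] = (spikes, resp)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_responses(self) -> int:
        return sum(r.size for _, r in self.trials)

    def subset(self, indices: Sequence[int]) -> "ResponseDataset":
        return ResponseDataset([self.trials[i] for i in indices], dict(self.metadata))

    def common_spike_train(self) -> Optional[SpikeTrain]:
        """The shared spike train if all trials use the same one, else None."""
        first = self.trials[0][0]
        for spikes, _ in self.trials[1:]:
            if spikes.M != first.M or not np.allclose(spikes.times, first.times):
                return None
        return first


@dataclass(frozen=True)
class StimulationProtocol:
    """Stimulation protocol descriptor.

    Parameters
    ----------
    kind : {"regular", "poisson", "single_sweep"}
    T : float
        (Mean) within-train interspike interval, ms.
    n_spikes_per_train : int
        Spikes per train, excluding the recovery spike.
    T_rec : float or None
        Recovery interval after the last train spike, ms; defaults to
        ``T + 500`` as in the experimental protocol.
    inter_trial_interval : float
        Silent gap between the recovery spike and the next trial's first
        spike, ms (ignored by ``single_sweep``).
    n_trials : int or None
        Number of trials (``regular``/``poisson``).
    duration : float or None
        Total recording duration, ms.  For ``single_sweep`` this bounds the
        concatenated train; for the trial-based protocols it determines
        ``n_trials`` when that is not given.
    """

    kind: str
    T: float
    n_spikes_per_train: int
    T_rec: Optional[float] = None
    inter_trial_interval: float = 4000.0
    n_trials: Optional[int] = None
    duration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("regular", "poisson", "single_sweep"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.T <= 0 or self.n_spikes_per_train < 1:
            raise ValueError("T must be > 0 and n_spikes_per_train >= 1")
        if self.T_rec is None:
            object.__setattr__(self, "T_rec", self.T + 500.0)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "T": self.T,
            "n_spikes_per_train": self.n_spikes_per_train,
            "T_rec": self.T_rec,
            "inter_trial_interval": self.inter_trial_interval,
            "n_trials": self.n_trials,
            "duration": self.duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        return cls(**{k: d[k] for k in (
            "kind", "T", "n_spikes_per_train", "T_rec",
            "inter_trial_interval", "n_trials", "duration") if k in d})


# ---------------------------------------------------------------------------
# elementary sampling operations

def sample_release(s_minus: int, u: float, rng: np.random.Generator) -> int:
    """Number of sites still competent after a spike: S+ = S- - Binom(S-, u)."""
    return int(s_minus - rng.binomial(s_minus, u))


def sample_docking(s_plus: int, N: int, l: float, rng: np.random.Generator) -> int:
    """Competent sites before the next spike: S- = S+ + Binom(N - S+, l)."""
    return int(s_plus + rng.binomial(N - s_plus, l))


def sample_inverse_gaussian(mu, lam, rng: np.random.Generator):
    """Inverse-Gaussian(mean mu, shape lam) samples by the chi-square
    transformation of Michael, Schucany & Haas (no unbounded rejection)."""
    mu = np.asarray(mu, dtype=float)
    lam = np.asarray(lam, dtype=float)
    shape = np.broadcast_shapes(mu.shape, lam.shape)
    nu = rng.standard_normal(shape)
    y = nu * nu
    x1 = mu + mu * mu * y / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * y + mu * mu * y * y
    )
    z = rng.uniform(size=shape)
    accept = z <= mu / (mu + x1)
    return np.where(accept, x1, mu * mu / x1)


def sample_response(
    n_released: int, q: float, sigma_q: float, sigma_n: float, rng: np.random.Generator
) -> float:
    """One response amplitude: m-vesicle inverse-Gaussian sum plus noise.

    ``m`` released vesicles yield an inverse-Gaussian amplitude with mean
    ``m*q`` and variance ``m*sigma_q**2`` (linear quantal summation); zero
    vesicles yield 0.  Gaussian baseline noise of SD ``sigma_n`` is added.
    """
    m = int(n_released)
    amp = 0.0
    if m >= 1:
        if sigma_q > 0:
            mu = m * q
            lam = m * m * q**3 / sigma_q**2  # variance m*sigma_q^2
            amp = float(sample_inverse_gaussian(mu, lam, rng))
        else:
            amp = m * q
    if sigma_n > 0:
        amp += sigma_n * rng.standard_normal()
    return amp


def simulate_trial(
    params: SynapticParameters, spikes: SpikeTrain, rng: np.random.Generator
) -> Tuple[np.ndarray, HiddenPath]:
    """Simulate one trial: alternate release and docking along the train.

    The hidden path starts fully recovered (``S^-_1 = N``); one response is
    emitted per spike.
    """
    u = release_probability_sequence(params.U, params.tau_F, spikes)
    l = docking_probability(spikes.intervals, params.tau_D) if spikes.M > 1 else np.empty(0)
    M = spikes.M
    s_minus = np.empty(M, dtype=int)
    s_plus = np.empty(M, dtype=int)
    responses = np.empty(M)
    s = params.N
    for k in range(M):
        s_minus[k] = s
        sp = sample_release(s, u[k], rng)
        s_plus[k] = sp
        responses[k] = sample_response(
            s - sp, params.q, params.sigma_q, params.sigma_n, rng
        )
        if k < M - 1:
            s = sample_docking(sp, params.N, float(l[k]), rng)
    return responses, HiddenPath(s_minus=s_minus, s_plus=s_plus)


# ---------------------------------------------------------------------------
# protocols

def _train_times(spec: StimulationProtocol, rng: Optional[np.random.Generator]) -> np.ndarray:
    """Spike times of one train (n spikes + recovery spike), starting at 0."""
    n = spec.n_spikes_per_train
    if spec.kind == "regular":
        isis = np.full(n - 1, spec.T)
    else:
        isis = rng.exponential(spec.T, size=n - 1)
    times = np.concatenate([[0.0], np.cumsum(isis)])
    return np.append(times, times[-1] + spec.T_rec)


def make_protocol(spec: StimulationProtocol, seed=None) -> List[SpikeTrain]:
    """Realize a protocol as a list of per-trial spike trains.

    ``single_sweep`` yields a single long train whose block boundaries share
    a spike (the recovery spike of block *i* is the first spike of block
    *i+1*), so each block contributes ``n_spikes_per_train`` responses.
    """
    rng = np.random.default_rng(seed)
    if spec.kind in ("regular", "poisson"):
        n_trials = spec.n_trials
        if n_trials is None:
            if spec.duration is None:
                raise ValueError("need n_trials or duration")
            # nominal trial footprint: train + recovery + inter-trial gap
            span = (spec.n_spikes_per_train - 1) * spec.T + spec.T_rec + spec.inter_trial_interval
            n_trials = int(spec.duration // span)
            if n_trials < 1:
                raise ValueError("duration too short for a single trial")
        return [SpikeTrain(_train_times(spec, rng)) for _ in range(n_trials)]

    # single sweep
    if spec.duration is None:
        raise ValueError("single_sweep requires a total duration")
    times = [0.0]
    while True:
        block = _train_times(spec, rng)  # starts at 0, ends at recovery spike
        new = times[-1] + block[1:]
        if new[-1] > spec.duration:
            break
        times.extend(new.tolist())
    if len(times) == 1:
        raise ValueError("duration too short for one block")
    return [SpikeTrain(np.array(times))]


def simulate_dataset(
    params: SynapticParameters,
    protocol: StimulationProtocol,
    seed=None,
    trains: Optional[List[SpikeTrain]] = None,
) -> ResponseDataset:
    """Simulate a full synthetic experiment under a protocol.

    If ``trains`` is given the protocol's spike trains are reused (regular
    protocols share one skeleton anyway); otherwise they are generated from
    the same seeded stream that drives the responses.
    """
    rng = np.random.default_rng(seed)
    if trains is None:
        trains = make_protocol(protocol, rng)
    trials = []
    for spikes in trains:
        responses, _ = simulate_trial(params, spikes, rng)
        trials.append((spikes, responses))
    return ResponseDataset(
        trials,
        metadata={
            "protocol": protocol.to_dict(),
            "params": params.to_dict(),
            "seed": seed,
            "sigma_n": params.sigma_n,
        },
    )


# ---------------------------------------------------------------------------
# synthetic population

#: (mean, SD, low, high) per parameter, matched to cortical connections
#: (ferret mPFC layer-5 pairs); N is rounded to an integer after clipping.
_POPULATION = {
    "N": (15.0, 12.0, 2, 40),
    "q": (0.15, 0.06, 0.06, 0.32),
    "sigma_q": (0.05, 0.04, 0.01, 0.20),
    "U": (0.33, 0.13, 0.05, 0.73),
    "tau_D": (335.0, 306.0, 50.0, 1800.0),
    "tau_F": (321.0, 340.0, 30.0, 1900.0),
}


def sample_population_parameters(
    rng: np.random.Generator, sigma_n: float = 0.03
) -> SynapticParameters:
    """Draw one synthetic connection from the population distributions.

    Positive parameters are drawn log-normally with matched mean and SD
    (U normally), then clipped to the population ranges.  ``sigma_n`` is the
    recording noise applied to every synthetic connection.
    """
    out = {}
    for name, (mean, sd, lo, hi) in _POPULATION.items():
        if name == "U":
            val = rng.normal(mean, sd)
        else:
            s2 = np.log1p((sd / mean) ** 2)
            val = rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2))
        val = float(np.clip(val, lo, hi))
        out[name] = val
    out["N"] = int(round(out["N"]))
    return SynapticParameters(sigma_n=sigma_n, **out)
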