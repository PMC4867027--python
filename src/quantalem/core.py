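"""Deterministic skeleton of the stochastic Tsodyks-Markram (TM) synapse model.

A synaptic connection is modelled as ``N`` identical, independent release
sites.  A release-competent site releases its vesicle upon a presynaptic
spike with probability ``u`` (facilitating between spikes towards spikes,
decaying back to the baseline ``U`` with time constant ``tau_F``), and an
empty site re-docks a vesicle with constant rate ``1/tau_D``.  A released
vesicle contributes a quantal response with mean ``q`` and SD ``sigma_q``;
the recorded amplitude additionally carries Gaussian baseline noise of SD
``sigma_n``.

This module holds the parameter/spike-train containers and the
deterministic recursions for the release probability ``u_k``, the site
occupancy ``x_k`` and the mean response ``A * u_k * x_k`` (``A = N*q`` is
the absolute synaptic efficacy).  Time is in milliseconds, amplitudes in
millivolts, throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "SynapticParameters",
    "SpikeTrain",
    "DeterministicTrajectory",
    "docking_probability",
    "release_probability_sequence",
    "occupancy_sequence",
    "mean_response_sequence",
    "deterministic_trajectory",
]

#: continuous parameters, in the order used by the Fisher information code
CONTINUOUS_PARAMS = ("q", "sigma_q", "U", "tau_D", "tau_F")


@dataclass(frozen=True)
class SynapticParameters:
    """Full parameter vector of the stochastic TM quantal model.

    Parameters
    ----------
    N : int
        Number of release sites (>= 1).
    q : float
        Quantal size, mV (> 0).
    sigma_q : float
        Quantal SD, mV (>= 0).
    U : float
        Initial release probability, in (0, 1].
    tau_D : float
        Vesicle docking (recovery-from-depression) time constant, ms (> 0).
        ``tau_D = 0`` is accepted as the instantaneous-refill limit.
    tau_F : float
        Facilitation time constant, ms (>= 0); 0 means no facilitation.
    sigma_n : float
        Baseline (recording) noise SD, mV (>= 0; 0 only sensible for
        simulation, since response failures then become a point mass).
    """

    N: int
    q: float
    sigma_q: float
    U: float
    tau_D: float
    tau_F: float
    sigma_n: float = 0.0

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be an integer >= 1, got {self.N}")
        object.__setattr__(self, "N", int(self.N))
        if not self.q > 0:
            raise ValueError(f"q must be > 0, got {self.q}")
        if self.sigma_q < 0:
            raise ValueError(f"sigma_q must be >= 0, got {self.sigma_q}")
        if not 0 < self.U <= 1:
            raise ValueError(f"U must be in (0, 1], got {self.U}")
        if self.tau_D < 0:
            raise ValueError(f"tau_D must be >= 0, got {self.tau_D}")
        if self.tau_F < 0:
            raise ValueError(f"tau_F must be >= 0, got {self.tau_F}")
        if self.sigma_n < 0:
            raise ValueError(f"sigma_n must be >= 0, got {self.sigma_n}")

    @property
    def A(self) -> float:
        """Absolute synaptic efficacy ``A = N * q`` (mV)."""
        return self.N * self.q

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "q": self.q,
            "sigma_q": self.sigma_q,
            "U": self.U,
            "tau_D": self.tau_D,
            "tau_F": self.tau_F,
            "sigma_n": self.sigma_n,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynapticParameters":
        known = {k: d[k] for k in ("N", "q", "sigma_q", "U", "tau_D", "tau_F") if k in d}
        known["sigma_n"] = d.get("sigma_n", 0.0)
        return cls(**known)

    def replace(self, **kw) -> "SynapticParameters":
        d = self.to_dict()
        d.update(kw)
        return SynapticParameters.from_dict(d)


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing presynaptic spike times (ms)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("spike train needs at least one spike time")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @property
    def M(self) -> int:
        return self.times.size

    @property
    def intervals(self) -> np.ndarray:
        """Interspike intervals ``Delta_k = t_{k+1} - t_k`` (length M-1)."""
        return np.diff(self.times)

    def __len__(self) -> int:
        return self.M


@dataclass(frozen=True)
class DeterministicTrajectory:
    """Per-spike deterministic quantities of the TM model."""

    u: np.ndarray               # release probabilities u_1..u_M
    x: np.ndarray               # occupancy probabilities x_1..x_M
    l: np.ndarray               # docking probabilities l_1..l_{M-1}
    mean_responses: np.ndarray  # N*q*u_k*x_k, mV


def docking_probability(delta, tau_D: float):
    """Probability that an empty site re-docks a vesicle within ``delta`` ms.

    ``l(Delta) = 1 - exp(-Delta / tau_D)``.  ``tau_D = 0`` is the
    instantaneous-refill limit (probability 1 for any positive interval).
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("interval must be >= 0")
    if tau_D < 0:
        raise ValueError("tau_D must be >= 0")
    if tau_D == 0:
        return np.where(delta > 0, 1.0, 0.0)[()] if delta.ndim == 0 else np.where(delta > 0, 1.0, 0.0)
    return -np.expm1(-delta / tau_D)


def release_probability_sequence(U: float, tau_F: float, spikes: SpikeTrain) -> np.ndarray:
    """Release probabilities ``u_1..u_M`` along a spike train.

    ``u_1 = U`` and ``u_{k+1} = U + u_k (1-U) exp(-Delta_k / tau_F)``.
    ``tau_F = 0`` is handled as the exact no-facilitation limit ``u_k = U``.
    """
    if not 0 < U <= 1:
        raise ValueError("U must be in (0, 1]")
    if tau_F < 0:
        raise ValueError("tau_F must be >= 0")
    M = spikes.M
    u = np.empty(M)
    u[0] = U
    if tau_F == 0:
        u[:] = U
        return u
    decay = np.exp(-spikes.intervals / tau_F)
    for k in range(M - 1):
        u[k + 1] = U + u[k] * (1.0 - U) * decay[k]
    return u


def occupancy_sequence(params: SynapticParameters, spikes: SpikeTrain) -> np.ndarray:
    """Site occupancy probabilities ``x_1..x_M``.

    ``x_1 = 1`` (all sites competent at rest) and
    ``x_{k+1} = 1 - [1 - (1-u_k) x_k] exp(-Delta_k / tau_D)``.
    """
    u = release_probability_sequence(params.U, params.tau_F, spikes)
    M = spikes.M
    x = np.empty(M)
    x[0] = 1.0
    if M == 1:
        return x
    if params.tau_D == 0:
        x[:] = 1.0
        return x
    decay = np.exp(-spikes.intervals / params.tau_D)
    for k in range(M - 1):
        x[k + 1] = 1.0 - (1.0 - (1.0 - u[k]) * x[k]) * decay[k]
    return x


def mean_response_sequence(params: SynapticParameters, spikes: SpikeTrain) -> np.ndarray:
    """Mean responses ``Rbar_k = N q u_k x_k`` (mV) along a spike train."""
    u = release_probability_sequence(params.U, params.tau_F, spikes)
    x = occupancy_sequence(params, spikes)
    return params.A * u * x


def deterministic_trajectory(params: SynapticParameters, spikes: SpikeTrain) -> DeterministicTrajectory:
    """Bundle u, x, l and mean responses for one spike train."""
    u = release_probability_sequence(params.U, params.tau_F, spikes)
    x = occupancy_sequence(params, spikes)
    l = docking_probability(spikes.intervals, params.tau_D) if spikes.M > 1 else np.empty(0)
    return DeterministicTrajectory(u=u, x=x, l=np.atleast_1d(l), mean_responses=params.A * u * x)
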