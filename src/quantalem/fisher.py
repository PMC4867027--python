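"""Fisher information and Cramér-Rao protocol analysis.

The score (gradient of the log-likelihood in the continuous parameters
``q, sigma_q, U, tau_D, tau_F``) is computed exactly by propagating the
derivatives of the forward variables alongside the scaled forward
recursion: the release-transition derivatives flow through ``du_k/dU`` and
``du_k/dtau_F`` (recursions of the facilitation dynamics), the docking
derivatives through ``dl_k/dtau_D``, and the emission derivatives through
the analytic inverse-Gaussian scores under the noise convolution.

The Fisher Information Matrix (FIM) of a stimulation protocol is the
expected outer product of the experiment score, estimated by Monte Carlo
over fully simulated experiments.  Its inverse yields per-parameter lower
bounds on the achievable relative estimation error (normalized Cramér-Rao
bounds), which makes stimulation protocols comparable before any
experiment.  ``N`` is discrete and excluded from the FIM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .core import CONTINUOUS_PARAMS, SpikeTrain, SynapticParameters
from .emission import emission_matrix_derivs
from .likelihood import (
    docking_matrix,
    docking_matrix_dl,
    release_matrix,
    release_matrix_du,
)
from .simulate import (
    ResponseDataset,
    StimulationProtocol,
    make_protocol,
    sample_inverse_gaussian,
)

__all__ = [
    "FIMResult",
    "score_vector",
    "dataset_score",
    "fisher_information_matrix",
    "min_relative_errors",
    "min_trials_for_precision",
    "compare_protocols",
]


@dataclass
class FIMResult:
    matrix: np.ndarray                 # (5, 5) over CONTINUOUS_PARAMS
    n_mc: int
    params: SynapticParameters
    seed: Optional[int] = None
    param_names: tuple = CONTINUOUS_PARAMS
    min_relative_errors: Dict[str, float] = field(default_factory=dict)


def _facilitation_with_grads(U, tau_F, intervals):
    """u_k, du_k/dU, du_k/dtau_F for a batch of trains; shapes (B, M)."""
    B, Mm1 = intervals.shape
    M = Mm1 + 1
    u = np.empty((B, M))
    du = np.empty((B, M))
    df = np.empty((B, M))
    u[:, 0], du[:, 0], df[:, 0] = U, 1.0, 0.0
    if M == 1:
        return u, du, df
    if tau_F == 0.0:
        u[:], du[:], df[:] = U, 1.0, 0.0
        return u, du, df
    e = np.exp(-intervals / tau_F)
    for k in range(M - 1):
        u[:, k + 1] = U + u[:, k] * (1.0 - U) * e[:, k]
        du[:, k + 1] = 1.0 + du[:, k] * (1.0 - U) * e[:, k] - u[:, k] * e[:, k]
        df[:, k + 1] = (
            df[:, k] * (1.0 - U) * e[:, k]
            + u[:, k] * (1.0 - U) * e[:, k] * intervals[:, k] / tau_F**2
        )
    return u, du, df


def _docking_with_grads(tau_D, intervals):
    """l_k and dl_k/dtau_D; shapes (B, M-1)."""
    if tau_D == 0.0:
        return np.ones_like(intervals), np.zeros_like(intervals)
    e = np.exp(-intervals / tau_D)
    return 1.0 - e, -e * intervals / tau_D**2


def _score_batch(resp: np.ndarray, intervals: np.ndarray, params: SynapticParameters):
    """Per-trial scores for a batch of trials of equal length.

    ``resp`` is (B, M); ``intervals`` is (B, M-1).  Returns (B, 5) in the
    order of :data:`~quantalem.core.CONTINUOUS_PARAMS`.
    """
    B, M = resp.shape
    N = params.N
    u, du_dU, du_dF = _facilitation_with_grads(params.U, params.tau_F, intervals)
    l, dl_dD = _docking_with_grads(params.tau_D, intervals)

    m_idx = np.arange(N + 1)[:, None] - np.arange(N + 1)[None, :]
    m_clip = np.clip(m_idx, 0, N)
    m_valid = m_idx >= 0

    a = np.zeros((B, N + 1))
    a[:, N] = 1.0
    d = np.zeros((B, 5, N + 1))

    for k in range(M):
        E, dEq, dEs = emission_matrix_derivs(
            resp[:, k], N, params.q, params.sigma_q, params.sigma_n
        )
        Em = np.where(m_valid, E[:, m_clip], 0.0)
        dEmq = np.where(m_valid, dEq[:, m_clip], 0.0)
        dEms = np.where(m_valid, dEs[:, m_clip], 0.0)
        rel = release_matrix(N, u[:, k])                       # (B, S, S)
        drel = release_matrix_du(N, u[:, k])
        T = rel * Em
        dT = np.empty((5, B, N + 1, N + 1))
        dT[0] = rel * dEmq
        dT[1] = rel * dEms
        dT[2] = drel * du_dU[:, k, None, None] * Em
        dT[3] = 0.0
        dT[4] = drel * du_dF[:, k, None, None] * Em

        ap = np.einsum("bi,bij->bj", a, T)
        dp = np.einsum("bpi,bij->bpj", d, T) + np.einsum("bi,pbij->bpj", a, dT)
        c = ap.sum(axis=1)
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            raise FloatingPointError(f"score recursion degenerate at spike {k + 1}")
        a = ap / c[:, None]
        d = dp / c[:, None, None]

        if k < M - 1:
            D = docking_matrix(N, l[:, k])
            dD = docking_matrix_dl(N, l[:, k]) * dl_dD[:, k, None, None]
            a_new = np.einsum("bi,bij->bj", a, D)
            d_new = np.einsum("bpi,bij->bpj", d, D)
            d_new[:, 3, :] += np.einsum("bi,bij->bj", a, dD)
            a, d = a_new, d_new

    return d.sum(axis=2)  # a sums to 1 after scaling


def score_vector(responses, spikes: SpikeTrain, params: SynapticParameters) -> np.ndarray:
    """Gradient of one trial's log-likelihood in the continuous parameters.

    Order: ``(q, sigma_q, U, tau_D, tau_F)``.  For a single-spike train the
    ``tau_D`` and ``tau_F`` components are exactly zero (``u_1 = U`` and no
    interspike interval exists).
    """
    resp = np.asarray(responses, dtype=float)[None, :]
    intervals = spikes.intervals[None, :]
    out = _score_batch(resp, intervals, params)[0]
    if not np.all(np.isfinite(out)):
        bad = [CONTINUOUS_PARAMS[i] for i in np.nonzero(~np.isfinite(out))[0]]
        raise FloatingPointError(f"non-finite score component(s): {bad}")
    return out


def dataset_score(dataset: ResponseDataset, params: SynapticParameters) -> np.ndarray:
    """Score of a whole experiment: sum of per-trial scores."""
    total = np.zeros(len(CONTINUOUS_PARAMS))
    for spikes, resp in dataset.trials:
        total += score_vector(resp, spikes, params)
    return total


# ---------------------------------------------------------------------------
# Monte-Carlo FIM

def _simulate_batch(params: SynapticParameters, u, l, rng) -> np.ndarray:
    """Vectorized simulation of B trials with per-trial u/l sequences."""
    B, M = u.shape
    N = params.N
    resp = np.empty((B, M))
    s = np.full(B, N)
    for k in range(M):
        released = rng.binomial(s, u[:, k])
        amp = np.zeros(B)
        pos = released > 0
        if np.any(pos):
            m = released[pos].astype(float)
            if params.sigma_q > 0:
                mu = m * params.q
                lam = m * m * params.q**3 / params.sigma_q**2
                amp[pos] = sample_inverse_gaussian(mu, lam, rng)
            else:
                amp[pos] = m * params.q
        if params.sigma_n > 0:
            amp += params.sigma_n * rng.standard_normal(B)
        resp[:, k] = amp
        if k < M - 1:
            s = (s - released) + rng.binomial(N - (s - released), l[:, k])
    return resp


def _experiment_scores(params, protocol: StimulationProtocol, n_mc: int, rng) -> np.ndarray:
    """(n_mc, 5) array of whole-experiment scores under the protocol."""
    P = len(CONTINUOUS_PARAMS)
    if protocol.kind in ("regular", "poisson"):
        trains = [make_protocol(protocol, rng) for _ in range(n_mc)]
        n_trials = len(trains[0])
        M = trains[0][0].M
        intervals = np.array(
            [t.intervals for rep in trains for t in rep]
        ).reshape(n_mc * n_trials, M - 1)
        u, du, df = _facilitation_with_grads(params.U, params.tau_F, intervals)
        l, _ = _docking_with_grads(params.tau_D, intervals)
        resp = _simulate_batch(params, u, l, rng)
        scores = _score_batch(resp, intervals, params)
        return scores.reshape(n_mc, n_trials, P).sum(axis=1)

    # single sweep: one long train per replicate; batch replicates of equal length
    trains = [make_protocol(protocol, rng)[0] for _ in range(n_mc)]
    scores = np.zeros((n_mc, P))
    by_M: Dict[int, list] = {}
    for i, t in enumerate(trains):
        by_M.setdefault(t.M, []).append(i)
    for M, idxs in by_M.items():
        intervals = np.array([trains[i].intervals for i in idxs])
        u, _, _ = _facilitation_with_grads(params.U, params.tau_F, intervals)
        l, _ = _docking_with_grads(params.tau_D, intervals)
        resp = _simulate_batch(params, u, l, rng)
        scores[idxs] = _score_batch(resp, intervals, params)
    return scores


def fisher_information_matrix(
    params: SynapticParameters,
    protocol: StimulationProtocol,
    n_mc: int = 1000,
    seed=None,
) -> FIMResult:
    """Monte-Carlo FIM: average outer product of simulated experiment scores."""
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(seed)
    scores = _experiment_scores(params, protocol, n_mc, rng)
    fim = np.einsum("bp,bq->pq", scores, scores) / n_mc
    result = FIMResult(matrix=fim, n_mc=n_mc, params=params, seed=seed)
    result.min_relative_errors = min_relative_errors(result, params)
    return result


def min_relative_errors(fim: FIMResult, params: SynapticParameters) -> Dict[str, float]:
    """Normalized Cramér-Rao bounds ``eps_j = sqrt([I^-1]_jj) / theta_j``.

    Parameters carrying no information (identically zero FIM row/column,
    e.g. the time constants for a single-spike protocol) are reported as
    infinite; a singular matrix on the informative block falls back to the
    pseudo-inverse.
    """
    I = fim.matrix
    theta = np.array([getattr(params, name) for name in CONTINUOUS_PARAMS])
    scale = np.sqrt(np.diag(I))
    dead = scale <= 1e-300
    eps = np.full(len(CONTINUOUS_PARAMS), np.inf)
    live = ~dead
    if live.any():
        sub = I[np.ix_(live, live)]
        try:
            inv = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            inv = np.linalg.pinv(sub)
        var = np.clip(np.diag(inv), 0.0, None)
        eps[live] = np.sqrt(var) / np.abs(theta[live])
    return dict(zip(CONTINUOUS_PARAMS, eps))


def min_trials_for_precision(cv: float, rel_precision: float, z: float = 3.0) -> int:
    """Minimum repetitions so the trial-averaged response reaches a target
    relative precision.

    By the central limit theorem the standard error of the average after
    ``n`` trials is ``cv / sqrt(n)`` of the mean; the smallest ``n`` with
    ``z * cv / sqrt(n) <= rel_precision`` is returned (``z = 3`` standard
    errors by default).  A CV of 0.3 gives 81 repetitions at 10% precision
    and 324 at 5%.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if not 0 < rel_precision < 1:
        raise ValueError("rel_precision must be in (0, 1)")
    if cv == 0:
        return 1
    n = math.ceil((z * cv / rel_precision) ** 2 - 1e-12)
    return max(int(n), 1)


def compare_protocols(
    params: SynapticParameters,
    protocols: Dict[str, StimulationProtocol],
    n_mc: int = 1000,
    seed=None,
) -> Dict[str, Dict[str, float]]:
    """Cramér-Rao error bounds per parameter for each named protocol."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, proto in protocols.items():
        sub = int(rng.integers(2**31))
        out[name] = fisher_information_matrix(params, proto, n_mc, sub).min_relative_errors
    return out
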