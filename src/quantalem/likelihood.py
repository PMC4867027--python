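"""Exact likelihood of response trains via forward-backward recursions.

The hidden state is the number of release-competent sites; each spike
involves a release transition (binomial thinning with probability ``u_k``),
an emission (quantal density of the released count) and, between spikes, a
docking transition (binomial refill with probability ``l_k``).  Forward and
backward variables are defined over the pair chain ``S^-_1, S^+_1, ...,
S^-_M, S^+_M`` with the deterministic initial condition ``S^-_1 = N``
(fully recovered synapse).

Underflow is controlled by per-spike normalization (scaling) constants; the
log-likelihood accumulates from the scalers.  A brute-force enumeration
over all hidden paths is provided as an independent oracle for small
instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iproduct

import numpy as np
from scipy.special import comb

from .core import (
    SpikeTrain,
    SynapticParameters,
    docking_probability,
    release_probability_sequence,
)
from .emission import emission_matrix

__all__ = [
    "FBTables",
    "release_matrix",
    "docking_matrix",
    "forward_pass",
    "backward_pass",
    "forward_backward",
    "pair_posteriors",
    "dataset_log_likelihood",
    "brute_force_log_likelihood",
    "brute_force_pair_posteriors",
]

_comb_cache: dict = {}


def _comb_table(N: int) -> np.ndarray:
    tab = _comb_cache.get(N)
    if tab is None:
        tab = comb(np.arange(N + 1)[:, None], np.arange(N + 1)[None, :])
        _comb_cache[N] = tab
    return tab


def release_matrix(N: int, u) -> np.ndarray:
    """P(S+ = col | S- = row): binomial release of ``row - col`` vesicles.

    ``u`` may be a scalar or a batch array; the result has shape
    ``(..., N+1, N+1)`` with zero entries where ``S+ > S-``.
    """
    u = np.asarray(u, dtype=float)
    C = _comb_table(N)
    s_minus = np.arange(N + 1)[:, None]
    s_plus = np.arange(N + 1)[None, :]
    k = s_minus - s_plus                      # vesicles released
    valid = k >= 0
    kc = np.where(valid, k, 0)
    uu = u[..., None, None]
    mat = C[s_minus, kc] * uu**kc * (1.0 - uu) ** s_plus
    return np.where(valid, mat, 0.0)


def release_matrix_du(N: int, u) -> np.ndarray:
    """Derivative of :func:`release_matrix` with respect to ``u``."""
    u = np.asarray(u, dtype=float)
    C = _comb_table(N)
    s_minus = np.arange(N + 1)[:, None]
    s_plus = np.arange(N + 1)[None, :]
    k = s_minus - s_plus
    valid = k >= 0
    kc = np.where(valid, k, 0)
    uu = u[..., None, None]
    # d/du [u^k (1-u)^s] = k u^(k-1) (1-u)^s - s u^k (1-u)^(s-1)
    t1 = kc * uu ** np.where(kc > 0, kc - 1, 0) * (1.0 - uu) ** s_plus
    t1 = np.where(kc > 0, t1, 0.0)
    t2 = s_plus * uu**kc * (1.0 - uu) ** np.where(s_plus > 0, s_plus - 1, 0)
    t2 = np.where(s_plus > 0, t2, 0.0)
    return np.where(valid, C[s_minus, kc] * (t1 - t2), 0.0)


def docking_matrix(N: int, l) -> np.ndarray:
    """P(next S- = col | S+ = row): binomial refill of empty sites."""
    l = np.asarray(l, dtype=float)
    C = _comb_table(N)
    s_plus = np.arange(N + 1)[:, None]
    s_next = np.arange(N + 1)[None, :]
    k = s_next - s_plus                       # refilled sites
    valid = k >= 0
    kc = np.where(valid, k, 0)
    ll = l[..., None, None]
    mat = C[N - s_plus, kc] * ll**kc * (1.0 - ll) ** (N - s_next)
    return np.where(valid, mat, 0.0)


def docking_matrix_dl(N: int, l) -> np.ndarray:
    """Derivative of :func:`docking_matrix` with respect to ``l``."""
    l = np.asarray(l, dtype=float)
    C = _comb_table(N)
    s_plus = np.arange(N + 1)[:, None]
    s_next = np.arange(N + 1)[None, :]
    k = s_next - s_plus
    nrem = N - s_next
    valid = k >= 0
    kc = np.where(valid, k, 0)
    ll = l[..., None, None]
    t1 = kc * ll ** np.where(kc > 0, kc - 1, 0) * (1.0 - ll) ** nrem
    t1 = np.where(kc > 0, t1, 0.0)
    t2 = nrem * ll**kc * (1.0 - ll) ** np.where(nrem > 0, nrem - 1, 0)
    t2 = np.where(nrem > 0, t2, 0.0)
    return np.where(valid, C[N - s_plus, kc] * (t1 - t2), 0.0)


@dataclass
class FBTables:
    """Scaled forward/backward tables for one trial.

    The scaled variables satisfy ``sum_S alpha_minus[k] * beta_minus[k] = 1``
    at every spike; unscaled quantities are recovered through the per-spike
    log scalers, whose sum is the log-likelihood.
    """

    alpha_minus: np.ndarray   # (M, N+1)
    alpha_plus: np.ndarray    # (M, N+1)
    beta_minus: np.ndarray    # (M, N+1)
    beta_plus: np.ndarray     # (M, N+1)
    log_scalers: np.ndarray   # (M,)
    log_likelihood: float


def _trial_matrices(responses, spikes: SpikeTrain, params: SynapticParameters):
    """Per-spike release+emission products T_k and docking matrices D_k."""
    N = params.N
    u = release_probability_sequence(params.U, params.tau_F, spikes)
    E = emission_matrix(responses, N, params.q, params.sigma_q, params.sigma_n)
    m_idx = np.arange(N + 1)[:, None] - np.arange(N + 1)[None, :]  # released count
    T = []
    for k in range(spikes.M):
        B = release_matrix(N, u[k])
        Em = np.where(m_idx >= 0, E[k][np.clip(m_idx, 0, N)], 0.0)
        T.append(B * Em)
    if spikes.M > 1:
        l = docking_probability(spikes.intervals, params.tau_D)
        D = [docking_matrix(N, l[k]) for k in range(spikes.M - 1)]
    else:
        D = []
    return T, D


def forward_backward(responses, spikes: SpikeTrain, params: SynapticParameters) -> FBTables:
    """Run the scaled forward and backward recursions for one trial."""
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (spikes.M,):
        raise ValueError("responses must align with spikes")
    N, M = params.N, spikes.M
    T, D = _trial_matrices(responses, spikes, params)

    a_minus = np.zeros((M, N + 1))
    a_plus = np.zeros((M, N + 1))
    log_c = np.zeros(M)
    a = np.zeros(N + 1)
    a[N] = 1.0                      # P(S1- = N) = 1
    for k in range(M):
        a_minus[k] = a
        ap = a @ T[k]
        c = ap.sum()
        if not np.isfinite(c) or c <= 0.0:
            raise FloatingPointError(f"forward pass degenerate at spike {k + 1}")
        a_plus[k] = ap / c
        log_c[k] = np.log(c)
        if k < M - 1:
            a = a_plus[k] @ D[k]

    b_minus = np.zeros((M, N + 1))
    b_plus = np.zeros((M, N + 1))
    b = np.ones(N + 1)              # terminal condition: no future observations
    for k in range(M - 1, -1, -1):
        b_plus[k] = b
        b_minus[k] = (T[k] @ b) / np.exp(log_c[k])
        if k > 0:
            b = D[k - 1] @ b_minus[k]

    return FBTables(
        alpha_minus=a_minus,
        alpha_plus=a_plus,
        beta_minus=b_minus,
        beta_plus=b_plus,
        log_scalers=log_c,
        log_likelihood=float(log_c.sum()),
    )


def forward_pass(responses, spikes: SpikeTrain, params: SynapticParameters) -> FBTables:
    """Forward recursion (alpha tables and log-likelihood)."""
    return forward_backward(responses, spikes, params)


def backward_pass(responses, spikes: SpikeTrain, params: SynapticParameters) -> FBTables:
    """Backward recursion (beta tables; shares scalers with the forward pass)."""
    return forward_backward(responses, spikes, params)


def pair_posteriors(responses, spikes: SpikeTrain, params: SynapticParameters) -> np.ndarray:
    """Posterior ``P(S^-_k, S^+_k | R_{1..M})`` as an (M, N+1, N+1) array."""
    fb = forward_backward(responses, spikes, params)
    T, _ = _trial_matrices(np.asarray(responses, dtype=float), spikes, params)
    M, N1 = fb.alpha_minus.shape
    post = np.empty((M, N1, N1))
    for k in range(M):
        post[k] = (
            fb.alpha_minus[k][:, None] * T[k] * fb.beta_plus[k][None, :]
        ) / np.exp(fb.log_scalers[k])
        s = post[k].sum()
        post[k] /= s  # guard against accumulated round-off
    return post


def dataset_log_likelihood(dataset, params: SynapticParameters) -> float:
    """Sum of per-trial log-likelihoods (trials are independent)."""
    return float(
        sum(forward_backward(r, s, params).log_likelihood for s, r in dataset.trials)
    )


def per_trial_log_likelihoods(dataset, params: SynapticParameters) -> np.ndarray:
    return np.array(
        [forward_backward(r, s, params).log_likelihood for s, r in dataset.trials]
    )


def batched_log_likelihood(responses: np.ndarray, spikes: SpikeTrain,
                           params: SynapticParameters) -> np.ndarray:
    """Log-likelihood of many trials sharing one spike train.

    ``responses`` is (B, M); returns a length-B vector.  Used where many
    simulated trials must be scored at once (e.g. the leave-one-out
    predictive check).
    """
    responses = np.asarray(responses, dtype=float)
    B, M = responses.shape
    N = params.N
    u = release_probability_sequence(params.U, params.tau_F, spikes)
    E = emission_matrix(responses.ravel(), N, params.q, params.sigma_q, params.sigma_n)
    E = E.reshape(B, M, N + 1)
    if M > 1:
        l = docking_probability(spikes.intervals, params.tau_D)
        D = [docking_matrix(N, l[k]) for k in range(M - 1)]
    m_idx = np.arange(N + 1)[:, None] - np.arange(N + 1)[None, :]
    m_clip = np.clip(m_idx, 0, N)
    m_valid = m_idx >= 0
    a = np.zeros((B, N + 1))
    a[:, N] = 1.0
    ll = np.zeros(B)
    for k in range(M):
        T = release_matrix(N, u[k])[None, :, :] * np.where(
            m_valid, E[:, k, :][:, m_clip], 0.0
        )
        ap = np.einsum("bi,bij->bj", a, T)
        c = ap.sum(axis=1)
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            raise FloatingPointError(f"forward pass degenerate at spike {k + 1}")
        a = ap / c[:, None]
        ll += np.log(c)
        if k < M - 1:
            a = a @ D[k]
    return ll


# ---------------------------------------------------------------------------
# enumeration oracle

_BRUTE_N_MAX = 4
_BRUTE_M_MAX = 4


def _enumerate_paths(responses, spikes: SpikeTrain, params: SynapticParameters):
    """Yield (probability-density weight, s_minus, s_plus) over all paths."""
    N, M = params.N, spikes.M
    if N > _BRUTE_N_MAX or M > _BRUTE_M_MAX:
        raise ValueError(
            f"enumeration limited to N <= {_BRUTE_N_MAX}, M <= {_BRUTE_M_MAX}"
        )
    responses = np.asarray(responses, dtype=float)
    u = release_probability_sequence(params.U, params.tau_F, spikes)
    l = docking_probability(spikes.intervals, params.tau_D) if M > 1 else np.empty(0)
    rel = [release_matrix(N, u[k]) for k in range(M)]
    dock = [docking_matrix(N, l[k]) for k in range(M - 1)]
    E = emission_matrix(responses, N, params.q, params.sigma_q, params.sigma_n)

    states = range(N + 1)
    for path in _iproduct(*([states] * (2 * M - 1))):
        s_minus = (N,) + path[1::2]
        s_plus = path[0::2]
        w = 1.0
        for k in range(M):
            if s_plus[k] > s_minus[k]:
                w = 0.0
                break
            w *= rel[k][s_minus[k], s_plus[k]] * E[k, s_minus[k] - s_plus[k]]
            if k < M - 1:
                w *= dock[k][s_plus[k], s_minus[k + 1]]
        if w > 0.0:
            yield w, s_minus, s_plus


def brute_force_log_likelihood(responses, spikes, params) -> float:
    """Exact log-likelihood by summation over every hidden path (oracle)."""
    total = sum(w for w, *_ in _enumerate_paths(responses, spikes, params))
    return float(np.log(total))


def brute_force_pair_posteriors(responses, spikes, params) -> np.ndarray:
    """Exact pair posteriors by enumeration (oracle for small instances)."""
    N, M = params.N, spikes.M
    post = np.zeros((M, N + 1, N + 1))
    total = 0.0
    for w, s_minus, s_plus in _enumerate_paths(responses, spikes, params):
        total += w
        for k in range(M):
            post[k, s_minus[k], s_plus[k]] += w
    return post / total
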