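"""Exact expectation-maximization over the hidden release-site counts.

The E-step computes posterior expectations of the pair states
``(S^-_k, S^+_k)`` with the forward-backward engine; the M-step solves the
re-estimation equations block by block (the auxiliary function separates):

* quantal block ``(q, sigma_q)`` — closed form without baseline noise;
  with noise, a simultaneous 2-D root of the implicit equations involving
  the posterior moments of the latent noiseless amplitude;
* docking block ``tau_D`` — a bracketed 1-D root of the docking score;
* release block ``(U, tau_F)`` — a simultaneous 2-D root of the two
  release scores (``u_k`` and its derivatives depend on both parameters).

``N`` is discrete and is selected by an outer scan (:func:`fit`): EM is run
per candidate ``N`` and the maximum-likelihood ``N`` is returned, ties
broken toward smaller ``N``.  Every M-step is verified to not decrease its
block of the auxiliary function (falling back to direct maximization if a
root lands badly), which preserves the EM monotonicity guarantee.

Baseline noise ``sigma_n`` is treated as known (measured from the traces or
configured), never re-estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .core import SpikeTrain, SynapticParameters
from .emission import emission_matrix, emission_moments
from .likelihood import docking_matrix, release_matrix
from .core import docking_probability, release_probability_sequence
from .simulate import ResponseDataset

__all__ = ["EMOptions", "EMResult", "SufficientStats", "e_step", "m_step", "fit_fixed_N", "fit"]

_SIGMA_Q_FLOOR = 1e-4
_TAU_LO, _TAU_HI = 1e-2, 1e7


@dataclass
class EMOptions:
    """Tunable knobs of the EM fit (defaults follow the package's choices)."""

    tol: float = 1e-8            # relative log-likelihood change to stop
    max_iter: int = 500
    restarts: int = 5            # independent perturbed initializations
    init: Optional[SynapticParameters] = None
    sigma_n: Optional[float] = None   # known baseline noise SD (mV)
    seed: int = 0                # for restart perturbations only

    def resolve_sigma_n(self, dataset: ResponseDataset) -> float:
        if self.sigma_n is not None:
            return float(self.sigma_n)
        return float(dataset.metadata.get("sigma_n", 0.0))


@dataclass
class GroupStats:
    """Posterior expectations for one group of trials sharing a spike train."""

    intervals: np.ndarray        # (M-1,)
    n_trials: int
    exp_s_minus: np.ndarray      # (M,) summed over the group's trials
    exp_s_plus: np.ndarray       # (M,)
    releases: np.ndarray         # (M,)  sum of <S- - S+>


@dataclass
class SufficientStats:
    """Accumulated E-step output for one dataset."""

    groups: List[GroupStats]
    responses: np.ndarray        # (J,) all responses, flattened over trials/spikes
    released_weights: np.ndarray  # (J, N+1) posterior weight of m released vesicles
    log_likelihood: float
    N: int


@dataclass
class EMResult:
    params_hat: SynapticParameters
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: np.ndarray
    per_N_profile: List[Tuple[int, float, SynapticParameters]] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# grouping trials by spike-train skeleton (regular protocols share one)

def _group_trials(dataset: ResponseDataset):
    groups = {}
    for spikes, resp in dataset.trials:
        key = tuple(np.round(spikes.times, 9))
        groups.setdefault(key, (spikes, []))[1].append(resp)
    return [(spikes, np.vstack(rs)) for spikes, rs in groups.values()]


# ---------------------------------------------------------------------------
# E-step

def _fb_group(resp: np.ndarray, spikes: SpikeTrain, params: SynapticParameters):
    """Batched forward-backward over trials sharing one spike train.

    Returns (log-likelihood summed over trials, exp_s_minus (B,M),
    exp_s_plus (B,M), released weights (B,M,N+1)).
    """
    B, M = resp.shape
    N = params.N
    u = release_probability_sequence(params.U, params.tau_F, spikes)
    rel = [release_matrix(N, u[k]) for k in range(M)]
    if M > 1:
        l = docking_probability(spikes.intervals, params.tau_D)
        dock = [docking_matrix(N, l[k]) for k in range(M - 1)]
    E = emission_matrix(resp.ravel(), N, params.q, params.sigma_q, params.sigma_n)
    E = E.reshape(B, M, N + 1)

    m_idx = np.arange(N + 1)[:, None] - np.arange(N + 1)[None, :]
    m_clip = np.clip(m_idx, 0, N)
    m_valid = m_idx >= 0

    # T[b] at spike k: rel[k] * E[b, k, m]
    a_minus = np.zeros((M, B, N + 1))
    a_plus = np.zeros((M, B, N + 1))
    log_c = np.zeros((B, M))
    a = np.zeros((B, N + 1))
    a[:, N] = 1.0
    Ts = []
    for k in range(M):
        Em = np.where(m_valid, E[:, k, :][:, m_clip], 0.0)   # (B, N+1, N+1)
        T = rel[k][None, :, :] * Em
        Ts.append(T)
        a_minus[k] = a
        ap = np.einsum("bi,bij->bj", a, T)
        c = ap.sum(axis=1)
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            raise FloatingPointError(f"forward pass degenerate at spike {k + 1}")
        a_plus[k] = ap / c[:, None]
        log_c[:, k] = np.log(c)
        if k < M - 1:
            a = a_plus[k] @ dock[k]

    b = np.ones((B, N + 1))
    sm = np.zeros((B, M))
    sp = np.zeros((B, M))
    wm = np.zeros((B, M, N + 1))
    states = np.arange(N + 1)
    for k in range(M - 1, -1, -1):
        # pair posterior at spike k
        P = a_minus[k][:, :, None] * Ts[k] * b[:, None, :] / np.exp(log_c[:, k])[:, None, None]
        P /= P.sum(axis=(1, 2), keepdims=True)
        sm[:, k] = np.einsum("bij,i->b", P, states)
        sp[:, k] = np.einsum("bij,j->b", P, states)
        for m in range(N + 1):
            idx = np.arange(m, N + 1)
            wm[:, k, m] = P[:, idx, idx - m].sum(axis=1)
        bminus = np.einsum("bij,bj->bi", Ts[k], b) / np.exp(log_c[:, k])[:, None]
        if k > 0:
            b = np.einsum("ij,bj->bi", dock[k - 1], bminus)
    return float(log_c.sum()), sm, sp, wm


def e_step(dataset: ResponseDataset, params: SynapticParameters) -> SufficientStats:
    """Posterior expectations of the hidden site counts, pooled over trials."""
    groups = []
    resp_all = []
    wm_all = []
    total_ll = 0.0
    for spikes, resp in _group_trials(dataset):
        ll, sm, sp, wm = _fb_group(resp, spikes, params)
        total_ll += ll
        groups.append(
            GroupStats(
                intervals=spikes.intervals,
                n_trials=resp.shape[0],
                exp_s_minus=sm.sum(axis=0),
                exp_s_plus=sp.sum(axis=0),
                releases=(sm - sp).sum(axis=0),
            )
        )
        resp_all.append(resp.ravel())
        wm_all.append(wm.reshape(-1, params.N + 1))
    return SufficientStats(
        groups=groups,
        responses=np.concatenate(resp_all),
        released_weights=np.vstack(wm_all),
        log_likelihood=total_ll,
        N=params.N,
    )


# ---------------------------------------------------------------------------
# M-step blocks

def _u_and_grads(U: float, tau_F: float, intervals: np.ndarray):
    """u_k with dU- and dtau_F-derivatives along one train (recursions)."""
    M = intervals.size + 1
    u = np.empty(M)
    du = np.empty(M)
    df = np.empty(M)
    u[0], du[0], df[0] = U, 1.0, 0.0
    if M == 1:
        return u, du, df
    e = np.exp(-intervals / tau_F)
    for k in range(M - 1):
        u[k + 1] = U + u[k] * (1.0 - U) * e[k]
        du[k + 1] = 1.0 + du[k] * (1.0 - U) * e[k] - u[k] * e[k]
        df[k + 1] = df[k] * (1.0 - U) * e[k] + u[k] * (1.0 - U) * e[k] * intervals[k] / tau_F**2
    return u, du, df


def _clip_z(z):
    """Keep (logit U, log tau_F) inside the admissible box."""
    return (
        float(np.clip(z[0], -13.8, 13.8)),
        float(np.clip(z[1], math.log(_TAU_LO), math.log(_TAU_HI))),
    )


def _release_scores(z, groups: Sequence[GroupStats]):
    """Score equations for (U, tau_F) in (logit U, log tau_F) coordinates."""
    z0, z1 = _clip_z(z)
    U = 1.0 / (1.0 + math.exp(-z0))
    tau_F = math.exp(z1)
    sU = sF = 0.0
    for g in groups:
        u, du, df = _u_and_grads(U, tau_F, g.intervals)
        uc = np.clip(u, 1e-12, 1.0 - 1e-12)
        dq_du = g.releases / uc - g.exp_s_plus / (1.0 - uc)
        sU += float(du @ dq_du)
        sF += float(df @ dq_du)
    return np.array([sU, sF])


def _release_Q(z, groups: Sequence[GroupStats]) -> float:
    z0, z1 = _clip_z(z)
    U = 1.0 / (1.0 + math.exp(-z0))
    tau_F = math.exp(z1)
    q = 0.0
    for g in groups:
        u, _, _ = _u_and_grads(U, tau_F, g.intervals)
        uc = np.clip(u, 1e-300, 1.0 - 1e-16)
        q += float(g.releases @ np.log(uc) + g.exp_s_plus @ np.log1p(-uc))
    return q


def _docking_score(tau_D: float, groups: Sequence[GroupStats], N: int) -> float:
    s = 0.0
    for g in groups:
        if g.intervals.size == 0:
            continue
        delta = g.intervals
        e = np.exp(-delta / tau_D)
        l = np.clip(1.0 - e, 1e-300, 1.0 - 1e-16)
        dl = -e * delta / tau_D**2
        refills = g.exp_s_minus[1:] - g.exp_s_plus[:-1]
        empty = g.n_trials * N - g.exp_s_minus[1:]
        s += float(dl @ (refills / l - empty / (1.0 - l)))
    return s


def _docking_Q(tau_D: float, groups: Sequence[GroupStats], N: int) -> float:
    q = 0.0
    for g in groups:
        if g.intervals.size == 0:
            continue
        l = np.clip(docking_probability(g.intervals, tau_D), 1e-300, 1.0 - 1e-16)
        refills = g.exp_s_minus[1:] - g.exp_s_plus[:-1]
        empty = g.n_trials * N - g.exp_s_minus[1:]
        q += float(refills @ np.log(l) + empty @ np.log1p(-l))
    return q


def _emission_equations(x, r, w, wm_sum, N, sigma_n):
    """Implicit (q, sigma_q) re-estimation equations with baseline noise.

    The posterior moments of the latent noiseless amplitude are evaluated
    at the *candidate* parameters, making the equations implicit; the
    quadratic moment is reduced via E[(y-a)^2/y] = E[y] - 2a + a^2 E[1/y].
    """
    q, sq = math.exp(x[0]), math.exp(x[1])
    _, m1, minv = emission_moments(r, N, q, sq, sigma_n)
    m_vals = np.arange(N + 1)[None, :]
    a = q * m_vals[:, 1:]
    m2 = m1[:, 1:] - 2.0 * a + a * a * minv[:, 1:]
    f1 = float(np.nansum(w[:, 1:] * (m1[:, 1:] - a)))
    f2 = float(np.nansum(w[:, 1:] * (m2 - sq * sq / q)))
    return np.array([f1, f2]) / max(wm_sum, 1e-12)


def _quantal_update_fast(r, w, N, sigma_n, params_old):
    """Closed-form ascent step for (q, sigma_q) with baseline noise.

    Treats the latent noiseless amplitude ``y`` as an additional hidden
    variable: its posterior moments at the current parameters give the
    exact maximizer of the expanded auxiliary function in closed form
    (one quadrature pass).  Shares its fixed points with the implicit
    equations of :func:`_emission_equations` while never decreasing the
    likelihood.
    """
    _, m1, minv = emission_moments(r, N, params_old.q, params_old.sigma_q, sigma_n)
    m_vals = np.arange(N + 1)[None, :]
    wp = w[:, 1:]
    wsum = max(float(wp.sum()), 1e-12)
    released = max(float((wp * m_vals[:, 1:]).sum()), 1e-12)
    q_new = float(np.nansum(wp * m1[:, 1:])) / released
    a = q_new * m_vals[:, 1:]
    m2 = m1[:, 1:] - 2.0 * a + a * a * minv[:, 1:]
    var = q_new * float(np.nansum(wp * m2)) / wsum
    sq_new = math.sqrt(max(var, _SIGMA_Q_FLOOR**2))
    return q_new, sq_new


def _emission_Q(x, r, w, N, sigma_n) -> float:
    q, sq = math.exp(x[0]), math.exp(x[1])
    E = emission_matrix(r, N, q, sq, sigma_n)
    logE = np.log(np.clip(E[:, 1:], 1e-300, None))
    return float((w[:, 1:] * logE).sum())


def m_step(
    stats: SufficientStats,
    dataset: ResponseDataset,
    params_old: SynapticParameters,
    safe: bool = True,
) -> SynapticParameters:
    """Solve the re-estimation equations given E-step expectations.

    ``N`` and ``sigma_n`` are left unchanged.  With ``safe=True`` (the
    public default) the noisy quantal block solves the implicit
    simultaneous equations exactly and every block is verified to not
    decrease its contribution to the auxiliary function, with a direct
    bounded maximization as fallback.  With ``safe=False`` the EM driver's
    fast path is taken: the quantal block uses the closed-form
    expanded-data ascent step (same fixed points, one quadrature pass) and
    verification is skipped — the driver re-runs the safe path whenever
    the log-likelihood would dip.
    """
    N = stats.N
    sigma_n = params_old.sigma_n
    r = stats.responses
    w = stats.released_weights
    m_vals = np.arange(N + 1)[None, :]
    w_pos = w[:, 1:]
    wm_sum = float(w_pos.sum())
    exp_released = float((w * m_vals).sum())

    # --- quantal block (q, sigma_q) ---
    if sigma_n == 0.0:
        # failures contribute R = 0 exactly, so summing all responses is safe
        q_new = float(r.sum()) / max(exp_released, 1e-12)
        pos = r > 0
        num = (w_pos[pos] * (r[pos, None] - q_new * m_vals[:, 1:]) ** 2 / r[pos, None]).sum()
        sq_new = math.sqrt(max(q_new * num / max(wm_sum, 1e-12), _SIGMA_Q_FLOOR**2))
    elif not safe:
        q_new, sq_new = _quantal_update_fast(r, w, N, sigma_n, params_old)
    else:
        x0 = np.log([params_old.q, max(params_old.sigma_q, _SIGMA_Q_FLOOR)])
        sol = optimize.root(
            _emission_equations, x0, args=(r, w, wm_sum, N, sigma_n), method="hybr",
            options={"xtol": 1e-10},
        )
        x_new = sol.x if sol.success else x0
        if (not sol.success) or (
            _emission_Q(x_new, r, w, N, sigma_n)
            < _emission_Q(x0, r, w, N, sigma_n) - 1e-9
        ):
            res = optimize.minimize(
                lambda x: -_emission_Q(x, r, w, N, sigma_n), x0, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400},
            )
            x_new = res.x if -res.fun >= _emission_Q(x0, r, w, N, sigma_n) else x0
        q_new, sq_new = math.exp(x_new[0]), max(math.exp(x_new[1]), _SIGMA_Q_FLOOR)

    # --- docking block (tau_D) ---
    tau_D_new = params_old.tau_D
    if any(g.intervals.size > 0 for g in stats.groups):
        grid = np.geomspace(_TAU_LO, _TAU_HI, 40)
        vals = np.array([_docking_score(t, stats.groups, N) for t in grid])
        # a maximum of Q sits where the score crosses + -> - (dl/dtau_D < 0)
        brackets = np.nonzero((vals[:-1] > 0) & (vals[1:] < 0))[0]
        cands = []
        for i in brackets:
            cands.append(optimize.brentq(
                _docking_score, grid[i], grid[i + 1], args=(stats.groups, N),
                xtol=1e-12, rtol=1e-12,
            ))
        if not cands:
            # score never brackets: polish the best grid point
            j = int(np.argmax([_docking_Q(t, stats.groups, N) for t in grid]))
            lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, grid.size - 1)]
            res = optimize.minimize_scalar(
                lambda lt: -_docking_Q(math.exp(lt), stats.groups, N),
                bounds=(math.log(lo), math.log(hi)), method="bounded",
                options={"xatol": 1e-10},
            )
            cands.append(math.exp(res.x))
        tau_D_new = max(cands, key=lambda t: _docking_Q(t, stats.groups, N))
        old_t = min(max(params_old.tau_D, _TAU_LO), _TAU_HI)
        if _docking_Q(tau_D_new, stats.groups, N) < _docking_Q(old_t, stats.groups, N):
            tau_D_new = old_t

    # --- release block (U, tau_F) ---
    U_old = min(max(params_old.U, 1e-6), 1.0 - 1e-6)
    tF_old = min(max(params_old.tau_F, _TAU_LO), _TAU_HI)
    z0 = np.array([math.log(U_old / (1.0 - U_old)), math.log(tF_old)])
    sol = optimize.root(_release_scores, z0, args=(stats.groups,), method="hybr",
                        options={"xtol": 1e-10})
    z_new = sol.x if sol.success and np.all(np.isfinite(sol.x)) else z0
    z_new[0] = np.clip(z_new[0], -13.8, 13.8)
    z_new[1] = np.clip(z_new[1], math.log(_TAU_LO), math.log(_TAU_HI))
    if (not sol.success) or (
        safe and _release_Q(z_new, stats.groups) < _release_Q(z0, stats.groups) - 1e-9
    ):
        res = optimize.minimize(
            lambda z: -_release_Q(z, stats.groups), z0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 400},
        )
        cand = res.x
        cand[0] = np.clip(cand[0], -13.8, 13.8)
        cand[1] = np.clip(cand[1], math.log(_TAU_LO), math.log(_TAU_HI))
        z_new = cand if _release_Q(cand, stats.groups) >= _release_Q(z0, stats.groups) else z0
    U_new = 1.0 / (1.0 + math.exp(-z_new[0]))
    tau_F_new = math.exp(z_new[1])

    return SynapticParameters(
        N=N, q=q_new, sigma_q=sq_new, U=U_new, tau_D=tau_D_new,
        tau_F=tau_F_new, sigma_n=sigma_n,
    )


# ---------------------------------------------------------------------------
# EM driver

def _moment_init(dataset: ResponseDataset, N: int, sigma_n: float) -> SynapticParameters:
    """Method-of-moments start from the first responses of every trial."""
    first = np.array([resp[0] for _, resp in dataset.trials])
    mu1 = max(float(first.mean()), 1e-3)
    v1 = float(first.var(ddof=1)) if first.size > 1 else (0.25 * mu1) ** 2
    fano = max((v1 - sigma_n**2) / mu1, 1e-3)
    q0 = max(fano + mu1 / N, 1e-3)
    U0 = float(np.clip(mu1 / (N * q0), 0.02, 0.98))
    isis = np.concatenate([s.intervals for s, _ in dataset.trials if s.M > 1])
    tau0 = float(np.exp(np.mean(np.log(isis)))) if isis.size else 300.0
    return SynapticParameters(
        N=N, q=q0, sigma_q=max(q0 / 3.0, 1e-3), U=U0,
        tau_D=tau0, tau_F=tau0, sigma_n=sigma_n,
    )


def _perturb(params: SynapticParameters, rng: np.random.Generator) -> SynapticParameters:
    f = lambda: float(np.exp(rng.uniform(np.log(1 / 3), np.log(3))))
    return params.replace(
        q=params.q * f(),
        sigma_q=max(params.sigma_q * f(), _SIGMA_Q_FLOOR),
        U=float(np.clip(params.U * f(), 0.02, 0.98)),
        tau_D=max(params.tau_D * f(), _TAU_LO),
        tau_F=max(params.tau_F * f(), _TAU_LO),
    )


def _to_vec(p: SynapticParameters) -> np.ndarray:
    U = min(max(p.U, 1e-9), 1 - 1e-9)
    return np.array([
        math.log(p.q), math.log(max(p.sigma_q, _SIGMA_Q_FLOOR)),
        math.log(U / (1 - U)),
        math.log(min(max(p.tau_D, _TAU_LO), _TAU_HI)),
        math.log(min(max(p.tau_F, _TAU_LO), _TAU_HI)),
    ])


def _from_vec(x: np.ndarray, like: SynapticParameters) -> SynapticParameters:
    return like.replace(
        q=math.exp(x[0]),
        sigma_q=max(math.exp(x[1]), _SIGMA_Q_FLOOR),
        U=1.0 / (1.0 + math.exp(-np.clip(x[2], -13.8, 13.8))),
        tau_D=min(max(math.exp(x[3]), _TAU_LO), _TAU_HI),
        tau_F=min(max(math.exp(x[4]), _TAU_LO), _TAU_HI),
    )


def _run_em(dataset, params0, options: EMOptions) -> EMResult:
    """EM iteration with a safeguarded extrapolation accelerator.

    Every few iterations a step along the recent parameter trajectory (in
    log/logit coordinates) is attempted and kept only if it improves the
    log-likelihood, which shortcuts EM's slow crawl along ridge
    directions without ever breaking monotonicity.
    """
    params = params0
    stats = e_step(dataset, params)
    ll = stats.log_likelihood
    trace = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, options.max_iter + 1):
        new_params = m_step(stats, dataset, params, safe=False)
        new_stats = e_step(dataset, new_params)
        new_ll = new_stats.log_likelihood
        if new_ll < ll - 1e-12:
            # a fast-path root landed badly; redo with verified block updates
            new_params = m_step(stats, dataset, params, safe=True)
            new_stats = e_step(dataset, new_params)
            new_ll = new_stats.log_likelihood
            if new_ll < ll - 1e-12:
                break  # numerically stuck at (local) optimum; keep old params
        if n_iter % 3 == 0 and new_ll > ll:
            # extrapolate along the EM trajectory
            step = _to_vec(new_params) - _to_vec(params)
            for c in (8.0, 3.0, 1.0):
                cand = _from_vec(_to_vec(new_params) + c * step, new_params)
                try:
                    cand_stats = e_step(dataset, cand)
                except FloatingPointError:
                    continue
                if cand_stats.log_likelihood > new_ll:
                    new_params, new_stats = cand, cand_stats
                    new_ll = cand_stats.log_likelihood
                    break
        trace.append(new_ll)
        done = abs(new_ll - ll) <= options.tol * max(abs(ll), 1.0)
        params, stats, ll = new_params, new_stats, new_ll
        if done:
            converged = True
            break
    return EMResult(
        params_hat=params,
        log_likelihood=ll,
        n_iterations=n_iter,
        converged=converged,
        loglik_trace=np.array(trace),
    )


def fit_fixed_N(dataset: ResponseDataset, N: int, options: Optional[EMOptions] = None) -> EMResult:
    """Maximum-likelihood fit of the continuous parameters at fixed ``N``.

    Runs EM from a method-of-moments initialization plus
    ``options.restarts - 1`` log-uniformly perturbed restarts and returns
    the best run.
    """
    options = options or EMOptions()
    if dataset.n_trials == 0:
        raise ValueError("empty dataset")
    sigma_n = options.resolve_sigma_n(dataset)
    base = options.init.replace(N=N, sigma_n=sigma_n) if options.init is not None \
        else _moment_init(dataset, N, sigma_n)
    rng = np.random.default_rng(options.seed)
    # deterministic restarts first: spread the time-constant inits across
    # facilitation- and depression-dominated regimes (the likelihood can
    # have distinct local maxima there), then random log-perturbations
    tau_variants = [(4.0, 8.0), (0.25, 8.0), (4.0, 0.25)]
    inits = [base]
    for fD, fF in tau_variants[: max(options.restarts - 1, 0)]:
        inits.append(base.replace(tau_D=base.tau_D * fD, tau_F=base.tau_F * fF))
    while len(inits) < options.restarts:
        inits.append(_perturb(base, rng))
    best: Optional[EMResult] = None
    failures = []
    for p0 in inits:
        try:
            res = _run_em(dataset, p0, options)
        except FloatingPointError as err:
            failures.append(str(err))
            continue
        if best is None or res.log_likelihood > best.log_likelihood:
            best = res
    if best is None:
        raise RuntimeError(f"all EM restarts failed: {failures}")
    return best


def fit(
    dataset: ResponseDataset,
    N_range: Sequence[int] = range(1, 101),
    options: Optional[EMOptions] = None,
    strategy: str = "grid",
    patience: int = 3,
) -> EMResult:
    """Model-order scan: EM per candidate ``N``, argmax of the likelihood.

    ``strategy="grid"`` scans ``N_range`` in ascending order, warm-starting
    each fit from the previous one (with ``q`` rescaled to preserve the
    efficacy ``A = N q``).  ``strategy="climb"`` hill-climbs outward from
    the middle of ``N_range``, stopping after three consecutive declines on
    each side — cheaper on the typically unimodal profile.  Exact ties are
    broken toward smaller ``N``; a maximum at the edge of the scanned range
    is flagged.
    """
    options = options or EMOptions()
    N_list = sorted(set(int(n) for n in N_range))
    if not N_list:
        raise ValueError("empty N range")

    profile: dict[int, EMResult] = {}

    def fit_at(N: int, warm: Optional[SynapticParameters]) -> EMResult:
        opts = EMOptions(**{**options.__dict__})
        if warm is not None:
            # chain along N: previous continuous estimate with q rescaled to
            # preserve the efficacy A = N q; restarts only at the first N
            opts.init = warm.replace(N=N, q=warm.q * warm.N / N)
            opts.restarts = 1
        res = fit_fixed_N(dataset, N, opts)
        profile[N] = res
        return res

    if strategy == "grid":
        warm = None
        for N in N_list:
            res = fit_at(N, warm)
            warm = res.params_hat
    elif strategy == "climb":
        center = N_list[len(N_list) // 2]
        res_c = fit_at(center, None)
        for direction in (+1, -1):
            warm = res_c.params_hat
            best_ll = res_c.log_likelihood
            declines = 0
            i = N_list.index(center)
            while 0 <= i + direction < len(N_list):
                i += direction
                res = fit_at(N_list[i], warm)
                warm = res.params_hat
                if res.log_likelihood > best_ll:
                    best_ll = res.log_likelihood
                    declines = 0
                else:
                    declines += 1
                    if declines >= patience:
                        break
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    scanned = sorted(profile)
    lls = np.array([profile[N].log_likelihood for N in scanned])
    best_N = scanned[int(np.argmax(lls))]     # argmax takes the first (smallest N) on ties
    best = profile[best_N]
    result = EMResult(
        params_hat=best.params_hat,
        log_likelihood=best.log_likelihood,
        n_iterations=best.n_iterations,
        converged=best.converged,
        loglik_trace=best.loglik_trace,
        per_N_profile=[(N, profile[N].log_likelihood, profile[N].params_hat) for N in scanned],
    )
    if best_N in (scanned[0], scanned[-1]) and len(scanned) > 1:
        result.warnings.append(
            f"likelihood maximal at the edge of the scanned range (N={best_N}); "
            "no interior maximum found"
        )
    return result
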