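"""Conventional least-squares fitting of trial-averaged responses.

The baseline method fits the deterministic TM mean responses
``Rbar_k = A u_k x_k`` to the empirical averages, weighted by per-position
response variances.  Only ``(A, U, tau_D, tau_F)`` are identifiable this
way — the efficacy ``A = N q`` cannot be split into quantal parameters.

The module also implements the conditioning analysis of that fit: the
sensitivity matrix ``D`` (derivatives of the fitted parameters with
respect to each average response, evaluated by perturb-and-refit central
differences) and the condition number ``c = ||D|| ||Rbar|| / ||theta||``
(spectral/2-norms).  Values ``c >> 1`` mean the mapping from averages to
parameters is ill posed: tiny noise on the averages produces wildly
different estimates, which the perturbation experiment quantifies
directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy import optimize

from .core import SpikeTrain, SynapticParameters, mean_response_sequence

__all__ = [
    "LSParams",
    "LSFResult",
    "ls_mean_responses",
    "lsf_fit",
    "sensitivity_matrix",
    "condition_number",
    "perturbation_range",
]

_TAU_LO, _TAU_HI = 1e-2, 1e7
LS_PARAM_NAMES = ("A", "U", "tau_D", "tau_F")


@dataclass(frozen=True)
class LSParams:
    """The four parameters resolvable by least squares."""

    A: float       # absolute efficacy N*q, mV
    U: float
    tau_D: float   # ms
    tau_F: float   # ms

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.U, self.tau_D, self.tau_F])

    def to_dict(self) -> Dict[str, float]:
        return dict(zip(LS_PARAM_NAMES, self.as_array()))


@dataclass
class LSFResult:
    params_ls: LSParams
    residual: float                 # weighted SSE at the optimum
    weights: np.ndarray             # per-position variances s_i^2
    condition_number: Optional[float] = None


def ls_mean_responses(p: LSParams, spikes: SpikeTrain) -> np.ndarray:
    """Deterministic mean responses ``A u_k x_k`` for LS parameters."""
    proxy = SynapticParameters(
        N=1, q=p.A, sigma_q=0.0, U=p.U, tau_D=p.tau_D, tau_F=p.tau_F
    )
    return mean_response_sequence(proxy, spikes)


def _pack(p: LSParams) -> np.ndarray:
    U = min(max(p.U, 1e-9), 1 - 1e-9)
    return np.array([
        math.log(p.A),
        math.log(U / (1 - U)),
        math.log(min(max(p.tau_D, _TAU_LO), _TAU_HI)),
        math.log(min(max(p.tau_F, _TAU_LO), _TAU_HI)),
    ])


def _unpack(x: np.ndarray) -> LSParams:
    return LSParams(
        A=math.exp(x[0]),
        U=1.0 / (1.0 + math.exp(-x[1])),
        tau_D=math.exp(x[2]),
        tau_F=math.exp(x[3]),
    )


def _residuals(x, avg, sd, spikes):
    return (avg - ls_mean_responses(_unpack(x), spikes)) / sd


def _default_inits(avg: np.ndarray, spikes: SpikeTrain):
    """Deterministic multi-start grid around a crude moment guess."""
    mean_isi = float(spikes.intervals.mean()) if spikes.M > 1 else 300.0
    base = LSParams(A=max(2.0 * avg[0], 1e-3), U=0.5, tau_D=mean_isi, tau_F=mean_isi)
    inits = [base]
    for fA, U0, fD, fF in [
        (1.0, 0.15, 2.0, 0.5),
        (3.0, 0.1, 1.0, 3.0),
        (0.7, 0.7, 0.5, 1.0),
        (2.0, 0.3, 4.0, 4.0),
    ]:
        inits.append(LSParams(base.A * fA, U0, base.tau_D * fD, base.tau_F * fF))
    return inits


def lsf_fit(
    avg_responses,
    weights,
    spikes: SpikeTrain,
    init: Optional[LSParams] = None,
    multi_start: bool = True,
) -> LSFResult:
    """Weighted least-squares fit of ``(A, U, tau_D, tau_F)`` to averages.

    ``weights`` are the per-position response variances ``s_i^2`` (pass
    all-ones for an unweighted/ordinary fit).  Bound constraints are
    enforced through log/logit transforms; several deterministic starts
    guard against local minima unless a warm ``init`` is given with
    ``multi_start=False``.
    """
    avg = np.asarray(avg_responses, dtype=float)
    wvar = np.asarray(weights, dtype=float)
    if avg.shape != (spikes.M,) or wvar.shape != (spikes.M,):
        raise ValueError("averages/weights must align with spikes")
    if np.any(wvar <= 0):
        raise ValueError("weights (variances) must be > 0")
    sd = np.sqrt(wvar)

    starts = []
    if init is not None:
        starts.append(init)
    if multi_start or not starts:
        starts.extend(_default_inits(avg, spikes))

    best_x, best_cost = None, np.inf
    for p0 in starts:
        try:
            sol = optimize.least_squares(
                _residuals, _pack(p0), args=(avg, sd, spikes),
                method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost, best_x = sol.cost, sol.x
    if best_x is None:
        raise RuntimeError("least-squares optimization failed from every start")
    p_hat = _unpack(best_x)
    res = float(np.sum(_residuals(best_x, avg, sd, spikes) ** 2))
    return LSFResult(params_ls=p_hat, residual=res, weights=wvar)


def sensitivity_matrix(
    params_ls: LSParams,
    spikes: SpikeTrain,
    weights=None,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """4 x M matrix ``D_ij = d theta_LS(i) / d <R>_j`` by perturb-and-refit.

    The averages are taken to be the model means at ``params_ls`` (so the
    fit is self-consistent with zero residual); each position is perturbed
    by ``rel_step`` relatively, refit warm-started at ``params_ls``, and a
    central difference taken.
    """
    avg = ls_mean_responses(params_ls, spikes)
    wvar = np.ones(spikes.M) if weights is None else np.asarray(weights, dtype=float)
    M = spikes.M
    D = np.empty((4, M))
    for j in range(M):
        h = rel_step * abs(avg[j])
        if h == 0:
            raise ValueError(f"zero mean response at position {j}")
        fits = []
        for sgn in (+1.0, -1.0):
            pert = avg.copy()
            pert[j] += sgn * h
            try:
                fit = lsf_fit(pert, wvar, spikes, init=params_ls, multi_start=False)
            except RuntimeError as err:
                raise RuntimeError(f"refit failed at position {j}: {err}") from err
            fits.append(fit.params_ls.as_array())
        D[:, j] = (fits[0] - fits[1]) / (2.0 * h)
    return D


def condition_number(params_ls: LSParams, spikes: SpikeTrain, weights=None) -> float:
    """``c = ||D||_2 * ||Rbar||_2 / ||theta_LS||_2`` of the LS mapping.

    With no ``weights`` the unweighted fit is analyzed, making ``c`` a
    function of the parameters and the protocol alone.
    """
    D = sensitivity_matrix(params_ls, spikes, weights)
    rbar = ls_mean_responses(params_ls, spikes)
    return float(
        np.linalg.norm(D, 2) * np.linalg.norm(rbar) / np.linalg.norm(params_ls.as_array())
    )


def perturbation_range(
    params_ls: LSParams,
    spikes: SpikeTrain,
    noise_rel_sd: float = 0.01,
    n_reps: int = 15,
    seed=None,
) -> Dict[str, float]:
    """Spread of LS estimates under small noise on the true averages.

    Gaussian noise with relative SD ``noise_rel_sd`` is added independently
    to each model-mean response; the fit is repeated ``n_reps`` times and,
    per parameter, the range (max minus min) of relative errors with
    respect to ``params_ls`` is returned.  Ill-conditioned parameter sets
    produce large ranges even at 1% noise.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    avg = ls_mean_responses(params_ls, spikes)
    truth = params_ls.as_array()
    errs = np.empty((n_reps, 4))
    wvar = np.ones(spikes.M)
    for i in range(n_reps):
        noisy = avg * (1.0 + noise_rel_sd * rng.standard_normal(spikes.M))
        fit = lsf_fit(noisy, wvar, spikes, init=params_ls)
        errs[i] = (fit.params_ls.as_array() - truth) / truth
    rng_per_param = errs.max(axis=0) - errs.min(axis=0)
    return dict(zip(LS_PARAM_NAMES, rng_per_param))
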