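"""Estimator diagnostics: bootstrap, predictive checks, shuffle controls.

* :func:`parametric_bootstrap` — simulate-and-refit replicates quantify the
  bias, spread and mutual correlations of the EM estimates for a given
  connection and protocol;
* :func:`leave_one_out_zout` — predictive tail probabilities of held-out
  trials (uniform on [0, 1] when the model is correct), with a
  Kolmogorov-Smirnov uniformity test;
* :func:`shuffle_within_position` — destroys within-trial response
  correlations while preserving every per-position amplitude multiset (the
  information least-squares fitting is limited to);
* :func:`cv_by_position` — coefficient of variation of the responses at
  each train position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats as sp_stats

from .core import SynapticParameters
from .em import EMOptions, fit
from .likelihood import batched_log_likelihood, per_trial_log_likelihoods
from .simulate import ResponseDataset, StimulationProtocol, simulate_dataset, simulate_trial

__all__ = [
    "BootstrapResult",
    "ZOutResult",
    "parametric_bootstrap",
    "leave_one_out_zout",
    "shuffle_within_position",
    "cv_by_position",
    "average_correlations",
]

PARAM_NAMES = ("N", "q", "sigma_q", "U", "tau_D", "tau_F")


@dataclass
class BootstrapResult:
    rel_errors: np.ndarray            # (n_ok, 6) relative errors per replicate
    bias: Dict[str, float]            # mean relative error per parameter
    sd: Dict[str, float]              # SD of relative errors per parameter
    correlations: np.ndarray          # (6, 6) Pearson correlations of estimates
    n_reps: int
    n_failed: int
    seed: Optional[int]
    param_names: tuple = PARAM_NAMES


@dataclass
class ZOutResult:
    z_out: np.ndarray
    ks_statistic: float
    p_value: float
    uniform_rejected: bool            # at significance 0.01
    n_skipped: int = 0


def parametric_bootstrap(
    params: SynapticParameters,
    protocol: StimulationProtocol,
    n_trials: int,
    n_reps: int,
    seed=None,
    options: Optional[EMOptions] = None,
    scan_halfwidth: int = 20,
    full_scan: bool = False,
) -> BootstrapResult:
    """Simulate-and-refit uncertainty quantification for one connection.

    Each replicate simulates ``n_trials`` trials under ``protocol``, then
    re-estimates all six parameters by EM with a model-order scan centred
    on the generating ``N`` (half-width ``scan_halfwidth``, clipped to
    1..100; ``full_scan=True`` scans 1..100).  Relative errors are taken
    with respect to the generating parameters.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    options = options or EMOptions(restarts=2, tol=1e-6, max_iter=300)
    if full_scan:
        N_range: Sequence[int] = range(1, 101)
    else:
        N_range = range(max(1, params.N - scan_halfwidth),
                        min(100, params.N + scan_halfwidth) + 1)
    proto = StimulationProtocol(**{**protocol.to_dict(), "n_trials": n_trials})

    estimates = []
    n_failed = 0
    truth = np.array([getattr(params, p) for p in PARAM_NAMES], dtype=float)
    for _ in range(n_reps):
        sub = int(rng.integers(2**31))
        data = simulate_dataset(params, proto, seed=sub)
        opts = EMOptions(**{**options.__dict__, "sigma_n": params.sigma_n, "seed": sub})
        try:
            res = fit(data, N_range, opts, strategy="climb", patience=2)
        except (RuntimeError, FloatingPointError):
            n_failed += 1
            continue
        p = res.params_hat
        estimates.append([getattr(p, name) for name in PARAM_NAMES])
    est = np.array(estimates, dtype=float)
    rel = (est - truth) / truth
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(est.T)
    return BootstrapResult(
        rel_errors=rel,
        bias={p: float(rel[:, i].mean()) for i, p in enumerate(PARAM_NAMES)},
        sd={p: float(rel[:, i].std(ddof=1)) for i, p in enumerate(PARAM_NAMES)},
        correlations=corr,
        n_reps=n_reps,
        n_failed=n_failed,
        seed=seed,
    )


def average_correlations(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Average correlation matrices Fisher-z-transform-wise.

    Coefficients are arctanh-transformed, averaged across connections, and
    transformed back; the diagonal stays 1.
    """
    z = np.arctanh(np.clip(np.asarray(matrices), -0.999999, 0.999999))
    out = np.tanh(z.mean(axis=0))
    np.fill_diagonal(out, 1.0)
    return out


def leave_one_out_zout(
    dataset: ResponseDataset,
    N_range: Sequence[int],
    options: Optional[EMOptions] = None,
    n_mc: int = 2000,
    seed=None,
    strategy: str = "climb",
) -> ZOutResult:
    """Predictive tail probability of each held-out trial.

    For every trial: refit on the remaining trials, simulate ``n_mc``
    response trains on the held-out trial's spike train, and report the
    fraction with log-likelihood less than or equal to that of the
    held-out trial.  Under a correct model the ``z_out`` values are
    uniform; uniformity is tested by Kolmogorov-Smirnov at p = 0.01.
    """
    if dataset.n_trials < 3:
        raise ValueError("leave-one-out needs at least 3 trials")
    rng = np.random.default_rng(seed)
    options = options or EMOptions(restarts=1, tol=1e-6, max_iter=300)
    z_values = []
    n_skipped = 0
    for i in range(dataset.n_trials):
        rest = dataset.subset([j for j in range(dataset.n_trials) if j != i])
        try:
            res = fit(rest, N_range, options, strategy=strategy)
        except (RuntimeError, FloatingPointError):
            n_skipped += 1
            continue
        p_hat = res.params_hat
        spikes, resp = dataset.trials[i]
        held_ll = per_trial_log_likelihoods(
            ResponseDataset([(spikes, resp)]), p_hat
        )[0]
        sims = np.vstack([
            simulate_trial(p_hat, spikes, rng)[0] for _ in range(n_mc)
        ])
        sim_ll = batched_log_likelihood(sims, spikes, p_hat)
        z_values.append(float(np.mean(sim_ll <= held_ll)))
    z = np.array(z_values)
    ks = sp_stats.kstest(z, "uniform")
    return ZOutResult(
        z_out=z,
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        uniform_rejected=bool(ks.pvalue < 0.01),
        n_skipped=n_skipped,
    )


def shuffle_within_position(dataset: ResponseDataset, seed=None) -> ResponseDataset:
    """Reassign responses across trials independently at each position.

    All trials must share the same spike train; the amplitude multiset at
    every position is preserved exactly, while within-trial correlations
    are destroyed.
    """
    skeleton = dataset.common_spike_train()
    if skeleton is None:
        raise ValueError("shuffling requires trials with identical spike trains")
    rng = np.random.default_rng(seed)
    R = np.vstack([resp for _, resp in dataset.trials])     # (B, M)
    for k in range(R.shape[1]):
        R[:, k] = R[rng.permutation(R.shape[0]), k]
    meta = dict(dataset.metadata)
    meta["shuffled_within_position"] = True
    return ResponseDataset(
        [(spikes, R[i]) for i, (spikes, _) in enumerate(dataset.trials)], meta
    )


def cv_by_position(dataset: ResponseDataset) -> np.ndarray:
    """Coefficient of variation (SD/mean across trials) per train position.

    The final position of the standard protocols is the recovery response.
    Positions with zero mean are returned as NaN.  Requires >= 2 trials
    sharing one spike train.
    """
    if dataset.n_trials < 2:
        raise ValueError("CV needs at least 2 trials")
    if dataset.common_spike_train() is None:
        raise ValueError("CV by position requires a shared spike train")
    R = np.vstack([resp for _, resp in dataset.trials])
    mean = R.mean(axis=0)
    sd = R.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return cv
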