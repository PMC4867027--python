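"""Quantal emission densities ``P(R | m vesicles released)``.

The amplitude produced by ``m >= 1`` released vesicles is inverse-Gaussian
with mean ``m*q`` and variance ``m*sigma_q**2`` (linear quantal summation;
shape parameter ``lambda_m = m**2 q**3 / sigma_q**2``).  With Gaussian
baseline noise of SD ``sigma_n`` the observable density is the convolution

    P(R | m) = int_0^inf  IG(y; m q, lambda_m) * Normal(R - y; 0, sigma_n^2) dy,

and the ``m = 0`` (failure) emission is the pure baseline density.  This
module evaluates that convolution, its derivatives with respect to ``q``
and ``sigma_q`` (used by the score recursions), and the posterior moments
of the latent noiseless amplitude ``y`` that enter the EM re-estimation
equations for the quantal parameters.

Quadrature: the integrand is a product of two unimodal factors.  When the
vesicular density is comfortably wider than the noise
(``sqrt(m)*sigma_q > 2*sigma_n``) Gauss-Hermite nodes in the noise
variable are used — those nodes are shared by every such ``m``, so all
columns evaluate in one vectorized pass.  Otherwise Gauss-Legendre nodes
cover the overlap of the two factors' supports (the inverse-Gaussian
support from its quantile function, the noise support from ``R ± 9
sigma_n``), with enough nodes to resolve the narrower factor.  All nodes
are parameter-smooth, so derivative tables stay consistent with finite
differences of the values; accuracy is checked by normalization tests to
~1e-9.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy import stats

__all__ = ["emission_density", "emission_matrix", "emission_matrix_derivs", "emission_moments"]

_N_GH = 40
_N_GL = 128

_gh_nodes, _gh_weights = hermgauss(_N_GH)
_gh_weights = _gh_weights / np.sqrt(np.pi)

_gl_x, _gl_w = leggauss(_N_GL)
_gl_p = 0.5 * (_gl_x + 1.0)      # nodes on (0, 1)
_gl_w01 = 0.5 * _gl_w            # weights summing to 1

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _accumulate(W, y, mu, q, sigma_q, val_out, out, cols, want_derivs, want_moments):
    """Reduce weighted nodes to the requested integrals for columns ``cols``.

    ``W`` carries quadrature weight times the non-score factor and is zero
    wherever ``y <= 0``; ``y`` and ``mu`` broadcast to ``W``'s shape
    ``(B, nodes, n_cols)``.
    """
    val = W.sum(axis=1)
    val_out[:, cols] = val
    if not (want_derivs or want_moments):
        return
    ysafe = np.where(y > 0, y, 1.0)
    d = y - mu
    if want_derivs:
        sq = d / sigma_q**2 + 1.5 / q * (1.0 - q / sigma_q**2 * d * d / ysafe)
        out["dq"][:, cols] = (W * sq).sum(axis=1)
        ss = -1.0 / sigma_q + q * d * d / (sigma_q**3 * ysafe)
        out["dsq"][:, cols] = (W * ss).sum(axis=1)
    if want_moments:
        safe = np.where(val > 0, val, 1.0)
        m1 = (W * y).sum(axis=1) / safe
        minv = (W / ysafe).sum(axis=1) / safe
        out["m1"][:, cols] = np.where(val > 0, m1, mu[0, 0])
        out["minv"][:, cols] = np.where(val > 0, minv, 1.0 / mu[0, 0])


def _emission_tables(R, N, q, sigma_q, sigma_n, want_derivs=False, want_moments=False):
    """Requested integrals for m = 0..N; each array has shape (len(R), N+1)."""
    if sigma_q <= 0:
        raise ValueError("sigma_q must be > 0 for emission evaluation")
    R = np.atleast_1d(np.asarray(R, dtype=float))
    B = R.size
    out = {}
    val = np.zeros((B, N + 1))
    if want_derivs:
        out["dq"] = np.zeros((B, N + 1))
        out["dsq"] = np.zeros((B, N + 1))
    if want_moments:
        out["m1"] = np.full((B, N + 1), np.nan)
        out["minv"] = np.full((B, N + 1), np.nan)

    # failure column: pure baseline noise (unit point mass at 0 if noiseless)
    if sigma_n > 0:
        val[:, 0] = np.exp(-(R**2) / (2.0 * sigma_n**2)) / (sigma_n * _SQRT2PI)
    else:
        val[:, 0] = (R == 0.0).astype(float)

    ms = np.arange(1, N + 1)
    mu_all = ms * q
    lam_all = ms * ms * q**3 / sigma_q**2

    half_prec = q / (2.0 * sigma_q**2)

    def _ig_block(y, mu, lam):
        # lam/mu^2 == q/sigma_q^2 for every m, so the exponent shares one
        # factor; fold y^(-3/2) into a single exponential over the grid
        pos = y > 0
        ysafe = np.where(pos, y, 1.0)
        logy = np.log(ysafe)                 # shared across the m axis
        d = y - mu
        f = np.exp(-1.5 * logy - half_prec * d * d / ysafe)
        f *= np.sqrt(lam) / _SQRT2PI
        return np.where(pos, f, 0.0)

    if sigma_n == 0.0:
        # point evaluation at y = R for every m
        y = R[:, None, None]                             # (B, 1, 1)
        mu = mu_all[None, None, :]
        lam = lam_all[None, None, :]
        W = np.broadcast_to(_ig_block(y, mu, lam), (B, 1, N)).copy()
        _accumulate(W, np.broadcast_to(y, W.shape), mu, q, sigma_q,
                    val, out, slice(1, None), want_derivs, want_moments)
        out["val"] = val
        return out

    gh_cols = ms[np.sqrt(ms) * sigma_q > 2.0 * sigma_n]
    gl_cols = ms[np.sqrt(ms) * sigma_q <= 2.0 * sigma_n]

    if gh_cols.size:
        # shared Gauss-Hermite grid in the noise variable: y = R - eps
        y = (R[:, None] - np.sqrt(2.0) * sigma_n * _gh_nodes[None, :])[:, :, None]
        mu = (gh_cols * q)[None, None, :]
        lam = (gh_cols**2 * q**3 / sigma_q**2)[None, None, :]
        W = _gh_weights[None, :, None] * _ig_block(y, mu, lam)
        _accumulate(W, np.broadcast_to(y, W.shape), mu, q, sigma_q,
                    val, out, gh_cols, want_derivs, want_moments)

    for m in gl_cols:
        # Gauss-Legendre over the overlap of the two factors' supports;
        # per-response windows so narrow quantal densities stay resolved
        mu_m, lam_m = m * q, m * m * q**3 / sigma_q**2
        sd_m = np.sqrt(m) * sigma_q
        if mu_m / lam_m < 0.04:
            # nearly Gaussian quantal density (CV < 0.2): analytic bounds
            # (the boost quantile solver struggles at extreme shapes)
            ig_lo = max(mu_m - 12.0 * sd_m, 1e-300)
            ig_hi = mu_m + 14.0 * sd_m
        else:
            with warnings.catch_warnings():
                # the boost quantile solver can fail at extreme shapes;
                # fall back to conservative analytic tail bounds
                warnings.simplefilter("ignore")
                ig_lo = float(stats.invgauss.ppf(1e-14, mu_m / lam_m, scale=lam_m))
                ig_hi = float(stats.invgauss.isf(1e-14, mu_m / lam_m, scale=lam_m))
            if not np.isfinite(ig_lo) or ig_lo <= 0:
                ig_lo = max(mu_m - 12.0 * sd_m, 1e-300)
            if not np.isfinite(ig_hi) or ig_hi <= mu_m:
                ig_hi = mu_m + 14.0 * sd_m + 66.0 * mu_m**2 / lam_m
        lo = np.maximum(np.maximum(R - 9.0 * sigma_n, ig_lo), 1e-300)
        hi = np.minimum(R + 9.0 * sigma_n, ig_hi)
        width = np.maximum(hi - lo, 0.0)                     # (B,)
        y = lo[:, None] + width[:, None] * _gl_p[None, :]    # (B, nodes)
        f = _ig_block(y[:, :, None], np.array([[[mu_m]]]), np.array([[[lam_m]]]))[:, :, 0]
        gauss = np.exp(-((R[:, None] - y) ** 2) / (2.0 * sigma_n**2)) / (
            sigma_n * _SQRT2PI
        )
        W = ((_gl_w01[None, :] * width[:, None]) * f * gauss)[:, :, None]
        _accumulate(W, y[:, :, None], np.array([[mu_m]]), q, sigma_q,
                    val, out, [m], want_derivs, want_moments)

    out["val"] = val
    return out


def emission_matrix(responses, N, q, sigma_q, sigma_n):
    """Density ``P(R_j | m)`` for each response (rows) and m = 0..N (cols)."""
    return _emission_tables(responses, N, q, sigma_q, sigma_n)["val"]


def emission_matrix_derivs(responses, N, q, sigma_q, sigma_n):
    """``(val, d/dq, d/dsigma_q)`` arrays of shape (len(responses), N+1)."""
    t = _emission_tables(responses, N, q, sigma_q, sigma_n, want_derivs=True)
    return t["val"], t["dq"], t["dsq"]


def emission_moments(responses, N, q, sigma_q, sigma_n):
    """EM emission-block integrals per (response, m).

    Returns ``(val, m1, minv)`` where ``m1 = E[y | R, m]`` and
    ``minv = E[1/y | R, m]`` are posterior moments of the latent noiseless
    amplitude under the convolution integrand; the quadratic moment
    entering the re-estimation equation for ``sigma_q`` follows from the
    identity ``E[(y - a)^2 / y] = E[y] - 2 a + a^2 E[1/y]``.  Columns for
    ``m = 0`` are NaN (failures carry no information about the quantal
    parameters).
    """
    t = _emission_tables(responses, N, q, sigma_q, sigma_n, want_moments=True)
    return t["val"], t["m1"], t["minv"]


def emission_density(R, s_minus, s_plus, q, sigma_q, sigma_n):
    """Density (per mV) of response ``R`` when sites drop ``s_minus -> s_plus``.

    ``m = s_minus - s_plus`` vesicles are released.  With ``sigma_n = 0``
    and ``m = 0`` the emission is a point mass at 0; its "density" is
    returned as the indicator of ``R == 0`` and is only meaningful inside
    the noiseless simulation path, never for inference on real data.
    """
    if s_plus > s_minus or s_plus < 0:
        raise ValueError("need 0 <= s_plus <= s_minus")
    m = int(s_minus - s_plus)
    out = _emission_tables(np.atleast_1d(R), max(m, 1), q, sigma_q, sigma_n)["val"]
    col = out[:, m]
    return float(col[0]) if np.isscalar(R) or np.ndim(R) == 0 else col
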