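"""From raw postsynaptic voltage traces to response amplitudes.

Overlapping EPSPs ride on each other's decay tails, so peak amplitudes
cannot be read off the raw trace.  The pipeline inverts the passive
membrane filter: with membrane time constant ``tau_m`` the synaptic drive
is ``RI(t) = tau_m dV/dt + V(t)``; in the deconvolved trace the responses
appear as well-separated transients.  Windows centred on the nominal
stimulation times are cropped, re-convolved through the membrane kernel,
and the peak of each re-convolved crop is the response amplitude.  The
baseline noise SD is measured from short pre-onset windows.

Traces with slow drift should be excluded upstream; a linear-drift
detector is provided as a warning aid only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "VoltageTrace",
    "smooth_trace",
    "estimate_membrane_tau",
    "deconvolve",
    "reconvolve",
    "extract_peaks",
    "baseline_noise_variance",
    "detect_drift",
]


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled voltage trace (mV vs ms)."""

    samples: np.ndarray
    dt: float                 # sampling interval, ms
    t0: float = 0.0
    tau_m: Optional[float] = None   # membrane time constant, ms, once estimated

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not np.all(np.isfinite(s)):
            raise ValueError("trace contains non-finite samples")
        object.__setattr__(self, "samples", s)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.samples.size)

    def index_of(self, t: float) -> int:
        return int(round((t - self.t0) / self.dt))


def smooth_trace(trace: VoltageTrace, window_ms: float = 2.0) -> VoltageTrace:
    """Rectangular (boxcar) moving average; edges use a shrinking window."""
    if window_ms < trace.dt:
        raise ValueError("window must be at least one sampling interval")
    w = max(int(round(window_ms / trace.dt)), 1)
    kernel = np.ones(w)
    num = np.convolve(trace.samples, kernel, mode="same")
    den = np.convolve(np.ones_like(trace.samples), kernel, mode="same")
    return VoltageTrace(num / den, trace.dt, trace.t0, trace.tau_m)


def estimate_membrane_tau(
    trace: VoltageTrace, fit_windows: Sequence[Tuple[float, float]]
) -> float:
    """Membrane time constant from exponential fits to falling edges.

    Each window ``(t_start, t_end)`` of the (trial-averaged) trace is fit
    with ``a * exp(-t/tau) + c``; non-decaying windows are skipped and the
    fitted time constants are averaged arithmetically.
    """
    if not fit_windows:
        raise ValueError("need at least one fit window")
    taus = []
    for (t_a, t_b) in fit_windows:
        i_a, i_b = trace.index_of(t_a), trace.index_of(t_b)
        if not (0 <= i_a < i_b <= trace.samples.size):
            continue
        seg = trace.samples[i_a:i_b]
        t = trace.dt * np.arange(seg.size)
        c0 = float(seg.min())
        a0 = float(seg[0] - c0)
        if a0 <= 0:
            continue  # not a falling edge
        try:
            popt, _ = curve_fit(
                lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
                t, seg, p0=(a0, max(t[-1] / 3.0, trace.dt), c0), maxfev=5000,
            )
        except RuntimeError:
            continue
        if popt[1] > 0 and popt[0] > 0:
            taus.append(float(popt[1]))
    if not taus:
        raise ValueError("no usable falling-edge window")
    return float(np.mean(taus))


def deconvolve(trace: VoltageTrace, tau_m: float) -> VoltageTrace:
    """Synaptic drive ``RI = tau_m dV/dt + V`` (central differences)."""
    if tau_m <= 0:
        raise ValueError("tau_m must be > 0")
    dv = np.gradient(trace.samples, trace.dt)
    return VoltageTrace(tau_m * dv + trace.samples, trace.dt, trace.t0, tau_m)


def reconvolve(ri: np.ndarray, dt: float, tau_m: float, v0: Optional[float] = None) -> np.ndarray:
    """Invert :func:`deconvolve`: first-order exponential membrane filter.

    Integrates ``tau_m dV/dt = RI - V`` exactly for piecewise-constant
    drive; ``v0`` defaults to the first drive sample (steady state).
    """
    ri = np.asarray(ri, dtype=float)
    decay = np.exp(-dt / tau_m)
    v = np.empty_like(ri)
    v[0] = ri[0] if v0 is None else v0
    for i in range(ri.size - 1):
        v[i + 1] = ri[i + 1] + (v[i] - ri[i + 1]) * decay
    return v


def extract_peaks(
    trace: VoltageTrace,
    tau_m: float,
    nominal_spike_times: Sequence[float],
    crop_ms: float = 12.0,
    sign: int = +1,
) -> np.ndarray:
    """Response amplitude per stimulation time by crop-and-reconvolve.

    The trace is deconvolved, a ``crop_ms`` window centred on each nominal
    spike time is cut out, re-convolved through the membrane kernel from a
    zero baseline, and the (signed) peak taken.  Overlapping crops are an
    error.  ``sign=-1`` extracts IPSP (negative) peaks.
    """
    times = np.asarray(nominal_spike_times, dtype=float)
    half = crop_ms / 2.0
    overlaps = [
        (i, i + 1) for i in range(times.size - 1) if times[i + 1] - times[i] < crop_ms
    ]
    if overlaps:
        raise ValueError(f"crop windows overlap for spike pairs {overlaps}")
    ri = deconvolve(trace, tau_m)
    amps = np.empty(times.size)
    for j, t in enumerate(times):
        i_a = max(trace.index_of(t - half), 0)
        i_b = min(trace.index_of(t + half) + 1, trace.samples.size)
        if i_a >= i_b:
            raise ValueError(f"crop for spike at {t} ms outside trace")
        v = reconvolve(ri.samples[i_a:i_b], trace.dt, tau_m, v0=0.0)
        amps[j] = sign * np.max(sign * v)
    return amps


def baseline_noise_variance(
    traces: Sequence[VoltageTrace],
    nominal_spike_times: Sequence[float],
    window_ms: float = 1.0,
) -> float:
    """Pooled baseline noise variance (mV^2) from pre-onset windows.

    The variance of each ``window_ms`` segment immediately preceding each
    nominal stimulation time is averaged over all spikes and trials — one
    value per connection, as the inference path expects.
    """
    times = np.asarray(nominal_spike_times, dtype=float)
    variances = []
    for trace in traces:
        for t in times:
            i_b = trace.index_of(t)
            i_a = trace.index_of(t - window_ms)
            if i_a < 0 or i_b > trace.samples.size or i_b - i_a < 2:
                raise ValueError(f"baseline window before {t} ms outside trace")
            variances.append(float(np.var(trace.samples[i_a:i_b])))
    return float(np.mean(variances))


def detect_drift(trace: VoltageTrace, threshold_mv: float = 0.5) -> float:
    """Linear-trend magnitude over the trace (mV end-to-end); warns only."""
    t = trace.times
    slope = np.polyfit(t, trace.samples, 1)[0]
    total = abs(slope * (t[-1] - t[0]))
    if total > threshold_mv:
        warnings.warn(
            f"trace drifts by {total:.2f} mV end-to-end; consider excluding it",
            stacklevel=2,
        )
    return float(total)
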