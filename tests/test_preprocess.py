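import numpy as np
import pytest

from quantalem.preprocess import (
    VoltageTrace,
    baseline_noise_variance,
    deconvolve,
    detect_drift,
    estimate_membrane_tau,
    extract_peaks,
    reconvolve,
    smooth_trace,
)

DT = 0.05  # ms
TAU_M = 20.0  # ms


def _epsp_trace(spike_times, amplitudes, duration, dt=DT, tau_m=TAU_M, noise=0.0, seed=0):
    """Sum of instant-rise exponential-decay EPSPs plus optional noise."""
    t = np.arange(0.0, duration, dt)
    v = np.zeros_like(t)
    for t0, a in zip(spike_times, amplitudes):
        mask = t >= t0
        v[mask] += a * np.exp(-(t[mask] - t0) / tau_m)
    if noise:
        v += noise * np.random.default_rng(seed).standard_normal(t.size)
    return VoltageTrace(v, dt=dt)


class TestSmoothing:
    def test_constant_unchanged(self):
        tr = VoltageTrace(np.full(500, 3.2), dt=DT)
        assert smooth_trace(tr, 2.0).samples == pytest.approx(tr.samples)

    def test_impulse_becomes_unit_boxcar(self):
        x = np.zeros(401)
        x[200] = 1.0
        sm = smooth_trace(VoltageTrace(x, dt=DT), 2.0).samples
        w = int(round(2.0 / DT))
        assert np.count_nonzero(sm) == w
        assert sm.sum() == pytest.approx(1.0)

    def test_noise_variance_reduction(self):
        rng = np.random.default_rng(1)
        tr = VoltageTrace(rng.standard_normal(200000), dt=DT)
        sm = smooth_trace(tr, 2.0)
        assert sm.samples.var() == pytest.approx(DT / 2.0, rel=0.1)

    def test_window_smaller_than_dt_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(VoltageTrace(np.zeros(10), dt=DT), DT / 2)


class TestMembraneTau:
    def test_pure_exponential(self):
        t = np.arange(0, 100, DT)
        tr = VoltageTrace(2.0 * np.exp(-t / 20.0), dt=DT)
        assert estimate_membrane_tau(tr, [(0.0, 80.0)]) == pytest.approx(20.0, rel=1e-4)

    def test_two_windows_averaged(self):
        t = np.arange(0, 100, DT)
        seg1 = 2.0 * np.exp(-t / 18.0)
        seg2 = 1.5 * np.exp(-t / 22.0)
        tr = VoltageTrace(np.concatenate([seg1, seg2]), dt=DT)
        tau = estimate_membrane_tau(tr, [(0.0, 90.0), (100.0, 190.0)])
        assert tau == pytest.approx(20.0, rel=1e-3)

    def test_noisy_recovery_within_five_percent(self):
        t = np.arange(0, 100, DT)
        rng = np.random.default_rng(2)
        v = 2.0 * np.exp(-t / 20.0)
        v += (2.0 / 20.0) * rng.standard_normal(t.size)  # SNR ~ 20 on the peak
        tau = estimate_membrane_tau(VoltageTrace(v, dt=DT), [(0.0, 80.0)])
        assert tau == pytest.approx(20.0, rel=0.05)

    def test_no_usable_window_raises(self):
        tr = VoltageTrace(np.linspace(0, 1, 100), dt=DT)  # rising, not decaying
        with pytest.raises(ValueError):
            estimate_membrane_tau(tr, [(0.0, 4.0)])


class TestDeconvolution:
    def test_constant_voltage_passthrough(self):
        tr = VoltageTrace(np.full(200, 1.7), dt=DT)
        assert deconvolve(tr, TAU_M).samples == pytest.approx(np.full(200, 1.7))

    def test_membrane_decay_nulled(self):
        t = np.arange(0, 60, DT)
        tr = VoltageTrace(np.exp(-t / TAU_M), dt=DT)
        ri = deconvolve(tr, TAU_M).samples
        assert np.max(np.abs(ri[2:-2])) < 1e-4  # interior (edges use one-sided diff)

    def test_overlapping_epsps_separate(self):
        tr = _epsp_trace([10.0, 25.0], [1.0, 1.0], 80.0)
        ri = deconvolve(tr, TAU_M).samples
        t = tr.times
        # drive is concentrated at the rise times and near zero in between
        between = ri[(t > 13) & (t < 22)]
        assert np.max(np.abs(between)) < 0.05 * np.max(ri)

    def test_reconvolve_inverts_deconvolve(self):
        # smooth trace: identity holds to discretization error; an instant
        # EPSP rise is a discontinuity where any difference scheme smears
        t = np.arange(0, 60, DT)
        v = np.exp(-t / 15.0) * np.sin(2 * np.pi * t / 20.0) + 0.3
        tr = VoltageTrace(v, dt=DT)
        ri = deconvolve(tr, TAU_M)
        back = reconvolve(ri.samples, DT, TAU_M, v0=tr.samples[0])
        err = np.abs(back - tr.samples)[2:]
        assert np.max(err) < 0.01 * np.max(np.abs(tr.samples))


class TestPeakExtraction:
    def test_zero_trace_zero_amplitudes(self):
        tr = VoltageTrace(np.zeros(4000), dt=DT)
        amps = extract_peaks(tr, TAU_M, [20.0, 60.0, 100.0])
        assert amps == pytest.approx(np.zeros(3))

    def test_overlapping_epsp_amplitudes_recovered(self):
        true_amps = [0.8, 0.5, 1.2]
        spikes = [20.0, 50.0, 80.0]  # 30 ms apart: tails overlap at tau_m = 20
        tr = _epsp_trace(spikes, true_amps, 140.0)
        amps = extract_peaks(tr, TAU_M, spikes)
        assert amps == pytest.approx(true_amps, rel=0.02)

    def test_overlapping_crops_rejected(self):
        tr = VoltageTrace(np.zeros(2000), dt=DT)
        with pytest.raises(ValueError, match="overlap"):
            extract_peaks(tr, TAU_M, [20.0, 26.0])

    def test_pipeline_on_simulated_responses(self):
        # end-to-end: model responses -> synthetic trace -> recovered peaks
        from quantalem import SpikeTrain, simulate_trial
        from tests.conftest import FACILITATING

        rng = np.random.default_rng(3)
        spikes = SpikeTrain(np.arange(5) * 50.0 + 25.0)
        resp, _ = simulate_trial(FACILITATING.replace(sigma_n=0.0), spikes, rng)
        tr = _epsp_trace(spikes.times, resp, 300.0)
        amps = extract_peaks(tr, TAU_M, spikes.times)
        assert amps == pytest.approx(resp, rel=0.02, abs=1e-4)


class TestBaselineNoise:
    def test_noiseless_zero(self):
        tr = VoltageTrace(np.zeros(4000), dt=DT)
        assert baseline_noise_variance([tr], [50.0, 100.0]) == 0.0

    def test_known_white_noise_variance(self):
        rng = np.random.default_rng(4)
        traces = [
            VoltageTrace(0.05 * rng.standard_normal(4000), dt=DT) for _ in range(40)
        ]
        var = baseline_noise_variance(traces, [50.0, 100.0, 150.0], window_ms=1.0)
        assert var == pytest.approx(0.0025, rel=0.1)

    def test_window_outside_trace_rejected(self):
        tr = VoltageTrace(np.zeros(100), dt=DT)
        with pytest.raises(ValueError):
            baseline_noise_variance([tr], [0.5])


class TestDriftDetector:
    def test_warns_on_linear_drift(self):
        t = np.arange(0, 1000, DT)
        tr = VoltageTrace(0.002 * t, dt=DT)  # 2 mV drift end-to-end
        with pytest.warns(UserWarning, match="drift"):
            total = detect_drift(tr)
        assert total == pytest.approx(2.0, rel=0.01)
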