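"""Semi-automated electrophysiological validation protocols.

Each protocol is a pure analysis of recorded traces plus stimulus
metadata; protocols that need sweeps (rheobase, f-I, dendritic
nonlinearity) take a run callable and orchestrate the simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .simulator import Trace

__all__ = [
    "SpikeTable",
    "input_resistance",
    "membrane_time_constant",
    "detect_spikes",
    "rheobase",
    "f_I_curve",
    "voltage_attenuation",
    "dendritic_nonlinearity",
    "sag_ratio",
]


def _at(trace: Trace, time: float) -> float:
    i = int(np.clip(np.searchsorted(trace.t, time), 0, len(trace.t) - 1))
    return float(trace.values[i])


def _pre(trace: Trace, time: float) -> float:
    """Value at the last sample at-or-before ``time`` but before any
    discontinuity placed exactly at it (the pre-stimulus level)."""
    i = int(np.clip(np.searchsorted(trace.t, time) - 1, 0, len(trace.t) - 1))
    return float(trace.values[i])


def _window(trace: Trace, t0: float, t1: float, inclusive: bool = True) -> np.ndarray:
    i0 = int(np.searchsorted(trace.t, t0))
    i1 = int(np.searchsorted(trace.t, t1, side="right" if inclusive else "left"))
    return trace.values[i0:i1]


def _offset_level(trace: Trace, onset: float, offset: float) -> float:
    """Steady level near the end of the step: mean of its last 5%
    (excluding the offset sample itself, where the step may have ended)."""
    span = offset - onset
    return float(
        np.mean(_window(trace, offset - 0.05 * span, offset, inclusive=False))
    )


def input_resistance(trace: Trace, I_ext: float, onset: float, offset: float) -> float:
    """R_in = (V_offset − V_onset)/I_ext in MΩ (mV/nA)."""
    if I_ext == 0:
        raise ValueError("I_ext must be nonzero")
    v_onset = _pre(trace, onset)
    v_offset = _offset_level(trace, onset, offset)
    return (v_offset - v_onset) / I_ext


def membrane_time_constant(
    trace: Trace, onset: float, offset: float | None = None, skip: float = 1.0
) -> float:
    """Slowest component of a double-exponential fit to the transient.

    Fits ``V(t) = V∞ + a1 e^(−t/τ1) + a2 e^(−t/τ2)`` to the voltage
    after ``onset`` (skipping ``skip`` ms of stimulus-onset
    discontinuity) and returns max(τ1, τ2) in ms.
    """
    t1 = offset if offset is not None else float(trace.t[-1])
    i0 = int(np.searchsorted(trace.t, onset + skip))
    i1 = int(np.searchsorted(trace.t, t1))
    t = trace.t[i0:i1] - trace.t[i0]
    y = trace.values[i0:i1]
    if len(t) < 10:
        raise ValueError("too few samples after onset for a fit")
    v_inf = float(np.mean(y[-max(len(y) // 20, 5):]))
    amp0 = float(y[0] - v_inf)
    if abs(amp0) < 1e-9 or float(np.ptp(y)) < 1e-9:
        raise ValueError("flat trace: no transient to fit")
    # log-linear initialization from the slow tail
    tail = slice(len(t) // 2, None)
    resid = (y[tail] - v_inf) / amp0
    pos = resid > 1e-12
    if pos.sum() > 5:
        coef = np.polyfit(t[tail][pos], np.log(resid[pos]), 1)
        tau_slow0 = -1.0 / coef[0] if coef[0] < 0 else float(t[-1] / 3)
    else:
        tau_slow0 = float(t[-1] / 5)
    tau_slow0 = float(np.clip(tau_slow0, 1e-3, 10 * t[-1]))

    def model(t, v_inf, a1, tau1, a2, tau2):
        return v_inf + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)

    p0 = [v_inf, 0.3 * amp0, tau_slow0 / 5, 0.7 * amp0, tau_slow0]
    try:
        popt, _ = curve_fit(
            model, t, y, p0=p0,
            bounds=(
                [-np.inf, -np.inf, 1e-4, -np.inf, 1e-4],
                [np.inf, np.inf, 100 * t[-1], np.inf, 100 * t[-1]],
            ),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        resid = float(np.sqrt(np.mean((model(t, *p0) - y) ** 2)))
        raise ValueError(
            f"double-exponential fit failed (initial RMSE {resid:.3g} mV)"
        ) from exc
    # on a near-single-exponential transient the second component is
    # unidentifiable: ignore components carrying <5% of the amplitude
    components = [(popt[1], popt[2]), (popt[3], popt[4])]
    total = sum(abs(a) for a, _tau in components)
    real = [tau for a, tau in components if abs(a) >= 0.05 * total]
    return float(max(real))


@dataclass
class SpikeTable:
    """Detected action potentials and their shape statistics."""

    times: np.ndarray        # ms, peak times
    peaks: np.ndarray        # mV, peak voltages
    amplitudes: np.ndarray   # mV, peak − preceding local minimum
    half_widths: np.ndarray  # ms, width at half amplitude
    rate: float              # Hz over the stimulus duration
    isis: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self) -> int:
        return len(self.times)


def detect_spikes(
    trace: Trace,
    threshold: float = 0.0,
    min_isi: float = 1.0,
    stim_duration: float | None = None,
) -> SpikeTable:
    """Peak detection with per-spike amplitude and half-width.

    The amplitude baseline is the preceding local minimum of each spike
    (robust for bursts); half-width is the time between the two
    half-amplitude crossings around the peak, by linear interpolation.
    """
    v = trace.values
    dt = trace.dt
    peaks, _props = find_peaks(v, height=threshold, distance=max(int(min_isi / dt), 1))
    times, pk_vals, amps, widths = [], [], [], []
    prev_peak = 0
    for p in peaks:
        base = float(np.min(v[prev_peak:p])) if p > prev_peak else float(v[0])
        amp = float(v[p]) - base
        half = base + amp / 2.0
        # crossing before the peak
        i = p
        while i > 0 and v[i - 1] > half:
            i -= 1
        if i == 0:
            t_lo = trace.t[0]
        else:
            frac = (half - v[i - 1]) / (v[i] - v[i - 1])
            t_lo = trace.t[i - 1] + frac * dt
        j = p
        while j < len(v) - 1 and v[j + 1] > half:
            j += 1
        if j == len(v) - 1:
            t_hi = trace.t[-1]
        else:
            frac = (v[j] - half) / (v[j] - v[j + 1])
            t_hi = trace.t[j] + frac * dt
        times.append(float(trace.t[p]))
        pk_vals.append(float(v[p]))
        amps.append(amp)
        widths.append(float(t_hi - t_lo))
        prev_peak = p
    times = np.array(times)
    duration = stim_duration if stim_duration else float(trace.t[-1] - trace.t[0])
    rate = len(times) / duration * 1000.0 if duration > 0 else 0.0
    return SpikeTable(
        times=times,
        peaks=np.array(pk_vals),
        amplitudes=np.array(amps),
        half_widths=np.array(widths),
        rate=rate,
        isis=np.diff(times),
    )


def rheobase(
    run_fn,
    lo: float,
    hi: float,
    resolution: float = 0.001,
    threshold: float = 0.0,
) -> float:
    """Minimal step amplitude (nA) eliciting ≥1 spike, by bisection.

    ``run_fn(amplitude) -> Trace``; the bracket [lo, hi] must span the
    threshold (no spikes at lo, ≥1 at hi).
    """

    def spikes(amp: float) -> int:
        return len(detect_spikes(run_fn(amp), threshold=threshold))

    if spikes(lo) > 0:
        raise ValueError(f"bracket low end {lo} nA already spikes")
    if spikes(hi) == 0:
        raise ValueError(f"bracket high end {hi} nA produces no spikes")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if spikes(mid) > 0:
            hi = mid
        else:
            lo = mid
    return hi


def f_I_curve(
    run_fn, amplitudes, stim_duration: float, threshold: float = 0.0
) -> list[tuple[float, float]]:
    """Firing rate (Hz, spikes per stimulus duration) vs step amplitude."""
    out = []
    for amp in amplitudes:
        table = detect_spikes(
            run_fn(amp), threshold=threshold, stim_duration=stim_duration
        )
        out.append((float(amp), table.rate))
    return out


def voltage_attenuation(
    stim_trace: Trace,
    probe_traces: list[Trace],
    distances: list[float],
    onset: float,
    offset: float,
) -> list[tuple[float, float]]:
    """(distance, ΔV_probe/ΔV_stim) per probe for a step stimulus."""
    dv_stim = _offset_level(stim_trace, onset, offset) - _pre(stim_trace, onset)
    out = []
    for tr, d in zip(probe_traces, distances):
        dv = _offset_level(tr, onset, offset) - _pre(tr, onset)
        out.append((float(d), float(dv / dv_stim)))
    return out


def dendritic_nonlinearity(
    run_epsp_fn, unitary_weight: float, multiples
) -> list[tuple[float, float, float]]:
    """Expected vs actual EPSP peak for increasing synaptic weight.

    ``run_epsp_fn(weight) -> peak ΔV (mV)``.  Returns (k, expected,
    actual) with expected(k) = k · unitary peak.
    """
    unitary = run_epsp_fn(unitary_weight)
    out = []
    for k in multiples:
        actual = run_epsp_fn(k * unitary_weight) if k > 0 else 0.0
        out.append((float(k), float(k * unitary), float(actual)))
    return out


def sag_ratio(trace: Trace, onset: float, offset: float) -> float:
    """(V_offset − V_min)/(V_onset − V_min) for a hyperpolarizing step."""
    v_onset = _pre(trace, onset)
    step = _window(trace, onset, offset)
    v_min = float(np.min(step))
    v_offset = _offset_level(trace, onset, offset)
    b = v_onset - v_min
    if b <= 0:
        raise ValueError("no hyperpolarization: V_onset - V_min is not positive")
    return (v_offset - v_min) / b
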