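"""Extraction of passive and active membrane properties from current-clamp
and on-cell sweeps: input resistance (linear fit of steady-state responses to
hyperpolarizing steps), membrane time constant (exponential fit of the -50 pA
step onset), sag amplitude, spike detection and waveform features, f-I
metrics, rheobase, and spontaneous firing rate.

Criteria the source analysis left unstated are fixed here and documented:
spike threshold is the first dV/dt >= 10 mV/ms crossing (confirmed by the
trace later exceeding -20 mV), steady state is the final 200 ms of a 1 s
step, sag is measured on the -100 pA step, and AHP amplitudes are measured
relative to the spike threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.optimize import curve_fit

from .model import BriefPulseProtocol, CurrentStepProtocol, TimeSeriesSweep, n_samples

__all__ = [
    "IntrinsicFeatures",
    "input_resistance",
    "time_constant",
    "sag_amplitude",
    "detect_spikes",
    "spike_features",
    "f_i_metrics",
    "rheobase",
    "spontaneous_rate",
    "flag_putative_cholinergic",
    "extract_features",
]

DVDT_THRESHOLD = 10.0  # mV/ms spike-onset criterion
SPIKE_CONFIRM_LEVEL = -20.0  # mV the trace must later exceed
REFRACTORY_MERGE = 2.0  # ms
FAHP_WINDOW = 5.0  # ms after the spike peak
SAHP_WINDOW = 70.0  # ms after the spike peak
STEADY_WINDOW = 0.2  # s, final portion of the 1 s step
SAG_PEAK_WINDOW = 0.3  # s from step onset


@dataclass
class IntrinsicFeatures:
    """One row of the membrane-property summary (units in field names)."""

    V_mean: Optional[float] = None  # mV
    R_in: Optional[float] = None  # MOhm
    tau_m: Optional[float] = None  # ms
    sag: Optional[float] = None  # mV
    f_100: Optional[float] = None  # Hz
    f_500: Optional[float] = None  # Hz
    f_max: Optional[float] = None  # Hz
    I_at_fmax: Optional[float] = None  # pA
    spike_height: Optional[float] = None  # mV
    spike_width: Optional[float] = None  # ms
    V_thr: Optional[float] = None  # mV
    fAHP_amp: Optional[float] = None  # mV
    fAHP_delay: Optional[float] = None  # ms
    sAHP_amp: Optional[float] = None  # mV
    sAHP_delay: Optional[float] = None  # ms
    rate_oncell: Optional[float] = None  # Hz
    rate_wholecell: Optional[float] = None  # Hz
    rheobase: Optional[float] = None  # pA
    flags: tuple = ()


def _step_deflection(sweep: TimeSeriesSweep, prot: CurrentStepProtocol) -> float:
    """Steady-state voltage deflection: mean of the final ``STEADY_WINDOW``
    of the step minus the pre-step baseline mean."""
    rate = sweep.sampling_rate
    i_on = n_samples(prot.step_onset, rate)
    i_off = n_samples(prot.step_onset + prot.step_duration, rate)
    n_st = n_samples(STEADY_WINDOW, rate)
    base = float(np.mean(sweep.samples[:i_on]))
    steady = float(np.mean(sweep.samples[i_off - n_st : i_off]))
    return steady - base


def input_resistance(sweeps_by_amplitude: dict, prot: CurrentStepProtocol) -> float:
    """Input resistance (MOhm) from the slope of steady-state deflection
    versus injected current over the hyperpolarizing step family.

    ``sweeps_by_amplitude`` maps step amplitude (pA, negative) to its sweep;
    at least two distinct amplitudes are required.
    """
    amps = sorted(a for a in sweeps_by_amplitude if a < 0)
    if len(amps) < 2:
        raise ValueError("need >= 2 hyperpolarizing amplitudes")
    dv = np.array([_step_deflection(sweeps_by_amplitude[a], prot) for a in amps])
    ii = np.asarray(amps, dtype=float)
    slope = float(np.polyfit(ii, dv, 1)[0])  # mV/pA = GOhm
    r = slope * 1000.0
    if r <= 0 or np.allclose(dv, 0.0):
        warnings.warn("implausible (non-positive or zero) input resistance")
    return r


def time_constant(sweep: TimeSeriesSweep, prot: CurrentStepProtocol) -> float:
    """Membrane time constant (ms) from the onset of the -50 pA step.

    Fits ``V(t) = V_inf + (V0 - V_inf) exp(-t/tau)`` over the first 5*tau_hat
    of the step onset, iterating the window once from an initial fit over
    50 ms. A non-monotonic onset (strong sag) restricts the fit to the first
    50 ms with a warning.
    """
    rate = sweep.sampling_rate
    i_on = n_samples(prot.step_onset, rate)

    def fit(window_s: float) -> float:
        i1 = min(sweep.samples.size, i_on + n_samples(window_s, rate))
        seg = sweep.samples[i_on:i1]
        t = np.arange(seg.size) / rate * 1000.0  # ms
        v0, v_inf0 = seg[0], seg[-1]
        if abs(v_inf0 - v0) < 1e-9:
            raise ValueError("flat response; time constant undefined")
        popt, _ = curve_fit(
            lambda tt, v_inf, dv, tau: v_inf + dv * np.exp(-tt / tau),
            t, seg, p0=(v_inf0, v0 - v_inf0, 10.0), maxfev=5000)
        if popt[2] <= 0:
            raise ValueError("exponential fit failed (non-positive tau)")
        return float(popt[2])

    tau_hat = fit(0.05)
    # non-monotonic onset (sag trough inside the first 300 ms) -> keep 50 ms
    i_end = min(sweep.samples.size, i_on + n_samples(SAG_PEAK_WINDOW, rate))
    seg = sweep.samples[i_on:i_end]
    trough = int(np.argmin(seg))
    if trough < seg.size - n_samples(0.05, rate):
        warnings.warn("non-monotonic step onset; tau fit restricted to 50 ms")
        return tau_hat
    return fit(min(5.0 * tau_hat / 1000.0, 0.25))


def sag_amplitude(sweep: TimeSeriesSweep, step_amplitude: float,
                  prot: CurrentStepProtocol) -> float:
    """Sag (mV, positive): peak hyperpolarization within the first 300 ms of
    the step minus the steady-state level over the final 200 ms."""
    if step_amplitude >= 0:
        raise ValueError("sag is measured on a hyperpolarizing step")
    rate = sweep.sampling_rate
    i_on = n_samples(prot.step_onset, rate)
    i_off = n_samples(prot.step_onset + prot.step_duration, rate)
    i_pk = min(i_off, i_on + n_samples(SAG_PEAK_WINDOW, rate))
    n_st = n_samples(STEADY_WINDOW, rate)
    peak = float(np.min(sweep.samples[i_on:i_pk]))
    steady = float(np.mean(sweep.samples[i_off - n_st : i_off]))
    return steady - peak


def detect_spikes(sweep: TimeSeriesSweep) -> np.ndarray:
    """Spike peak times (s, relative to sweep start).

    Onset where dV/dt first exceeds 10 mV/ms with the voltage subsequently
    exceeding -20 mV; the spike time is the local maximum after onset;
    crossings within a 2 ms merge window count as one spike.
    """
    v = sweep.samples
    rate = sweep.sampling_rate
    dvdt = np.diff(v) * rate / 1000.0  # mV/ms
    onsets = np.nonzero((dvdt[1:] >= DVDT_THRESHOLD) & (dvdt[:-1] < DVDT_THRESHOLD))[0] + 1
    merge = n_samples(REFRACTORY_MERGE / 1000.0, rate)
    peaks = []
    last_peak = -merge - 1
    for i_on in onsets:
        if peaks and i_on <= last_peak + merge:
            continue
        j = i_on
        while j + 1 < v.size and v[j + 1] >= v[j]:
            j += 1
        if v[j] < SPIKE_CONFIRM_LEVEL:
            continue
        if peaks and j == last_peak:
            continue
        peaks.append(j)
        last_peak = j
    return np.asarray(peaks, dtype=float) / rate


def spike_features(sweep: TimeSeriesSweep, spike_time: float,
                   next_spike_time: Optional[float] = None) -> dict:
    """Waveform features of one spike.

    Threshold voltage at the dV/dt criterion crossing; height threshold to
    peak; width at half height; fAHP = most negative voltage within 5 ms of
    the peak; sAHP = most negative voltage in (fAHP delay, 70 ms] after the
    peak. AHP amplitudes are positive mV relative to the threshold voltage;
    delays are from the spike peak. The sAHP window is truncated at the next
    spike onset when the cell fires again inside it (flagged).
    """
    v = sweep.samples
    rate = sweep.sampling_rate
    i_peak = sweep.index_at(spike_time)
    dvdt = np.diff(v) * rate / 1000.0
    i_thr = i_peak
    while i_thr > 0 and dvdt[i_thr - 1] >= DVDT_THRESHOLD:
        i_thr -= 1
    v_thr = float(v[i_thr])
    v_peak = float(v[i_peak])
    height = v_peak - v_thr
    flags = []

    half = v_thr + 0.5 * height
    i = i_peak
    while i > i_thr and v[i - 1] > half:
        i -= 1
    t_up = _cross_time(v, i, half, rate)
    j = i_peak
    while j + 1 < v.size and v[j + 1] > half:
        j += 1
    t_dn = _cross_time(v, j + 1, half, rate) if j + 1 < v.size else j / rate
    width = (t_dn - t_up) * 1000.0

    end_f = min(v.size, i_peak + n_samples(FAHP_WINDOW / 1000.0, rate) + 1)
    end_s = min(v.size, i_peak + n_samples(SAHP_WINDOW / 1000.0, rate) + 1)
    if next_spike_time is not None:
        i_next = sweep.index_at(next_spike_time)
        if i_next < end_s:
            end_s = i_next
            flags.append("sahp_truncated_by_next_spike")
    fahp_amp = fahp_delay = sahp_amp = sahp_delay = None
    if end_f > i_peak + 1:
        seg = v[i_peak + 1 : end_f]
        k = int(np.argmin(seg))
        if seg[k] < v_thr:
            fahp_amp = v_thr - float(seg[k])
            fahp_delay = (k + 1) / rate * 1000.0
    if fahp_amp is None:
        flags.append("no_fahp_below_threshold")
    else:
        start_s = i_peak + 1 + int(fahp_delay / 1000.0 * rate)
        if end_s > start_s + 1:
            seg = v[start_s + 1 : end_s]
            k = int(np.argmin(seg))
            if seg[k] < v_thr:
                sahp_amp = v_thr - float(seg[k])
                sahp_delay = (start_s + 1 + k - i_peak) / rate * 1000.0
        if sahp_amp is None:
            flags.append("no_sahp_below_threshold")
    return dict(V_thr=v_thr, height=height, width=width,
                fAHP_amp=fahp_amp, fAHP_delay=fahp_delay,
                sAHP_amp=sahp_amp, sAHP_delay=sahp_delay, flags=flags)


def _cross_time(v: np.ndarray, k: int, level: float, rate: float) -> float:
    """Interpolated time (s) where v crosses ``level`` between k-1 and k."""
    if k == 0 or v[k] == v[k - 1]:
        return k / rate
    frac = (level - v[k - 1]) / (v[k] - v[k - 1])
    return (k - 1 + frac) / rate


def f_i_metrics(sweeps_by_amplitude: dict, prot: CurrentStepProtocol) -> dict:
    """Firing frequency per step (spike count over the 1 s step), the
    maximum frequency, and the smallest current achieving it."""
    rates = {}
    for amp, sweep in sweeps_by_amplitude.items():
        if amp <= 0:
            continue
        spikes = detect_spikes(sweep)
        in_step = np.sum((spikes >= prot.step_onset)
                         & (spikes < prot.step_onset + prot.step_duration))
        rates[float(amp)] = float(in_step) / prot.step_duration
    if not rates:
        raise ValueError("no depolarizing steps supplied")
    f_max = max(rates.values())
    i_at_fmax = min(a for a, f in rates.items() if f == f_max)
    return dict(f_100=rates.get(100.0), f_500=rates.get(500.0),
                f_max=f_max, I_at_fmax=i_at_fmax, rates=rates)


def rheobase(series: Iterable, prot: BriefPulseProtocol) -> Optional[float]:
    """Smallest grid amplitude evoking at least one spike.

    ``series`` yields ``(amplitude, sweep)`` in ascending order (e.g. the
    lazy generator from the synthetic module); the search stops at the first
    success. Returns None when no amplitude spikes ("no rheobase found").
    """
    for amp, sweep in series:
        if detect_spikes(sweep).size > 0:
            return float(amp)
    return None


def spontaneous_rate(sweep: TimeSeriesSweep, mode: str = "whole_cell"):
    """Spontaneous firing rate (Hz) = spike count / duration.

    Durations under 30 s are flagged as unreliable (the study recorded
    on-cell activity for at least 2 min).
    """
    flags = []
    if sweep.duration < 30.0:
        flags.append("short_recording")
    rate = detect_spikes(sweep).size / sweep.duration
    return float(rate), flags


GP_STN_PRESET_WIDTH = 0.95  # ms, reference spike width for the heuristic


def flag_putative_cholinergic(features: IntrinsicFeatures) -> bool:
    """Advisory heuristic for large, quiet, broad-spiked GP cells (putative
    cholinergic): on-cell rate strictly below 3 Hz and spike width more than
    1.5x the prototypic GP width."""
    if features.rate_oncell is None or features.spike_width is None:
        return False
    return (features.rate_oncell < 3.0
            and features.spike_width > 1.5 * GP_STN_PRESET_WIDTH)


def extract_features(step_sweeps: dict, prot: CurrentStepProtocol,
                     spont_oncell: Optional[TimeSeriesSweep] = None,
                     spont_wholecell: Optional[TimeSeriesSweep] = None,
                     rheobase_series=None,
                     rheobase_prot: Optional[BriefPulseProtocol] = None,
                     sag_step: float = -100.0) -> IntrinsicFeatures:
    """Convenience extraction of the full feature row for one cell."""
    flags = []
    f = IntrinsicFeatures()
    try:
        f.R_in = input_resistance(step_sweeps, prot)
    except (ValueError, RuntimeError):
        flags.append("r_in_failed")
    if -50.0 in step_sweeps:
        try:
            f.tau_m = time_constant(step_sweeps[-50.0], prot)
        except (ValueError, RuntimeError):
            flags.append("tau_failed")
    if sag_step in step_sweeps:
        f.sag = sag_amplitude(step_sweeps[sag_step], sag_step, prot)
    try:
        fi = f_i_metrics(step_sweeps, prot)
        f.f_100, f.f_500 = fi["f_100"], fi["f_500"]
        f.f_max, f.I_at_fmax = fi["f_max"], fi["I_at_fmax"]
    except ValueError:
        flags.append("no_depolarizing_steps")
    # spike features from the weakest depolarizing step that fires
    for amp in sorted(a for a in step_sweeps if a > 0):
        spikes = detect_spikes(step_sweeps[amp])
        if spikes.size:
            nxt = float(spikes[1]) if spikes.size > 1 else None
            sf = spike_features(step_sweeps[amp], float(spikes[0]), nxt)
            f.V_thr, f.spike_height, f.spike_width = sf["V_thr"], sf["height"], sf["width"]
            f.fAHP_amp, f.fAHP_delay = sf["fAHP_amp"], sf["fAHP_delay"]
            f.sAHP_amp, f.sAHP_delay = sf["sAHP_amp"], sf["sAHP_delay"]
            break
    if spont_oncell is not None:
        f.rate_oncell, fl = spontaneous_rate(spont_oncell, "on_cell")
        flags += fl
        f.V_mean = None
    if spont_wholecell is not None:
        f.rate_wholecell, fl = spontaneous_rate(spont_wholecell, "whole_cell")
        flags += fl
        if f.rate_wholecell == 0:
            f.V_mean = float(np.mean(spont_wholecell.samples))
    if rheobase_series is not None and rheobase_prot is not None:
        f.rheobase = rheobase(rheobase_series, rheobase_prot)
    f.flags = tuple(flags)
    return f
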