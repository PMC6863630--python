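"""Synthetic-data generators with known ground truth.

The generators emulate the study's recordings so that every downstream
analysis stage can be exercised and validated without raw data:

* voltage-clamp trains of light-evoked EPSCs -- an inward, peak-normalized
  difference-of-exponentials kernel per pulse, with latency jitter, Gaussian
  baseline noise, per-pulse short-term-plasticity gains and release failures;
* current-clamp step protocols -- a leaky integrate-and-fire (LIF) membrane
  with a hyperpolarization-activated sag current, fast and slow
  after-hyperpolarization currents, a stamped spike waveform, and an optional
  tonic pacemaker drive;
* cohorts -- Bernoulli innervation per cell with type-dependent connection
  probabilities and log-normal (optionally bimodal) oEPSC amplitudes;
* bouton-count tables -- Poisson ROI counts from a mediolateral density field.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .model import (
    BriefPulseProtocol,
    CellRecord,
    CurrentStepProtocol,
    Dataset,
    LightStimProtocol,
    TimeSeriesSweep,
    DEFAULT_SAMPLING_RATE,
)

__all__ = [
    "SynapseParams",
    "MembraneParams",
    "NoiseModel",
    "AmplitudeDistribution",
    "GroupSpec",
    "CohortConfig",
    "BoutonFieldConfig",
    "membrane_preset",
    "synapse_preset",
    "analytic_rheobase",
    "simulate_vc_train",
    "simulate_vc_trains",
    "simulate_cc_step",
    "simulate_cc_steps",
    "simulate_brief_pulse_series",
    "simulate_spontaneous",
    "iter_cohort_cells",
    "simulate_cohort",
    "generate_bouton_counts",
    "default_cohort_config",
    "default_bouton_config",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class SynapseParams:
    """Ground-truth parameters of a compound optically evoked EPSC.

    ``amplitude`` is the true baseline-to-peak magnitude (pA) of the first
    pulse; per-pulse amplitudes are ``amplitude * plasticity_factors[k]``.
    The kernel is normalized so the configured amplitude is the exact peak.
    """

    amplitude: float = 50.0  # pA, first-pulse peak
    tau_rise: float = 0.8  # ms
    tau_decay: float = 8.0  # ms
    latency_mean: float = 3.0  # ms from light onset to oEPSC onset
    latency_jitter_sd: float = 0.3  # ms
    plasticity_factors: Optional[np.ndarray] = None  # per-pulse gains
    failure_prob: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if np.any(np.asarray(self.amplitude) < 0):
            raise ValueError("amplitude must be >= 0")
        if not (0.0 <= self.failure_prob <= 1.0):
            raise ValueError("failure_prob must be in [0, 1]")
        if self.plasticity_factors is not None:
            self.plasticity_factors = np.asarray(self.plasticity_factors, dtype=float)

    def factors(self, n_pulses: int) -> np.ndarray:
        if self.plasticity_factors is None:
            return np.ones(n_pulses)
        f = np.ones(n_pulses)
        m = min(n_pulses, self.plasticity_factors.size)
        f[:m] = self.plasticity_factors[:m]
        return f

    def kernel_peak_time(self) -> float:
        """Time to peak (ms) of the difference-of-exponentials kernel."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    def kernel(self, t_ms: np.ndarray) -> np.ndarray:
        """Peak-normalized kernel (unit peak) evaluated at times in ms."""
        tr, td = self.tau_rise, self.tau_decay
        tp = self.kernel_peak_time()
        gmax = math.exp(-tp / td) - math.exp(-tp / tr)
        t = np.maximum(t_ms, 0.0)
        g = (np.exp(-t / td) - np.exp(-t / tr)) / gmax
        return np.where(t_ms >= 0.0, g, 0.0)


@dataclass
class MembraneParams:
    """Ground truth of a LIF cell with sag and after-currents.

    ``R_in`` is the leak (passive) input resistance and ``tau_m`` the leak
    time constant; when the sag current is enabled the steady-state chord
    resistance seen by hyperpolarizing steps is ``R_in / (1 + g_sag*R_in)``
    (the preset factory calibrates ``R_in`` so the chord value matches the
    study's linear-fit estimate).
    """

    R_in: float = 232.0  # MOhm (leak)
    tau_m: float = 13.0  # ms (leak)
    E_rest: float = -46.6  # mV
    V_thr: float = -37.6  # mV
    V_reset: float = -58.7  # mV
    pacemaker_current: float = 0.0  # pA tonic drive
    sag_strength: float = 0.0  # nS of the slow hyperpolarization-activated current
    sag_tau: float = 400.0  # ms activation time constant
    fahp_amp: float = 0.0  # pA peak of the fast after-current (alpha kernel)
    fahp_tau: float = 1.0  # ms (alpha peak time)
    sahp_amp: float = 0.0  # pA peak of the slow after-current
    sahp_tau: float = 10.0  # ms
    spike_height: float = 74.0  # mV threshold-to-peak
    spike_width: float = 0.95  # ms at half height

    def __post_init__(self) -> None:
        if self.R_in <= 0 or self.tau_m <= 0:
            raise ValueError("R_in and tau_m must be positive")
        if not self.V_thr > self.V_reset:
            raise ValueError("V_thr must exceed V_reset")
        if self.spike_width <= 0 or self.spike_height <= 0:
            raise ValueError("spike waveform must have positive height and width")

    def passive(self) -> "MembraneParams":
        """Copy with all active mechanisms disabled (pure RC membrane)."""
        return replace(self, pacemaker_current=0.0, sag_strength=0.0,
                       fahp_amp=0.0, sahp_amp=0.0)

    def silenced(self) -> "MembraneParams":
        """Copy with the tonic pacemaker drive offset to zero, emulating a
        recording held at rest for passive-property protocols."""
        return replace(self, pacemaker_current=0.0)

    @property
    def chord_resistance(self) -> float:
        """Steady-state resistance seen by hyperpolarizing steps (MOhm)."""
        g = self.sag_strength * 1e-3  # nS -> uS = 1/MOhm
        return self.R_in / (1.0 + g * self.R_in)


@dataclass
class NoiseModel:
    """Additive observation noise: i.i.d. Gaussian plus optional linear drift."""

    gaussian_sd: float = 0.0  # pA (VC) or mV (CC)
    drift_slope: float = 0.0  # units per second

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")

    def apply(self, samples: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
        out = samples
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=samples.size)
        if self.drift_slope != 0.0:
            out = out + self.drift_slope * np.arange(samples.size) / rate
        return out


# ---------------------------------------------------------------------------
# presets

_TABLE_TARGETS = {
    # chord R_in (MOhm), tau_m (ms), V_mean (mV), V_thr (mV), sag (mV at -100 pA),
    # spike height (mV), width (ms), on-cell rate (Hz)
    "GP_STN": dict(r_chord=232.35, tau=12.94, e_rest=-46.63, v_thr=-37.57,
                   sag_mv=7.23, height=74.06, width=0.95, rate=20.79,
                   reset_depth=21.16, fahp=(100.0, 1.0), sahp=(60.0, 10.0)),
    "GP_CPu": dict(r_chord=329.97, tau=21.92, e_rest=-46.36, v_thr=-37.70,
                   sag_mv=8.71, height=76.55, width=1.19, rate=5.47,
                   reset_depth=18.09, fahp=(60.0, 1.5), sahp=(120.0, 40.0)),
    # MSN/STN values from the printed cohort summaries; time constants and
    # AHP shapes are plausible choices (not printed) and are documented.
    "MSN": dict(r_chord=79.17, tau=10.0, e_rest=-73.45, v_thr=-51.8,
                sag_mv=0.0, height=80.0, width=1.1, rate=0.0,
                reset_depth=18.0, fahp=(80.0, 1.0), sahp=(30.0, 12.0)),
    "STN": dict(r_chord=253.14, tau=13.0, e_rest=-45.43, v_thr=-41.0,
                sag_mv=3.0, height=70.0, width=0.8, rate=10.0,
                reset_depth=15.0, fahp=(90.0, 1.0), sahp=(50.0, 8.0)),
}

SAG_REFERENCE_STEP = -100.0  # pA; sag calibration step


def _preset_uncalibrated(name: str) -> MembraneParams:
    t = _TABLE_TARGETS[name]
    r_chord = t["r_chord"]
    sag_mv = t["sag_mv"]
    # Full sag at the -100 pA reference step equals |I| * (R_leak - R_chord);
    # solve for the leak resistance and the linear sag conductance.
    r_leak = r_chord + sag_mv / (abs(SAG_REFERENCE_STEP) * 1e-3)
    if sag_mv > 0:
        g_sag_us = 1.0 / r_chord - 1.0 / r_leak  # uS
        sag_strength = g_sag_us * 1e3  # nS
    else:
        sag_strength = 0.0
    v_reset = t["v_thr"] - t["reset_depth"]
    return MembraneParams(
        R_in=r_leak,
        tau_m=t["tau"],
        E_rest=t["e_rest"],
        V_thr=t["v_thr"],
        V_reset=v_reset,
        pacemaker_current=0.0,
        sag_strength=sag_strength,
        fahp_amp=t["fahp"][0],
        fahp_tau=t["fahp"][1],
        sahp_amp=t["sahp"][0],
        sahp_tau=t["sahp"][1],
        spike_height=t["height"],
        spike_width=t["width"],
    )


@lru_cache(maxsize=None)
def membrane_preset(name: str, with_pacemaker: bool = True) -> MembraneParams:
    """Membrane-parameter preset for a cell type.

    Presets are calibrated so the study's estimators recover the published
    phenotype: the chord resistance equals the published input resistance,
    the sag current yields the published sag amplitude at the -100 pA step,
    and (when ``with_pacemaker``) the tonic drive is tuned by bisection to
    the published spontaneous rate.
    """
    mp = _preset_uncalibrated(name)
    rate = _TABLE_TARGETS[name]["rate"]
    if with_pacemaker and rate > 0:
        mp = replace(mp, pacemaker_current=_calibrate_pacemaker(mp, rate))
    return mp


def synapse_preset(latency_mean: float = 3.0) -> SynapseParams:
    """Default monosynaptic oEPSC kinetics (non-published, documented
    order-of-magnitude choices: 0.8/8 ms rise/decay, 3 +/- 0.3 ms latency)."""
    return SynapseParams(latency_mean=latency_mean)


# ---------------------------------------------------------------------------
# LIF core


def _integrate_lif(
    mp: MembraneParams,
    i_inj: np.ndarray,
    rate: float = DEFAULT_SAMPLING_RATE,
    v0: Optional[float] = None,
):
    """Exponential-Euler integration of the LIF membrane.

    Returns (v, spike_peak_indices). ``i_inj`` is the injected current per
    sample in pA (the pacemaker drive is added internally).
    """
    dt = 1000.0 / rate  # ms
    if dt > mp.tau_m / 10.0:
        warnings.warn("integration step exceeds tau_m/10; accuracy degraded")
    n = i_inj.size
    v = np.empty(n)
    v[0] = mp.E_rest if v0 is None else v0
    decay_m = math.exp(-dt / mp.tau_m)
    decay_sag = math.exp(-dt / mp.sag_tau)
    decay_f = math.exp(-dt / mp.fahp_tau)
    decay_s = math.exp(-dt / mp.sahp_tau)
    w = 0.0  # sag activation (mV of hyperpolarization, low-pass filtered)
    xf = yf = xs = ys = 0.0  # after-current alpha-kernel states
    e_const = math.e
    spikes = []
    # spike stamp geometry: rise over `width`, fall over width*(h+D)/h so the
    # half-height width equals the configured spike_width exactly
    n_rise = max(1, int(round(mp.spike_width / dt)))
    d_reset = mp.V_thr - mp.V_reset
    n_fall = max(1, int(round(mp.spike_width * (mp.spike_height + d_reset)
                              / mp.spike_height / dt)))
    peak_v = mp.V_thr + mp.spike_height
    i = 0
    while i < n - 1:
        drive = mp.E_rest - v[i]
        if drive < 0.0:
            drive = 0.0
        w = drive + (w - drive) * decay_sag
        i_ahp = -(mp.fahp_amp * e_const * yf + mp.sahp_amp * e_const * ys)
        xf_new = xf * decay_f
        yf = (yf + dt / mp.fahp_tau * xf) * decay_f
        xf = xf_new
        xs_new = xs * decay_s
        ys = (ys + dt / mp.sahp_tau * xs) * decay_s
        xs = xs_new
        i_total = i_inj[i] + mp.pacemaker_current + mp.sag_strength * w + i_ahp
        v_inf = mp.E_rest + mp.R_in * i_total * 1e-3
        v[i + 1] = v_inf + (v[i] - v_inf) * decay_m
        i += 1
        if v[i] >= mp.V_thr:
            # stamp the spike waveform: linear rise to peak, linear fall to reset
            i_cross = i
            up = min(n, i_cross + n_rise + 1)
            ramp = np.linspace(mp.V_thr, peak_v, n_rise + 1)
            v[i_cross:up] = ramp[: up - i_cross]
            i_peak = i_cross + n_rise
            if i_peak < n:
                spikes.append(i_peak)
            down_end = min(n, i_peak + n_fall + 1)
            if i_peak < n:
                fall = np.linspace(peak_v, mp.V_reset, n_fall + 1)
                v[i_peak:down_end] = fall[: down_end - i_peak]
            i = down_end - 1
            if i <= 0:
                break
            xf += 1.0
            xs += 1.0
    return v, np.asarray(spikes, dtype=int)


# ---------------------------------------------------------------------------
# voltage-clamp oEPSC trains


def simulate_vc_train(
    sp: SynapseParams,
    prot: LightStimProtocol,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    holding: float = -60.0,
) -> TimeSeriesSweep:
    """Simulate one voltage-clamp train of optically evoked EPSCs.

    The trace is zero-baseline plus, for every pulse ``k``, an inward
    (negative) kernel of peak magnitude ``amplitude * plasticity_factors[k]``
    starting ``latency`` ms after the pulse onset. With zero noise and zero
    jitter the configured amplitude is the true peak within discretization.
    """
    rng = np.random.default_rng(seed)
    n = int(round(prot.sweep_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    trace = np.zeros(n)
    factors = sp.factors(prot.pulse_onsets.size)
    if prot.pulse_onsets.size > 1:
        ipi_ms = float(np.min(np.diff(prot.pulse_onsets))) * 1000.0
        if ipi_ms < sp.tau_rise:
            warnings.warn("inter-pulse interval shorter than tau_rise; "
                          "responses superpose heavily")
    for k, onset in enumerate(prot.pulse_onsets):
        latency = sp.latency_mean
        if sp.latency_jitter_sd > 0:
            latency = rng.normal(sp.latency_mean, sp.latency_jitter_sd)
        failed = sp.failure_prob > 0 and rng.random() < sp.failure_prob
        amp = 0.0 if failed else float(np.asarray(sp.amplitude).ravel()[0]) * factors[k]
        if amp == 0.0:
            continue
        start = onset + latency / 1000.0
        i0 = max(0, int(start * sampling_rate))
        i1 = min(n, i0 + int(0.5 * sampling_rate))
        tt = (t[i0:i1] - start) * 1000.0  # ms
        trace[i0:i1] -= amp * sp.kernel(tt)
    if noise is not None:
        trace = noise.apply(trace, sampling_rate, rng)
    return TimeSeriesSweep(trace, sampling_rate, "voltage_clamp", holding=holding)


def simulate_vc_trains(
    sp: SynapseParams,
    prot: LightStimProtocol,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    n_trains: Optional[int] = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> list:
    """Repeat :func:`simulate_vc_train` with independent jitter/noise per train."""
    n_trains = prot.n_trains if n_trains is None else n_trains
    ss = np.random.SeedSequence(entropy=seed)
    child = ss.spawn(n_trains)
    return [
        simulate_vc_train(sp, prot, noise,
                          seed=int(child[k].generate_state(1)[0] % (2**31)),
                          sampling_rate=sampling_rate)
        for k in range(n_trains)
    ]


# ---------------------------------------------------------------------------
# current-clamp protocols


def simulate_cc_step(
    mp: MembraneParams,
    amplitude: float,
    prot: CurrentStepProtocol,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> TimeSeriesSweep:
    """Simulate one current-clamp step sweep (step of ``amplitude`` pA)."""
    rng = np.random.default_rng(seed)
    n = int(round(prot.sweep_duration * sampling_rate))
    i_inj = np.zeros(n)
    i0 = int(round(prot.step_onset * sampling_rate))
    i1 = int(round((prot.step_onset + prot.step_duration) * sampling_rate))
    i_inj[i0:i1] = amplitude
    v, _ = _integrate_lif(mp, i_inj, sampling_rate)
    if noise is not None:
        v = noise.apply(v, sampling_rate, rng)
    return TimeSeriesSweep(v, sampling_rate, "current_clamp", holding=0.0)


def simulate_cc_steps(
    mp: MembraneParams,
    prot: CurrentStepProtocol,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> dict:
    """Simulate the full step family; returns ``{amplitude: sweep}``."""
    out = {}
    ss = np.random.SeedSequence(entropy=seed)
    child = ss.spawn(prot.step_amplitudes.size)
    for k, amp in enumerate(prot.step_amplitudes):
        sub = int(child[k].generate_state(1)[0] % (2**31))
        out[float(amp)] = simulate_cc_step(mp, float(amp), prot, noise, sub, sampling_rate)
    return out


def analytic_rheobase(mp: MembraneParams, prot: BriefPulseProtocol) -> Optional[float]:
    """Closed-form rheobase of the passive membrane on the protocol grid.

    The minimal current for a pulse of duration ``T`` is
    ``(V_thr - E_rest) / (R_in * (1 - exp(-T/tau_m)))``, rounded up to the
    amplitude grid. Returns None if the grid maximum is insufficient.
    """
    if mp.V_thr <= mp.E_rest:
        raise ValueError("V_thr must be above E_rest for a rheobase to exist")
    t_over_tau = prot.pulse_duration / mp.tau_m
    i_min = (mp.V_thr - mp.E_rest) / (mp.R_in * (1.0 - math.exp(-t_over_tau))) * 1e3  # pA
    grid = prot.amplitude_grid
    idx = np.searchsorted(grid, i_min - 1e-9)
    if idx >= grid.size:
        return None
    return float(grid[idx])


def simulate_brief_pulse_series(
    mp: MembraneParams,
    prot: BriefPulseProtocol,
    seed: int = 0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> Iterator[tuple]:
    """Lazily yield ``(amplitude, sweep)`` for the ascending pulse grid.

    Laziness lets the rheobase search stop at the first spiking amplitude
    without simulating the rest of the grid.
    """
    if mp.V_thr <= mp.E_rest:
        raise ValueError("V_thr must be above E_rest")
    n = int(round(prot.sweep_duration * sampling_rate))
    i0 = int(round(prot.pulse_onset * sampling_rate))
    i1 = i0 + int(round(prot.pulse_duration / 1000.0 * sampling_rate))
    for amp in prot.amplitude_grid:
        i_inj = np.zeros(n)
        i_inj[i0:i1] = amp
        v, _ = _integrate_lif(mp, i_inj, sampling_rate)
        yield float(amp), TimeSeriesSweep(v, sampling_rate, "current_clamp", holding=0.0)


def simulate_spontaneous(
    mp: MembraneParams,
    duration: float = 40.0,
    mode: str = "whole_cell",
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> TimeSeriesSweep:
    """Simulate spontaneous activity (no injected current) for ``duration`` s."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    v, _ = _integrate_lif(mp, np.zeros(n), sampling_rate)
    if noise is not None:
        v = noise.apply(v, sampling_rate, rng)
    clamp = "on_cell" if mode == "on_cell" else "current_clamp"
    return TimeSeriesSweep(v, sampling_rate, clamp, holding=0.0)


def _calibrate_pacemaker(mp: MembraneParams, target_hz: float,
                         sampling_rate: float = DEFAULT_SAMPLING_RATE) -> float:
    """Bisection on the tonic drive to hit a target spontaneous rate."""
    horizon = max(2.0, 6.0 / target_hz)
    n = int(round(horizon * sampling_rate))

    def rate(i_pace: float) -> float:
        trial = replace(mp, pacemaker_current=i_pace)
        _, spikes = _integrate_lif(trial, np.zeros(n), sampling_rate)
        if spikes.size < 3:
            return 0.0
        isi = np.diff(spikes[-3:]).mean() / sampling_rate
        return 1.0 / isi

    # minimal suprathreshold drive
    i_thr = (mp.V_thr - mp.E_rest) / mp.chord_resistance * 1e3
    lo, hi = i_thr * 1.001, i_thr * 1.001 + 10.0
    if rate(lo) > target_hz:
        warnings.warn("target rate below the minimal sustainable pacemaker "
                      "rate; using the minimal suprathreshold drive")
        return lo
    while rate(hi) < target_hz:
        hi *= 1.6
        if hi > 1e5:
            raise RuntimeError("pacemaker calibration failed")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if rate(mid) < target_hz:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class AmplitudeDistribution:
    """Mixture of log-normal components; ``components`` is a list of
    ``(weight, median_pA, sigma_log)``."""

    components: list = field(default_factory=lambda: [(1.0, 30.0, 0.7)])

    def __post_init__(self) -> None:
        w = np.asarray([c[0] for c in self.components], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("mixture weights must be non-negative and sum > 0")

    def sample(self, rng: np.random.Generator) -> float:
        w = np.asarray([c[0] for c in self.components], dtype=float)
        k = rng.choice(len(self.components), p=w / w.sum())
        _, median, sigma = self.components[k]
        return float(rng.lognormal(math.log(median), sigma))


@dataclass
class GroupSpec:
    n_cells: int
    innervation_prob: float
    amplitude: AmplitudeDistribution = field(default_factory=AmplitudeDistribution)

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0.0 <= self.innervation_prob <= 1.0):
            raise ValueError("innervation_prob must be in [0, 1]")


# Connection probabilities published for the four (source, class) pairs.
PUBLISHED_INNERVATION = {
    ("M1", "GP_CPu"): 28 / 35,
    ("M1", "GP_STN"): 17 / 51,
    ("M2", "GP_CPu"): 23 / 27,
    ("M2", "GP_STN"): 36 / 75,
}

# Non-published, order-of-magnitude amplitude models per cell class; the
# striatum-projecting class gets a 2-component mixture (its published
# amplitude distribution appeared bimodal, the low mode matching GP_STN).
DEFAULT_AMPLITUDES = {
    "GP_STN": AmplitudeDistribution([(1.0, 30.0, 0.7)]),
    "GP_CPu": AmplitudeDistribution([(0.5, 30.0, 0.7), (0.5, 120.0, 0.5)]),
    "GP_Bi": AmplitudeDistribution([(1.0, 15.0, 0.7)]),
    "MSN": AmplitudeDistribution([(1.0, 250.0, 0.5)]),
    "STN": AmplitudeDistribution([(1.0, 40.0, 0.7)]),
}


@dataclass
class CohortConfig:
    """Design of a simulated optogenetic mapping cohort."""

    groups: dict = field(default_factory=dict)  # (source, pclass) -> GroupSpec
    protocol: LightStimProtocol = field(default_factory=LightStimProtocol)
    synapse: SynapseParams = field(default_factory=synapse_preset)
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(gaussian_sd=2.0))
    seed: int = 0


def default_cohort_config(n_cells: Optional[int] = None, seed: int = 0) -> CohortConfig:
    """Cohort with the published connection probabilities for the four
    (motor area, projection class) pairs; ``n_cells`` overrides the published
    per-group sample sizes with a common value."""
    published_n = {("M1", "GP_CPu"): 35, ("M1", "GP_STN"): 51,
                   ("M2", "GP_CPu"): 27, ("M2", "GP_STN"): 75}
    groups = {}
    for key, p in PUBLISHED_INNERVATION.items():
        n = published_n[key] if n_cells is None else n_cells
        groups[key] = GroupSpec(n, p, DEFAULT_AMPLITUDES[key[1]])
    return CohortConfig(groups=groups, seed=seed)


def iter_cohort_cells(cfg: CohortConfig) -> Iterator[CellRecord]:
    """Yield simulated cells one at a time (sweeps included).

    Streaming keeps memory flat for large cohorts; ground-truth innervation
    flags and amplitudes are stored in each cell's metadata.
    """
    root = np.random.SeedSequence(entropy=cfg.seed)
    group_seeds = root.spawn(len(cfg.groups))
    for g_idx, (key, spec) in enumerate(sorted(cfg.groups.items())):
        source, pclass = key
        g_ss = group_seeds[g_idx]
        cell_ss = g_ss.spawn(max(spec.n_cells, 1))
        for c in range(spec.n_cells):
            rng = np.random.default_rng(cell_ss[c])
            innervated = bool(rng.random() < spec.innervation_prob)
            amp = spec.amplitude.sample(rng) if innervated else 0.0
            sp = replace(cfg.synapse, amplitude=amp)
            sweep_seed = int(rng.integers(0, 2**31))
            sweeps = simulate_vc_trains(sp, cfg.protocol, cfg.noise, seed=sweep_seed)
            yield CellRecord(
                cell_id=f"{source}_{pclass}_{c:04d}",
                projection_class=pclass,
                cortical_source=source,
                sweeps={"vc_train": sweeps},
                protocols={"vc_train": cfg.protocol},
                metadata={"innervated": innervated, "amplitude_pA": amp},
            )


def simulate_cohort(cfg: CohortConfig) -> Dataset:
    """Materialize :func:`iter_cohort_cells` into a Dataset (see the streaming
    iterator for cohorts too large to hold in memory)."""
    cells = list(iter_cohort_cells(cfg))
    return Dataset(cells=cells, metadata={"seed": cfg.seed, "synthetic": True})


# ---------------------------------------------------------------------------
# bouton-count fields


@dataclass
class BoutonFieldConfig:
    """Mediolateral bouton-density fields per region (densities in boutons
    per 100x100 um^2) sampled as Poisson ROI counts."""

    density_profiles: dict = field(default_factory=dict)  # region -> [(ml_mm, density)]
    cortical_source: str = "M1"
    n_animals: int = 4
    rois_per_site: int = 1
    roi_width: float = 233.0  # um
    roi_height: float = 173.0  # um
    animal_scale: Optional[np.ndarray] = None  # tracer-efficacy multipliers
    seed: int = 0

    def __post_init__(self) -> None:
        for region, profile in self.density_profiles.items():
            for _, d in profile:
                if d < 0:
                    raise ValueError(f"negative density in {region} profile")
        if self.n_animals < 0 or self.rois_per_site < 1:
            raise ValueError("bad n_animals / rois_per_site")


def default_bouton_config(source: str = "M1", seed: int = 0) -> BoutonFieldConfig:
    """Density fields whose per-animal maxima sit at the magnitudes of the
    published maximum-density table, with broad GP and sharp STN
    mediolateral tuning."""
    ml = [2.4, 2.8, 3.2, 3.6, 4.0]
    if source == "M1":
        gp_peak, st_peak, stn_peak = 224.0, 1083.0, 468.0
    else:
        gp_peak, st_peak, stn_peak = 415.0, 1387.0, 488.0
    shape_gp = [0.5, 0.85, 1.0, 0.8, 0.45]  # broad
    shape_stn = [0.15, 0.5, 1.0, 0.4, 0.1]  # sharp
    shape_st = [0.7, 0.95, 1.0, 0.9, 0.7]
    profiles = {
        "GP": list(zip(ml, [gp_peak * s for s in shape_gp])),
        "CPu": list(zip(ml, [st_peak * s for s in shape_st])),
        "STN": list(zip(ml, [stn_peak * s for s in shape_stn])),
    }
    return BoutonFieldConfig(density_profiles=profiles, cortical_source=source, seed=seed)


def generate_bouton_counts(cfg: BoutonFieldConfig) -> pd.DataFrame:
    """Sample Poisson ROI counts from the density fields.

    Counts are Poisson with mean ``density * roi_area / 10^4 um^2`` scaled by
    the per-animal tracer-efficacy multiplier. Returns a tidy table with one
    row per ROI (columns: animal_id, cortical_source, region, ml_position,
    count, roi_width, roi_height).
    """
    rng = np.random.default_rng(cfg.seed)
    area_factor = cfg.roi_width * cfg.roi_height / 1e4
    scales = (np.ones(cfg.n_animals) if cfg.animal_scale is None
              else np.asarray(cfg.animal_scale, dtype=float))
    rows = []
    for a in range(cfg.n_animals):
        animal = f"{cfg.cortical_source.lower()}_rat{a + 1}"
        for region, profile in cfg.density_profiles.items():
            for ml, density in profile:
                lam = density * area_factor * scales[a]
                counts = rng.poisson(lam, size=cfg.rois_per_site)
                for cnt in counts:
                    rows.append(dict(
                        animal_id=animal, cortical_source=cfg.cortical_source,
                        region=region, ml_position=ml, count=int(cnt),
                        roi_width=cfg.roi_width, roi_height=cfg.roi_height,
                    ))
    return pd.DataFrame(rows)
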