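"""Data model for patch-clamp sweeps, stimulus protocols, and recorded cells.

Conventions used throughout the package:

* voltage clamp -- samples are membrane current in pA, holding potential in mV
  (recordings at -60 mV holding); inward (excitatory) currents are negative.
* current clamp -- samples are membrane potential in mV, injected holding
  current in pA.
* time is in seconds, sampling rate in Hz (20 kHz by default).

All conversions from a time window to a sample count go through
:func:`n_samples` so that rounding policy lives in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DEFAULT_SAMPLING_RATE",
    "CLAMP_MODES",
    "PROJECTION_CLASSES",
    "CORTICAL_SOURCES",
    "n_samples",
    "TimeSeriesSweep",
    "LightStimProtocol",
    "CurrentStepProtocol",
    "BriefPulseProtocol",
    "CellRecord",
    "Dataset",
    "ProtocolError",
    "check_series_resistance",
]

DEFAULT_SAMPLING_RATE = 20_000.0  # Hz

CLAMP_MODES = ("voltage_clamp", "current_clamp", "on_cell")
PROJECTION_CLASSES = (
    "GP_STN",
    "GP_CPu",
    "GP_Bi",
    "MSN",
    "STN",
    "putative_cholinergic",
    "unknown",
)
CORTICAL_SOURCES = ("M1", "M2", "Cg", "LO")
MARKERS = ("PV", "Lhx6", "FoxP2")
MARKER_STATES = ("positive", "negative", "untested")


class ProtocolError(ValueError):
    """A sweep lacks the protocol annotation an analysis step requires."""


def n_samples(duration_s: float, sampling_rate: float = DEFAULT_SAMPLING_RATE) -> int:
    """Convert a duration in seconds to a sample count (round to nearest)."""
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    return int(round(duration_s * sampling_rate))


@dataclass
class TimeSeriesSweep:
    """One uniformly sampled recorded or simulated trace.

    ``samples`` are pA in voltage clamp and mV in current clamp; the clamp
    mode fixes the unit interpretation and must not change after creation.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    clamp_mode: str = "voltage_clamp"
    t0: float = 0.0
    holding: Optional[float] = None  # mV in VC, pA in CC

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")
        if self.clamp_mode not in CLAMP_MODES:
            raise ValueError(f"clamp_mode must be one of {CLAMP_MODES}")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Sample index of absolute time ``t`` (round to nearest)."""
        return n_samples(t - self.t0, self.sampling_rate)


@dataclass
class LightStimProtocol:
    """Timing of an optical stimulation sequence.

    The study protocol is 10 five-millisecond pulses at 10 Hz per train,
    repeated 10-15 times at 1 s inter-train intervals.
    """

    pulse_onsets: np.ndarray = field(default=None)  # s, within one train
    pulse_duration: float = 5.0  # ms
    n_pulses: int = 10
    train_freq: float = 10.0  # Hz
    n_trains: int = 10
    inter_train_interval: float = 1.0  # s
    first_onset: float = 0.1  # s of pre-stimulus baseline before pulse 1

    def __post_init__(self) -> None:
        if self.pulse_onsets is None:
            self.pulse_onsets = self.first_onset + np.arange(self.n_pulses) / self.train_freq
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.pulse_onsets.size == 0:
            raise ValueError("at least one pulse onset required")
        if np.any(np.diff(self.pulse_onsets) <= 0):
            raise ValueError("pulse onsets must be strictly increasing")
        if not (0 < self.train_freq):
            raise ValueError("train_freq must be positive")
        if self.pulse_onsets.size > 1:
            period = 1.0 / self.train_freq
            jitter = np.abs(np.diff(self.pulse_onsets) - period)
            if np.any(jitter > 1.0 / DEFAULT_SAMPLING_RATE + 1e-12):
                raise ValueError("pulse onsets inconsistent with train_freq")

    @property
    def sweep_duration(self) -> float:
        """Duration of one train sweep: onsets plus one inter-pulse period."""
        return float(self.pulse_onsets[-1] + 1.0 / self.train_freq)

    def to_dict(self) -> dict:
        return {
            "type": "light",
            "pulse_onsets": self.pulse_onsets.tolist(),
            "pulse_duration": self.pulse_duration,
            "n_pulses": int(self.n_pulses),
            "train_freq": self.train_freq,
            "n_trains": int(self.n_trains),
            "inter_train_interval": self.inter_train_interval,
            "first_onset": self.first_onset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightStimProtocol":
        d = {k: v for k, v in d.items() if k != "type"}
        d["pulse_onsets"] = np.asarray(d["pulse_onsets"])
        return cls(**d)


@dataclass
class CurrentStepProtocol:
    """One-second current steps with pre/post baselines (current clamp)."""

    step_amplitudes: np.ndarray = field(default=None)  # pA
    step_duration: float = 1.0  # s
    pre_baseline: float = 0.2  # s
    post_baseline: float = 0.3  # s

    def __post_init__(self) -> None:
        if self.step_amplitudes is None:
            dep = np.arange(50.0, 1000.0 + 1, 50.0)
            hyp = -np.arange(20.0, 100.0 + 1, 20.0)
            amps = np.unique(np.concatenate([hyp, [-50.0], dep]))
            self.step_amplitudes = amps
        self.step_amplitudes = np.asarray(self.step_amplitudes, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")
        if self.step_amplitudes.size == 0:
            raise ValueError("at least one step amplitude required")
        if np.unique(self.step_amplitudes).size != self.step_amplitudes.size:
            raise ValueError("step amplitudes must be unique")

    @property
    def step_onset(self) -> float:
        return self.pre_baseline

    @property
    def sweep_duration(self) -> float:
        return self.pre_baseline + self.step_duration + self.post_baseline

    def to_dict(self) -> dict:
        return {
            "type": "current_steps",
            "step_amplitudes": self.step_amplitudes.tolist(),
            "step_duration": self.step_duration,
            "pre_baseline": self.pre_baseline,
            "post_baseline": self.post_baseline,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CurrentStepProtocol":
        d = {k: v for k, v in d.items() if k != "type"}
        d["step_amplitudes"] = np.asarray(d["step_amplitudes"])
        return cls(**d)


@dataclass
class BriefPulseProtocol:
    """Brief (5 ms) depolarizing pulses on an ascending amplitude grid,
    used for rheobase measurement. Grid resolution 5 pA, matching the
    smallest rheobase observed in GP neurons."""

    pulse_duration: float = 5.0  # ms
    amplitude_grid: np.ndarray = field(default=None)  # pA
    pre_baseline: float = 0.1  # s
    post_baseline: float = 0.1  # s

    def __post_init__(self) -> None:
        if self.amplitude_grid is None:
            self.amplitude_grid = np.arange(5.0, 1500.0 + 1, 5.0)
        self.amplitude_grid = np.asarray(self.amplitude_grid, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.amplitude_grid.size == 0:
            raise ValueError("amplitude grid must be non-empty")
        if np.any(self.amplitude_grid <= 0):
            raise ValueError("amplitude grid must be positive")
        if np.any(np.diff(self.amplitude_grid) <= 0):
            raise ValueError("amplitude grid must be strictly increasing")

    @property
    def pulse_onset(self) -> float:
        return self.pre_baseline

    @property
    def sweep_duration(self) -> float:
        return self.pre_baseline + self.pulse_duration / 1000.0 + self.post_baseline

    def to_dict(self) -> dict:
        return {
            "type": "brief_pulse",
            "pulse_duration": self.pulse_duration,
            "amplitude_grid": self.amplitude_grid.tolist(),
            "pre_baseline": self.pre_baseline,
            "post_baseline": self.post_baseline,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BriefPulseProtocol":
        d = {k: v for k, v in d.items() if k != "type"}
        d["amplitude_grid"] = np.asarray(d["amplitude_grid"])
        return cls(**d)


PROTOCOL_TYPES = {
    "light": LightStimProtocol,
    "current_steps": CurrentStepProtocol,
    "brief_pulse": BriefPulseProtocol,
}


def protocol_from_dict(d: dict):
    return PROTOCOL_TYPES[d["type"]].from_dict(d)


@dataclass
class CellRecord:
    """One recorded (or simulated) cell with its sweeps grouped by protocol.

    ``sweeps`` maps a protocol label (e.g. ``"vc_train"``, ``"cc_steps"``)
    to a list of :class:`TimeSeriesSweep`; ``protocols`` maps the same label
    to the protocol object describing the stimulus timing.
    """

    cell_id: str
    projection_class: str = "unknown"
    cortical_source: str = "M1"
    marker_status: dict = field(default_factory=lambda: {m: "untested" for m in MARKERS})
    sweeps: dict = field(default_factory=dict)
    protocols: dict = field(default_factory=dict)
    series_resistance: Optional[float] = None  # MOhm
    location: Optional[tuple] = None  # (x, y) within-slice, mm
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.projection_class not in PROJECTION_CLASSES:
            raise ValueError(f"unknown projection_class {self.projection_class!r}")
        if self.cortical_source not in CORTICAL_SOURCES:
            raise ValueError(f"unknown cortical_source {self.cortical_source!r}")
        for m, s in self.marker_status.items():
            if m not in MARKERS or s not in MARKER_STATES:
                raise ValueError(f"bad marker status {m}={s}")
        for label in self.sweeps:
            if label not in self.protocols:
                raise ValueError(f"sweep group {label!r} has no protocol")


@dataclass
class Dataset:
    """A collection of cells plus free-form provenance metadata (including
    the random seed when the data are synthetic)."""

    cells: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell_ids must be unique")

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, cell_id: str) -> CellRecord:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)


def check_series_resistance(
    sweep: TimeSeriesSweep,
    pulse_onset: float,
    pulse_duration: float = 0.010,
    delta_v: float = -10.0,
    threshold: float = 25.0,
):
    """Estimate access (series) resistance from a brief test voltage pulse.

    A -10 mV, 10 ms pulse evokes a capacitive current transient; the access
    resistance is estimated from the peak of that transient,
    ``Rs = |dV| / |I_peak|``. The recording-quality gate passes only if
    ``Rs`` is strictly less than ``threshold`` (25 MOhm by default).

    Parameters
    ----------
    sweep : voltage-clamp sweep containing the test pulse.
    pulse_onset : absolute time (s) of the pulse start.
    pulse_duration : pulse length in seconds.
    delta_v : command step in mV (must be non-zero).
    threshold : MOhm; pass iff Rs < threshold.

    Returns
    -------
    (rs_mohm, passed)
    """
    if sweep.clamp_mode != "voltage_clamp":
        raise ProtocolError("series-resistance check requires a voltage-clamp sweep")
    if delta_v == 0:
        raise ProtocolError("test pulse amplitude must be non-zero")
    i0 = sweep.index_at(pulse_onset)
    i1 = sweep.index_at(pulse_onset + pulse_duration)
    if not (0 <= i0 < i1 <= sweep.samples.size):
        raise ProtocolError("test pulse window outside the sweep")
    n_base = min(i0, n_samples(0.005, sweep.sampling_rate))
    if n_base < 1:
        raise ProtocolError("no pre-pulse baseline available")
    baseline = float(np.mean(sweep.samples[i0 - n_base : i0]))
    transient = sweep.samples[i0:i1] - baseline
    peak = float(transient[np.argmax(np.abs(transient))])
    if peak == 0:
        raise ProtocolError("no capacitive transient found in the test-pulse window")
    # mV / pA = GOhm; report MOhm
    rs = abs(delta_v) / abs(peak) * 1000.0
    return rs, bool(rs < threshold)
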