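"""Core data containers shared across the pipeline.

Conventions
-----------
* Time is in seconds; frame timestamps mark the frame start; windows are
  half-open ``[start, end)``.
* Fluorescence trace matrices are ``cell x frame`` and carry a processing
  tag ``kind`` that may only advance ``raw -> dff -> z``.
* Tabular data (locomotion bouts, stimulus schedules) are plain
  :class:`pandas.DataFrame` objects with documented, validated columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TRACE_KINDS = ("raw", "dff", "z")

#: required columns of a bout table
BOUT_COLUMNS = ("onset", "offset", "class_label", "distance", "mean_speed", "duration")

#: required columns of a stimulus schedule
STIM_COLUMNS = ("time", "modality", "duration")

#: modality name reserved for the no-response control stimulus
NULL_MODALITY = "null"


class ParameterError(ValueError):
    """Invalid user-supplied parameter."""


@dataclass
class TraceMatrix:
    """Cell x frame fluorescence values with sampling metadata.

    Parameters
    ----------
    values
        ``(n_cells, n_frames)`` array. Arbitrary units for ``kind='raw'``,
        unitless for ``'dff'`` and ``'z'``.
    rate
        Sampling rate in Hz.
    t0
        Time of the first frame, seconds.
    kind
        Processing state: ``'raw'``, ``'dff'`` or ``'z'``.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.rate <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.rate}")
        if self.kind not in TRACE_KINDS:
            raise ParameterError(f"kind must be one of {TRACE_KINDS}, got {self.kind!r}")
        if self.kind != "raw" and not np.all(np.isfinite(self.values)):
            raise ParameterError("processed traces must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame-start timestamps in seconds."""
        return self.t0 + np.arange(self.n_frames) / self.rate

    def time_to_index(self, t: float) -> int:
        """Nearest frame index for time ``t``."""
        return int(round((t - self.t0) * self.rate))

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "TraceMatrix":
        return replace(self, values=values, kind=self.kind if kind is None else kind)

    def to_frame(self) -> pd.DataFrame:
        """Cells as rows, frames as columns."""
        return pd.DataFrame(self.values)


@dataclass
class SpeedTrace:
    """Locomotion speed in cm/s sampled at ``rate`` Hz."""

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.rate}")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("speed trace must be finite")
        if np.any(self.values < 0):
            raise ParameterError("speed cannot be negative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


@dataclass
class GcampKernel:
    """Spike-to-fluorescence impulse response of the calcium reporter.

    A delayed double exponential: zero for ``t < report_delay``, then
    ``A * (exp(-(t-d)/tau_decay) - exp(-(t-d)/tau_rise))`` normalised so one
    spike contributes a peak of ``amplitude_per_spike``.

    The default delay of 0.15 s matches the lag from the onset of a spike
    train to a detectable fluorescence increase measured for GCaMP6s at
    cellular resolution; rise/decay constants are typical of GCaMP6s.
    """

    report_delay: float = 0.15
    tau_rise: float = 0.2
    tau_decay: float = 1.8
    amplitude_per_spike: float = 0.03

    def __post_init__(self) -> None:
        for name in ("report_delay", "tau_rise", "tau_decay", "amplitude_per_spike"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be positive and finite, got {v}")
        if self.tau_decay <= self.tau_rise:
            raise ParameterError("tau_decay must exceed tau_rise")

    @property
    def peak_time(self) -> float:
        """Time from spike to kernel maximum (closed form)."""
        r, d = self.tau_rise, self.tau_decay
        return self.report_delay + np.log(d / r) * r * d / (d - r)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Kernel values at times ``t`` (seconds since the spike)."""
        t = np.asarray(t, dtype=float)
        s = t - self.report_delay
        r, d = self.tau_rise, self.tau_decay
        raw = np.where(s >= 0, np.exp(-np.maximum(s, 0) / d) - np.exp(-np.maximum(s, 0) / r), 0.0)
        s_pk = self.peak_time - self.report_delay
        peak = np.exp(-s_pk / d) - np.exp(-s_pk / r)
        return self.amplitude_per_spike * raw / peak

    def sample(self, rate: float, n_tau: float = 8.0) -> np.ndarray:
        """Kernel sampled at ``rate`` Hz out to ``n_tau`` decay constants."""
        n = int(np.ceil((self.report_delay + n_tau * self.tau_decay) * rate)) + 1
        return self.evaluate(np.arange(n) / rate)


SUBTYPE_LABELS = ("ON", "OFF", "up_down", "down_up", "non_mod")


@dataclass
class SubtypeTemplate:
    """Peri-locomotor firing-rate template for one cell class.

    ``onset_lead`` is the time of the rate change relative to the bout
    onset (negative = leads the movement). ``phase_durations`` gives the
    duration of each phase of a biphasic profile; monophasic templates use
    a single entry meaning "until bout offset" when set to ``None``.
    """

    label: str
    baseline_rate: float
    peak_rate: float
    onset_lead: float = 0.0
    phase_durations: tuple = ()

    def __post_init__(self) -> None:
        if self.label not in SUBTYPE_LABELS:
            raise ParameterError(f"unknown subtype label {self.label!r}")
        if self.baseline_rate < 0 or self.peak_rate < 0:
            raise ParameterError("firing rates must be non-negative")
        if self.label == "non_mod" and self.peak_rate != self.baseline_rate:
            raise ParameterError("non_mod template requires peak_rate == baseline_rate")


@dataclass
class GroundTruth:
    """Everything the synthetic generator knows about a recording."""

    cell_labels: list
    spike_trains: list  # per cell: sorted array of spike times (s)
    true_onsets: np.ndarray  # cell x bout rate-change times (s), NaN where none
    kernel: GcampKernel
    noise_sd: float
    bleach_tau: float
    neuropil_gain: float
    duration: float
    sensory_responsive: pd.DataFrame | None = None  # cell x modality bool
    templates: dict = field(default_factory=dict)


@dataclass
class PeriEventTensor:
    """Cell x event x relative-time values around aligned events."""

    values: np.ndarray  # (n_cells, n_events, n_samples)
    rate: float
    window: tuple  # (start, end) seconds relative to the event
    alignment: str = "bout_onset"
    truncated: np.ndarray | None = None  # per-event flag

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.truncated is None:
            self.truncated = np.zeros(self.values.shape[1], dtype=bool)

    @property
    def rel_times(self) -> np.ndarray:
        """Sample times relative to the event (seconds)."""
        n = self.values.shape[2]
        return self.window[0] + np.arange(n) / self.rate

    def event_mean(self, include_truncated: bool = False) -> np.ndarray:
        """Cell x time average across events (truncated excluded by default)."""
        keep = np.ones(self.values.shape[1], bool) if include_truncated else ~self.truncated
        if not keep.any():
            raise ValueError("no usable (non-truncated) events to average")
        return np.nanmean(self.values[:, keep, :], axis=1)


def make_bout_table(onsets, offsets, class_label="run", distance=None, mean_speed=None) -> pd.DataFrame:
    """Assemble and validate a bout table."""
    onsets = np.asarray(onsets, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    n = onsets.size
    df = pd.DataFrame(
        {
            "onset": onsets,
            "offset": offsets,
            "class_label": [class_label] * n if isinstance(class_label, str) else list(class_label),
            "distance": np.full(n, np.nan) if distance is None else np.asarray(distance, float),
            "mean_speed": np.full(n, np.nan) if mean_speed is None else np.asarray(mean_speed, float),
        }
    )
    df["duration"] = df["offset"] - df["onset"]
    return validate_bouts(df)


def validate_bouts(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("onset", "offset"):
        if col not in df.columns:
            raise ParameterError(f"bout table missing column {col!r}")
    if "duration" not in df.columns:
        df = df.assign(duration=df["offset"] - df["onset"])
    if len(df):
        if not (df["offset"] > df["onset"]).all():
            raise ParameterError("bout offsets must exceed onsets")
        on = df["onset"].to_numpy()
        off = df["offset"].to_numpy()
        order = np.argsort(on)
        if np.any(off[order][:-1] > on[order][1:]):
            raise ParameterError("bouts overlap")
        df = df.iloc[order].reset_index(drop=True)
    return df


def make_stimulus_schedule(times, modalities, durations) -> pd.DataFrame:
    """Assemble and validate a stimulus schedule."""
    df = pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "modality": list(modalities),
            "duration": np.asarray(durations, dtype=float),
        }
    )
    if len(df):
        if not np.all(np.diff(df["time"].to_numpy()) > 0):
            raise ParameterError("stimulus times must be strictly increasing")
        if not (df["duration"] > 0).all():
            raise ParameterError("stimulus durations must be positive")
    return df
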