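"""Core in-memory containers for uniformly sampled physiological channels.

A recording session is a set of synchronously acquired channels (surface EMG
of up to four inspiratory muscles, ECG, airflow, and optionally mouth
pressure), all sharing one sampling rate and timebase. Times throughout the
package are reported in milliseconds relative to the session start (t0 = 0
unless the source file says otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical muscle channel roles. Any subset may be present in a session.
MUSCLES = ("diaphragm_intercostal", "scalene", "parasternal", "sternocleidomastoid")

#: Non-muscle channel roles.
AUX_ROLES = ("ecg", "flow", "pm")


@dataclass
class SampledSignal:
    """A single uniformly sampled channel.

    Parameters
    ----------
    values : ndarray
        Sample values in channel units (µV for EMG, L/s for flow,
        cmH2O for mouth pressure, mV for ECG).
    sampling_rate : float
        Samples per second; must be positive.
    t0 : float
        Session-relative start time in seconds.
    """

    values: np.ndarray
    sampling_rate: float = 1000.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("SampledSignal values must be one-dimensional")
        if self.values.size < 2:
            raise ValueError("SampledSignal needs at least 2 samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SampledSignal values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sampling_rate

    def times_ms(self) -> np.ndarray:
        """Sample times in milliseconds from session start."""
        return (self.t0 + np.arange(self.values.size) / self.sampling_rate) * 1000.0

    def index_to_ms(self, idx: int | np.ndarray) -> float | np.ndarray:
        return (self.t0 + np.asarray(idx) / self.sampling_rate) * 1000.0

    def ms_to_index(self, t_ms: float) -> int:
        """Nearest sample index for a session-relative time in ms."""
        return int(round((t_ms / 1000.0 - self.t0) * self.sampling_rate))

    def copy_with(self, values: np.ndarray) -> "SampledSignal":
        """New signal with the same timebase but different sample values."""
        return SampledSignal(np.asarray(values, dtype=float), self.sampling_rate, self.t0)


@dataclass
class SessionRecording:
    """Named channels of one acquisition session plus free-form metadata.

    Channels are keyed by role: muscle names from :data:`MUSCLES` plus
    ``ecg``, ``flow`` and optionally ``pm``. All channels must share the
    sampling rate, start time, and length.
    """

    channels: dict[str, SampledSignal]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("SessionRecording needs at least one channel")
        if "flow" not in self.channels:
            raise ValueError("SessionRecording requires a flow channel")
        if not self.muscle_names():
            raise ValueError("SessionRecording requires at least one EMG channel")
        lengths = {len(s) for s in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"all channels must have equal length, got {lengths}")
        rates = {s.sampling_rate for s in self.channels.values()}
        t0s = {s.t0 for s in self.channels.values()}
        if len(rates) != 1 or len(t0s) != 1:
            raise ValueError("all channels must share sampling_rate and t0")

    def muscle_names(self) -> list[str]:
        return [m for m in MUSCLES if m in self.channels]

    @property
    def sampling_rate(self) -> float:
        return next(iter(self.channels.values())).sampling_rate

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def __getitem__(self, role: str) -> SampledSignal:
        return self.channels[role]

    def __contains__(self, role: str) -> bool:
        return role in self.channels
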