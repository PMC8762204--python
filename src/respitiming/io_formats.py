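"""Reading and writing delimited-text sessions, event tables, and configs.

Sessions are the text export of the acquisition software: one row per
sample at a fixed rate (1000 Hz by default), tab- or comma-delimited
(auto-detected), optional header lines, optional time column. Channel roles
are declared in a column map rather than guessed from header names, because
channel naming in exports is site-specific.

Event tables are CSVs with one row per (participant, muscle, breath_index,
event_kind, source); missing event times are written as the literal ``NA``,
the same convention a human assessor uses for an undetectable onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signals import AUX_ROLES, MUSCLES, SampledSignal, SessionRecording

__all__ = [
    "SessionFormatError", "ConfigurationError",
    "read_session", "write_session", "read_events", "write_events",
    "AnalysisConfig", "load_config",
]

EVENT_COLUMNS = ["participant", "muscle", "breath_index", "event_kind",
                 "time_ms", "source", "missing"]
_VALID_ROLES = set(MUSCLES) | set(AUX_ROLES) | {"time"}


class SessionFormatError(ValueError):
    """Malformed session or event file."""


class ConfigurationError(ValueError):
    """Invalid column map or config."""


def _detect_delimiter(path: Path, skip_header: int) -> str:
    with open(path) as fh:
        for _ in range(skip_header):
            fh.readline()
        line = fh.readline()
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_session(path: str | Path, column_map: dict[str, int | str],
                 sampling_rate: float = 1000.0, skip_header: int = 0,
                 delimiter: str | None = None,
                 metadata: dict | None = None) -> SessionRecording:
    """Parse a delimited-text multi-channel export into a SessionRecording.

    ``column_map`` assigns each required role (muscle names, ``ecg``,
    ``flow``, optionally ``pm`` and ``time``) to a column name or 0-based
    index. A mapped time column is validated as uniform at ``sampling_rate``
    to one part in 1e6; non-numeric cells and missing columns raise with the
    offending location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    for role in column_map:
        if role not in _VALID_ROLES:
            raise ConfigurationError(f"unknown channel role: {role!r}")
    if "flow" not in column_map:
        raise ConfigurationError("column_map must assign the 'flow' role")
    if not any(m in column_map for m in MUSCLES):
        raise ConfigurationError("column_map must assign at least one EMG role")

    delim = delimiter or _detect_delimiter(path, skip_header)
    by_name = any(isinstance(v, str) for v in column_map.values())
    try:
        df = pd.read_csv(path, sep=delim, skiprows=skip_header,
                         header=0 if by_name else None, engine="c")
    except pd.errors.ParserError as exc:
        raise SessionFormatError(f"cannot parse {path.name}: {exc}") from exc

    t0 = 0.0
    channels: dict[str, SampledSignal] = {}
    for role, col in column_map.items():
        if isinstance(col, str):
            if col not in df.columns:
                raise ConfigurationError(f"column {col!r} (role {role!r}) not in file")
            raw = df[col]
        else:
            if col >= df.shape[1]:
                raise ConfigurationError(f"column index {col} (role {role!r}) out of range")
            raw = df.iloc[:, col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if bad.size:
            raise SessionFormatError(
                f"non-numeric value in column {col!r} at data row {bad[0]}")
        arr = vals.to_numpy(dtype=float)
        if role == "time":
            dt = np.diff(arr)
            expected = 1.0 / sampling_rate
            off = np.flatnonzero(np.abs(dt - expected) > expected * 1e-6)
            if off.size:
                raise SessionFormatError(
                    f"time column not uniform at {sampling_rate} Hz: "
                    f"step {dt[off[0]]:.9g} s at data row {off[0] + 1}")
            t0 = float(arr[0])
        else:
            channels[role] = arr  # type: ignore[assignment]

    out = {role: SampledSignal(arr, sampling_rate, t0) for role, arr in channels.items()}
    return SessionRecording(out, metadata=dict(metadata or {}))


def write_session(recording: SessionRecording, path: str | Path,
                  delimiter: str = "\t", include_time: bool = True,
                  float_format: str = "%.9g") -> None:
    """Write a session as delimited text (one header line, one row/sample).

    Values are written with 6 significant digits, so a write-read round trip
    reproduces samples to <=1e-6 relative error.
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {}
    if include_time:
        first = next(iter(recording.channels.values()))
        cols["time"] = first.t0 + np.arange(recording.n_samples) / recording.sampling_rate
    for role, sig in recording.channels.items():
        cols[role] = sig.values
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False,
                              float_format=float_format)


def write_events(table: pd.DataFrame, path: str | Path) -> None:
    """Write an event table; missing times become the literal ``NA``."""
    _validate_events(table)
    out = table[EVENT_COLUMNS].copy()
    out["time_ms"] = out["time_ms"].map(
        lambda v: "NA" if pd.isna(v) else f"{float(v):.3f}")
    out["missing"] = out["missing"].astype(bool)
    out.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event table; ``NA`` times become NaN with the missing flag set.

    Duplicate (participant, muscle, breath_index, event_kind, source) keys
    raise a format error.
    """
    df = pd.read_csv(path, dtype={"participant": str, "muscle": str,
                                  "event_kind": str, "source": str},
                     na_values=["NA"], keep_default_na=True)
    missing_cols = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SessionFormatError(f"event file missing columns: {missing_cols}")
    df["breath_index"] = df["breath_index"].astype(int)
    df["time_ms"] = pd.to_numeric(df["time_ms"], errors="coerce")
    df["missing"] = df["missing"].astype(bool) | df["time_ms"].isna()
    key = ["participant", "muscle", "breath_index", "event_kind", "source"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df[dup].iloc[0]
        raise SessionFormatError(
            f"duplicate event key: {tuple(first[k] for k in key)}")
    _validate_events(df)
    return df[EVENT_COLUMNS]


def _validate_events(df: pd.DataFrame) -> None:
    missing_cols = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SessionFormatError(f"event table missing columns: {missing_cols}")
    bad_kind = set(df["event_kind"].unique()) - {"onset", "offset"}
    if bad_kind:
        raise SessionFormatError(f"unknown event kinds: {sorted(bad_kind)}")
    present = df[~df["missing"].astype(bool)]
    if (pd.to_numeric(present["time_ms"], errors="coerce") < 0).any():
        raise SessionFormatError("event times must be >= 0 unless flagged missing")


@dataclass
class AnalysisConfig:
    """YAML-backed analysis configuration.

    ``channels`` maps roles to column names/indices of the session file;
    the remaining sections carry keyword overrides for the corresponding
    stage specs (see preprocess.FilterSpec/LmsSpec/EnvelopeSpec,
    breaths.BreathParams, timing.DetectionSpec).
    """

    channels: dict[str, int | str] = field(default_factory=dict)
    sampling_rate: float = 1000.0
    skip_header: int = 0
    delimiter: str | None = None
    ecg_removal_enabled: bool = True
    filter: dict = field(default_factory=dict)
    ecg_removal: dict = field(default_factory=dict)
    envelope: dict = field(default_factory=dict)
    breaths: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML; unknown keys raise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)
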