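"""End-to-end session analysis: channels in, breaths/events/metrics out."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import breaths as br
from . import timing
from .io_formats import AnalysisConfig
from .preprocess import EnvelopeSpec, FilterSpec, LmsSpec, preprocess_emg
from .signals import SessionRecording

__all__ = ["SessionResult", "analyze_session", "events_table_from_result"]


@dataclass
class SessionResult:
    """Tables produced by one full analysis of a session."""

    breaths: pd.DataFrame   # per-breath ventilatory landmarks
    events: pd.DataFrame    # detected onset/offset per muscle x breath
    metrics: pd.DataFrame   # completed timing metrics per muscle x breath
    breath_objs: list
    envelopes: dict


def analyze_session(recording: SessionRecording,
                    config: AnalysisConfig | None = None) -> SessionResult:
    """Run the full pipeline on a recording.

    Stages: breath segmentation from flow (+ pressure onsets when a pm
    channel is present); per-muscle high-pass -> adaptive ECG removal (when
    enabled and an ECG channel exists) -> RMS envelope; phase segmentation
    and breath-by-breath onset/offset detection; timing metrics.
    """
    config = config or AnalysisConfig()
    filter_spec = FilterSpec(**config.filter)
    lms_spec = LmsSpec(**config.ecg_removal)
    env_spec = EnvelopeSpec(**config.envelope)
    breath_params = br.BreathParams(**config.breaths)
    det_spec = timing.DetectionSpec(**config.detection)

    breath_list = br.detect_breaths(recording["flow"], breath_params)
    if "pm" in recording:
        br.detect_pressure_onsets(recording["pm"], breath_list, breath_params)

    ecg = recording["ecg"] if (config.ecg_removal_enabled and "ecg" in recording) else None
    envelopes = {}
    all_events: list[timing.MuscleEvent] = []
    for muscle in recording.muscle_names():
        env = preprocess_emg(recording[muscle], ecg, filter_spec, lms_spec, env_spec)
        envelopes[muscle] = env
        events = timing.detect_events_for_breaths(env, breath_list, muscle, det_spec)
        by_index = {b.index: b for b in breath_list}
        for e in events:
            timing.compute_timing_metrics(e, by_index[e.breath_index])
        all_events.extend(events)

    return SessionResult(
        breaths=br.breaths_to_frame(breath_list),
        events=_detections_frame(all_events),
        metrics=timing.events_to_frame(all_events),
        breath_objs=breath_list,
        envelopes=envelopes,
    )


def _detections_frame(events: list[timing.MuscleEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append({"muscle": e.muscle, "breath_index": e.breath_index,
                     "emg_onset": e.emg_onset, "emg_offset": e.emg_offset})
    return pd.DataFrame(rows, columns=["muscle", "breath_index",
                                       "emg_onset", "emg_offset"])


def events_table_from_result(result: SessionResult, participant: str = "p1",
                             source: str = "algorithm") -> pd.DataFrame:
    """Detected events in the events-CSV schema (missing -> NA on write)."""
    rows = []
    for _, r in result.events.iterrows():
        for kind, col in (("onset", "emg_onset"), ("offset", "emg_offset")):
            t = r[col]
            missing = pd.isna(t)
            rows.append({"participant": participant, "muscle": r["muscle"],
                         "breath_index": int(r["breath_index"]),
                         "event_kind": kind,
                         "time_ms": float(t) if not missing else float("nan"),
                         "source": source, "missing": missing})
    return pd.DataFrame(rows, columns=["participant", "muscle", "breath_index",
                                       "event_kind", "time_ms", "source", "missing"])
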