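"""EMG onset/offset detection on the RMS envelope and breath-timing metrics.

Detection logic
---------------
The first derivative of a lightly smoothed envelope partitions it into rising
and descending phases: a positive derivative marks a rising EMG RMS, a
negative derivative a descending one. Working on derivative sign rather than
absolute level is what makes the method robust to between-subject baseline
differences and envelopes that never return to baseline between bursts.

Within the rising phase assigned to a breath, the EMG onset is the earliest
time the envelope reaches 5% of that breath's rise (baseline at the start of
the rise plus 5% of peak-minus-baseline); referencing the threshold to the
rise keeps baseline variability from being mistaken for activation. The EMG
offset is the earliest time after the peak at which the envelope has dropped
by 30% from the peak — the conventional cycling-off criterion. Both are
resolved to one sample (±1 ms at 1000 Hz).

Timing metrics
--------------
Per breath and muscle, with all times in milliseconds:

    dPon  = EMG,onset  - INSP,onset          (Eq. 1)
    dPoff = EMG,offset - INSP,offset         (Eq. 2)
    %Ti,on  = dPon  / Ti x 100               (Eq. 3)
    %Ti,off = dPoff / Ti x 100               (Eq. 4)

Zero means synchrony of EMG and flow; negative values mean the EMG change
preceded the flow. The same equations applied against the mouth-pressure
onset give the pressure-based variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .breaths import Breath
from .signals import SampledSignal

__all__ = [
    "Phase", "DetectionSpec", "MuscleEvent",
    "segment_phases", "assign_phase_to_breath",
    "detect_emg_onset", "detect_emg_offset",
    "detect_events_for_breaths", "compute_timing_metrics",
    "isotime_minutes", "summarize_windows",
]


@dataclass(frozen=True)
class Phase:
    """One rising/descending excursion of the envelope (sample indices)."""

    rise_start: int
    peak_index: int
    fall_end: int


@dataclass
class DetectionSpec:
    """Onset/offset thresholds and segmentation smoothing.

    onset_fraction: fraction of the breath-wise rise (peak minus baseline at
    rise start) defining the onset threshold. onset_reference='rise' uses the
    baseline-referenced rise; 'peak' thresholds on the absolute peak instead.
    offset_drop: fractional drop from peak defining the offset.
    derivative_smooth_ms / min_phase_ms: pre-differentiation smoothing and the
    minimum persistence of a derivative sign for a phase to count.
    min_rise_amplitude: rises smaller than this are discarded; when None it is
    taken as 3x the envelope SD over the session's quietest second.
    """

    onset_fraction: float = 0.05
    offset_drop: float = 0.30
    onset_reference: str = "rise"           # "rise" | "peak"
    derivative_smooth_ms: float = 25.0
    min_phase_ms: float = 25.0
    min_rise_amplitude: float | None = None
    merge_trough_fraction: float = 0.5

    def validate(self) -> None:
        if not 0 < self.onset_fraction < 1:
            raise ValueError("onset_fraction must be in (0, 1)")
        if not 0 < self.offset_drop < 1:
            raise ValueError("offset_drop must be in (0, 1)")
        if self.onset_reference not in ("rise", "peak"):
            raise ValueError("onset_reference must be 'rise' or 'peak'")


@dataclass
class MuscleEvent:
    """Detected events and derived timing metrics for one muscle and breath.

    Metrics are None whenever a constituent event or landmark is missing.
    Negative dP means the EMG change preceded the reference signal.
    """

    muscle: str
    breath_index: int
    emg_onset: float | None = None
    emg_offset: float | None = None
    dPon: float | None = None
    dPoff: float | None = None
    pct_ti_on: float | None = None
    pct_ti_off: float | None = None
    duration: float | None = None
    pct_ti_duration: float | None = None
    dPon_pm: float | None = None
    pct_ti_on_pm: float | None = None
    onset_to_peak_pm: float | None = None


def _runs(sign: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a sign array into (sign, start, stop) with stop exclusive."""
    out = []
    start = 0
    for i in range(1, sign.size + 1):
        if i == sign.size or sign[i] != sign[start]:
            out.append((int(sign[start]), start, i))
            start = i
    return out


def default_min_rise_amplitude(envelope: SampledSignal) -> float:
    """3x the envelope SD over the quietest 1 s of the session.

    The quietest second is the 1-s window with the lowest mean envelope;
    rises smaller than three of its SDs are treated as undetectable,
    mirroring a human assessor's 'NA' for bursts lost in the baseline.
    """
    fs = envelope.sampling_rate
    n = min(int(round(fs)), len(envelope))
    means = uniform_filter1d(envelope.values, size=n, mode="nearest")
    lo = max(0, int(np.argmin(means)) - n // 2)
    quiet = envelope.values[lo:lo + n]
    return 3.0 * float(np.std(quiet))


def segment_phases(envelope: SampledSignal, spec: DetectionSpec | None = None) -> list[Phase]:
    """Partition the envelope into rising/descending phases.

    The envelope is smoothed with a centered moving mean before
    differentiation and a derivative sign must persist for ``min_phase_ms``
    to open a phase, otherwise sign chatter at the sampling rate would
    fragment every burst. A flat envelope yields an empty list.
    """
    spec = spec or DetectionSpec()
    spec.validate()
    fs = envelope.sampling_rate
    nsm = max(1, int(round(spec.derivative_smooth_ms * fs / 1000.0)))
    if nsm % 2 == 0:
        nsm += 1
    smooth = uniform_filter1d(envelope.values, size=nsm, mode="nearest")
    deriv = np.gradient(smooth)
    scale = float(np.max(np.abs(envelope.values))) or 1.0
    tol = 1e-12 * scale
    sign = np.zeros(deriv.size, dtype=int)
    sign[deriv > tol] = 1
    sign[deriv < -tol] = -1

    # absorb sub-persistence runs into the preceding run's sign
    min_run = max(1, int(round(spec.min_phase_ms * fs / 1000.0)))
    runs = _runs(sign)
    cleaned = np.array(sign)
    prev_sign = 0
    for s, a, b in runs:
        if b - a < min_run:
            cleaned[a:b] = prev_sign
        else:
            prev_sign = s
    runs = _runs(cleaned)

    min_rise = (spec.min_rise_amplitude
                if spec.min_rise_amplitude is not None
                else default_min_rise_amplitude(envelope))

    env = envelope.values
    raw: list[Phase] = []
    for k, (s, a, b) in enumerate(runs):
        if s != 1:
            continue
        # find the descending run that ends this excursion (skip flats,
        # stop at the next rise)
        fall_a, fall_b = b, b
        for s2, a2, b2 in runs[k + 1:]:
            if s2 == 1:
                break
            if s2 == -1:
                fall_a, fall_b = a2, b2
                break
        peak = a + int(np.argmax(env[a:fall_a + 1] if fall_a > a else env[a:b]))
        if env[peak] <= env[a]:
            continue
        raw.append(Phase(rise_start=a, peak_index=peak, fall_end=min(fall_b, env.size - 1)))

    merged = _merge_burst_ripples(raw, env, spec.merge_trough_fraction)
    return [p for p in merged
            if env[p.peak_index] - env[p.rise_start] >= max(min_rise, 0.0)
            and env[p.peak_index] > env[p.rise_start]]


def _merge_burst_ripples(phases: list[Phase], env: np.ndarray,
                         trough_fraction: float) -> list[Phase]:
    """Fuse consecutive phases that are ripples on one sustained burst.

    The RMS envelope of a noise-carried burst fluctuates on its plateau, so
    raw derivative-sign segmentation splits a single burst into several
    small phases. Two adjacent phases are treated as one burst when the
    trough between them retains more than ``trough_fraction`` of the smaller
    adjacent peak-to-trough excursion — i.e. the envelope never really gave
    the rise back. A return toward baseline between genuine bursts fails
    this test and keeps the bursts separate. Applied to a fixpoint.
    """
    if not phases:
        return []
    out = [phases[0]]
    for p in phases[1:]:
        q = out[-1]
        trough_idx = q.fall_end if q.fall_end < p.rise_start else p.rise_start
        trough = min(env[trough_idx], env[p.rise_start])
        lower_peak = min(env[q.peak_index], env[p.peak_index])
        base = min(env[q.rise_start], trough)
        excursion = lower_peak - base
        if excursion > 0 and (trough - base) >= trough_fraction * excursion:
            peak = q.peak_index if env[q.peak_index] >= env[p.peak_index] else p.peak_index
            out[-1] = Phase(rise_start=q.rise_start, peak_index=peak,
                            fall_end=p.fall_end)
        else:
            out.append(p)
    return out


def assign_phase_to_breath(phases: list[Phase], envelope: SampledSignal,
                           breath: Breath, prev_breath: Breath | None) -> Phase | None:
    """Pick the rising phase belonging to one breath.

    The eligible window runs from the midpoint of the preceding expiration
    (session start for the first breath) to the breath's inspiratory offset;
    a phase is eligible when its rising interval (rise start to peak)
    overlaps the window — the envelope peak itself may fall after the
    inspiratory offset, since inspiratory-muscle activity routinely outlasts
    the inspiratory flow. Among eligible phases the one with the greatest
    peak wins; ties go to the peak closest to the inspiratory onset.
    """
    if prev_breath is not None:
        win_lo = 0.5 * (prev_breath.insp_offset + breath.insp_onset)
    else:
        win_lo = envelope.index_to_ms(0)
    win_hi = breath.insp_offset
    env = envelope.values
    eligible = [p for p in phases
                if envelope.index_to_ms(p.rise_start) <= win_hi
                and envelope.index_to_ms(p.peak_index) >= win_lo]
    if not eligible:
        return None
    best_peak = max(env[p.peak_index] for p in eligible)
    top = [p for p in eligible if env[p.peak_index] == best_peak]
    return min(top, key=lambda p: abs(envelope.index_to_ms(p.peak_index) - breath.insp_onset))


def detect_emg_onset(envelope: SampledSignal, phase: Phase | None,
                     spec: DetectionSpec | None = None) -> float | None:
    """Earliest time (ms) within the rising phase at which the envelope
    reaches the onset threshold; None when no phase was assigned."""
    if phase is None:
        return None
    spec = spec or DetectionSpec()
    spec.validate()
    env = envelope.values
    baseline = env[phase.rise_start]
    peak = env[phase.peak_index]
    if spec.onset_reference == "rise":
        thr = baseline + spec.onset_fraction * (peak - baseline)
    else:
        thr = spec.onset_fraction * peak
    seg = env[phase.rise_start:phase.peak_index + 1]
    hits = np.flatnonzero(seg >= thr)
    if hits.size == 0:
        return None
    return float(envelope.index_to_ms(phase.rise_start + int(hits[0])))


def detect_emg_offset(envelope: SampledSignal, phase: Phase | None,
                      spec: DetectionSpec | None = None,
                      search_end_ms: float | None = None) -> float | None:
    """Earliest durable drop (ms) of the envelope by ``offset_drop`` from the
    phase's peak; None if it never drops before ``search_end_ms`` (default:
    the phase's fall end).

    'Durable' means the envelope does not rise back above the threshold
    within the search window: on a monotone descent this is exactly the
    first crossing, while on a rippled plateau it rejects transient dips
    that would otherwise end the burst long before activity ceases.
    """
    if phase is None:
        return None
    spec = spec or DetectionSpec()
    spec.validate()
    env = envelope.values
    peak = env[phase.peak_index]
    thr = (1.0 - spec.offset_drop) * peak
    end = phase.fall_end
    if search_end_ms is not None:
        end = max(end, min(envelope.ms_to_index(search_end_ms), env.size - 1))
    seg = env[phase.peak_index + 1:end + 1]
    if seg.size == 0:
        return None
    above = seg > thr
    if above[-1]:
        return None
    last_above = np.flatnonzero(above)
    first_durable = 0 if last_above.size == 0 else int(last_above[-1]) + 1
    return float(envelope.index_to_ms(phase.peak_index + 1 + first_durable))


def detect_events_for_breaths(envelope: SampledSignal, breaths: list[Breath],
                              muscle: str,
                              spec: DetectionSpec | None = None) -> list[MuscleEvent]:
    """Breath-by-breath onset/offset detection for one muscle's envelope."""
    spec = spec or DetectionSpec()
    phases = segment_phases(envelope, spec)
    events: list[MuscleEvent] = []
    for i, b in enumerate(breaths):
        prev_b = breaths[i - 1] if i > 0 else None
        nxt = breaths[i + 1] if i + 1 < len(breaths) else None
        phase = assign_phase_to_breath(phases, envelope, b, prev_b)
        onset = detect_emg_onset(envelope, phase, spec)
        # the offset may be searched up to the start of the next breath's window
        if nxt is not None:
            search_end = 0.5 * (b.insp_offset + nxt.insp_onset)
        else:
            search_end = envelope.index_to_ms(len(envelope) - 1)
        offset = detect_emg_offset(envelope, phase, spec, search_end_ms=search_end)
        if onset is not None and offset is not None and offset <= onset:
            offset = None
        events.append(MuscleEvent(muscle=muscle, breath_index=b.index,
                                  emg_onset=onset, emg_offset=offset))
    return events


def compute_timing_metrics(event: MuscleEvent, breath: Breath) -> MuscleEvent:
    """Complete a MuscleEvent with the flow- and pressure-based metrics.

    Flow basis uses INSP,onset / INSP,offset and Ti from the flow signal;
    pressure basis uses pm_onset (inspiratory time for the pressure basis is
    insp_offset - pm_onset). Any metric whose constituent event or landmark
    is missing stays None.
    """
    ti = breath.ti
    if event.emg_onset is not None:
        event.dPon = event.emg_onset - breath.insp_onset
        event.pct_ti_on = event.dPon / ti * 100.0
        if breath.pm_onset is not None:
            ti_pm = breath.insp_offset - breath.pm_onset
            event.dPon_pm = event.emg_onset - breath.pm_onset
            event.pct_ti_on_pm = event.dPon_pm / ti_pm * 100.0 if ti_pm > 0 else None
        if breath.t_peak_pm is not None:
            event.onset_to_peak_pm = breath.t_peak_pm - event.emg_onset
    if event.emg_offset is not None:
        event.dPoff = event.emg_offset - breath.insp_offset
        event.pct_ti_off = event.dPoff / ti * 100.0
    if event.emg_onset is not None and event.emg_offset is not None:
        event.duration = event.emg_offset - event.emg_onset
        event.pct_ti_duration = event.duration / ti * 100.0
    return event


def events_to_frame(events: list[MuscleEvent]) -> pd.DataFrame:
    """Tabulate MuscleEvents (one row per muscle x breath, times in ms)."""
    cols = ["muscle", "breath_index", "emg_onset", "emg_offset", "dPon", "dPoff",
            "pct_ti_on", "pct_ti_off", "duration", "pct_ti_duration",
            "dPon_pm", "pct_ti_on_pm", "onset_to_peak_pm"]
    rows = [{c: getattr(e, c) for c in cols} for e in events]
    return pd.DataFrame(rows, columns=cols)


def isotime_minutes(durations_min: list[float] | np.ndarray) -> int:
    """Isotime across participants: the highest equivalent time achieved by
    all of them, i.e. the minimum session duration after rounding each to the
    nearest minute (round-half-up)."""
    if len(durations_min) == 0:
        raise ValueError("need at least one session duration")
    return int(min(math.floor(d + 0.5) for d in durations_min))


_BREATH_VARS = ["ti", "ttot", "fr", "peak_flow", "vt", "peak_pm"]
_EVENT_VARS = ["dPon", "dPoff", "pct_ti_on", "pct_ti_off", "duration",
               "pct_ti_duration", "dPon_pm", "pct_ti_on_pm", "onset_to_peak_pm"]


def summarize_windows(metrics: pd.DataFrame, breaths: pd.DataFrame,
                      isotime_min: float | None = None,
                      bin_minutes: float = 2.0,
                      session_duration_ms: float | None = None) -> pd.DataFrame:
    """Windowed means/SDs: 2-min bins up to isotime plus a task-failure window.

    ``metrics`` is the per-muscle-per-breath table (events_to_frame output
    after compute_timing_metrics), ``breaths`` the per-breath table. Windows
    are labelled ``min_0_2``, ``min_2_4``, ... and ``task_failure`` (the last
    2 min of the session, which may overlap the final bin). Returns a long
    table (window, muscle, variable, mean, sd, n, empty); breath-level
    ventilatory variables appear with muscle = "". Empty bins are flagged,
    not dropped.
    """
    if session_duration_ms is None:
        session_duration_ms = float(breaths["insp_offset"].max())
    if isotime_min is None:
        isotime_min = session_duration_ms / 60000.0
    n_bins = max(1, int(math.ceil(min(isotime_min, session_duration_ms / 60000.0)
                                  / bin_minutes)))
    bin_ms = bin_minutes * 60000.0

    windows: list[tuple[str, float, float]] = []
    for k in range(n_bins):
        label = f"min_{int(k * bin_minutes)}_{int((k + 1) * bin_minutes)}"
        windows.append((label, k * bin_ms, (k + 1) * bin_ms))
    windows.append(("task_failure", max(0.0, session_duration_ms - bin_ms),
                    session_duration_ms + 1.0))

    joined = metrics.merge(breaths[["breath_index", "insp_onset"]], on="breath_index")
    rows = []
    for label, lo, hi in windows:
        bsel = breaths[(breaths["insp_onset"] >= lo) & (breaths["insp_onset"] < hi)]
        for var in _BREATH_VARS:
            vals = pd.to_numeric(bsel[var], errors="coerce").dropna()
            rows.append({"window": label, "muscle": "", "variable": var,
                         "mean": vals.mean() if len(vals) else np.nan,
                         "sd": vals.std(ddof=1) if len(vals) > 1 else (0.0 if len(vals) == 1 else np.nan),
                         "n": len(vals), "empty": len(vals) == 0})
        msel = joined[(joined["insp_onset"] >= lo) & (joined["insp_onset"] < hi)]
        for muscle, grp in msel.groupby("muscle"):
            for var in _EVENT_VARS:
                vals = pd.to_numeric(grp[var], errors="coerce").dropna()
                rows.append({"window": label, "muscle": muscle, "variable": var,
                             "mean": vals.mean() if len(vals) else np.nan,
                             "sd": vals.std(ddof=1) if len(vals) > 1 else (0.0 if len(vals) == 1 else np.nan),
                             "n": len(vals), "empty": len(vals) == 0})
        if msel.empty:
            for muscle in metrics["muscle"].unique():
                for var in _EVENT_VARS:
                    rows.append({"window": label, "muscle": muscle, "variable": var,
                                 "mean": np.nan, "sd": np.nan, "n": 0, "empty": True})
    return pd.DataFrame(rows, columns=["window", "muscle", "variable",
                                       "mean", "sd", "n", "empty"])
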