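"""Breath segmentation from the airflow channel and per-breath landmarks.

Inspiration is taken as positive flow (configurable). A breath's inspiratory
onset (INSP,onset) is found by a small positive-threshold crossing followed by
back-tracking to the preceding zero-crossing, which keeps the detection within
about a millisecond of the true start while remaining robust to baseline
noise. The inspiratory offset is where flow returns to the zero band. Tidal
volume is the trapezoidal integral of inspiratory flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import SampledSignal

__all__ = ["Breath", "BreathParams", "detect_breaths", "detect_pressure_onsets",
           "breaths_to_frame"]


@dataclass
class Breath:
    """One respiratory cycle's flow-derived landmarks (times in ms)."""

    index: int
    insp_onset: float
    insp_offset: float
    peak_flow: float
    vt: float
    ttot: float | None = None       # onset-to-next-onset; None for last breath
    peak_pm: float | None = None
    pm_onset: float | None = None
    t_peak_pm: float | None = None

    @property
    def ti(self) -> float:
        return self.insp_offset - self.insp_onset

    @property
    def fr(self) -> float | None:
        """Respiratory frequency in breaths/min (needs Ttot)."""
        return None if self.ttot is None else 60000.0 / self.ttot


@dataclass
class BreathParams:
    """Detection thresholds for flow-based breath segmentation.

    onset_threshold_frac: flow must exceed this fraction of the session's
    median per-breath peak flow (floor onset_threshold_min L/s) before the
    onset is back-tracked to the preceding zero-crossing.
    """

    onset_threshold_frac: float = 0.02
    onset_threshold_min: float = 0.02
    zero_band: float = 1e-3           # L/s; |flow| below this counts as zero
    min_ti_ms: float = 200.0
    min_vt_l: float = 0.05
    debounce_ms: float = 300.0
    inspiration_positive: bool = True
    pm_threshold: float = 2.0         # cmH2O deflection for pressure onsets
    pm_window_ms: float = 1000.0      # search lead before flow onset


def _candidate_segments(flow: np.ndarray, thr: float, zero_band: float) -> list[tuple[int, int]]:
    """Supra-threshold excursions expanded to their surrounding zero-band."""
    above = flow > thr
    if not above.any():
        return []
    starts = list(np.flatnonzero(np.diff(above.astype(int)) == 1) + 1)
    ends = list(np.flatnonzero(np.diff(above.astype(int)) == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(flow.size)
    segs = []
    for s, e in zip(starts, ends):
        # back-track onset to the preceding zero-crossing / zero-band entry
        i = s
        while i > 0 and flow[i - 1] > zero_band:
            i -= 1
        # extend offset to where flow returns to the zero band
        j = e
        while j < flow.size and flow[j] > zero_band:
            j += 1
        segs.append((i, j))
    return segs


def detect_breaths(flow: SampledSignal, params: BreathParams | None = None) -> list[Breath]:
    """Segment the airflow channel into breaths.

    Returns an ordered, non-overlapping list of :class:`Breath`. All-zero or
    all-expiratory flow yields an empty list. Candidate excursions shorter
    than ``min_ti_ms`` or integrating to less than ``min_vt_l`` are rejected;
    candidates beginning within ``debounce_ms`` of the previous accepted
    offset are merged into it.
    """
    params = params or BreathParams()
    fs = flow.sampling_rate
    x = flow.values if params.inspiration_positive else -flow.values

    if np.all(x <= params.zero_band):
        return []

    # provisional segmentation with the floor threshold to estimate typical
    # peak flow, then final segmentation at the adaptive threshold
    rough = _candidate_segments(x, params.onset_threshold_min, params.zero_band)
    if not rough:
        return []
    med_peak = float(np.median([x[s:e].max() for s, e in rough]))
    thr = max(params.onset_threshold_frac * med_peak, params.onset_threshold_min)
    segs = _candidate_segments(x, thr, params.zero_band)

    # debounce: merge candidates that begin too soon after the previous offset
    merged: list[list[int]] = []
    debounce = int(round(params.debounce_ms * fs / 1000.0))
    for s, e in segs:
        if merged and s - merged[-1][1] <= debounce:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    breaths: list[Breath] = []
    for s, e in merged:
        ti_ms = (e - s) / fs * 1000.0
        if ti_ms < params.min_ti_ms:
            continue
        vt = float(np.trapezoid(x[s:e], dx=1.0 / fs))
        if vt < params.min_vt_l:
            continue
        breaths.append(Breath(
            index=len(breaths),
            insp_onset=float(flow.index_to_ms(s)),
            insp_offset=float(flow.index_to_ms(e - 1)),
            peak_flow=float(x[s:e].max()),
            vt=vt,
        ))
    for b, nxt in zip(breaths, breaths[1:]):
        b.ttot = nxt.insp_onset - b.insp_onset
    return breaths


def detect_pressure_onsets(pm: SampledSignal, breaths: list[Breath],
                           params: BreathParams | None = None) -> list[Breath]:
    """Annotate breaths with mouth-pressure landmarks (in place).

    For each breath the pressure-based inspiratory start (``pm_onset``) is
    the first time the deflection from the local pre-inspiratory baseline
    exceeds ``pm_threshold`` cmH2O, searched from ``pm_window_ms`` before the
    flow onset up to the inspiratory offset. Inspiratory mouth pressure
    against a threshold load is negative; the deflection magnitude is used,
    so polarity does not matter. Breaths with no qualifying deflection keep
    ``pm_onset = None``. ``peak_pm`` is the largest deflection magnitude and
    ``t_peak_pm`` its time.
    """
    params = params or BreathParams()
    fs = pm.sampling_rate
    x = pm.values
    for b in breaths:
        i_on = pm.ms_to_index(b.insp_onset)
        i_off = pm.ms_to_index(b.insp_offset)
        lead = int(round(params.pm_window_ms * fs / 1000.0))
        s = max(0, i_on - lead)
        # baseline from the quiet interval just before the search window
        base_lo = max(0, s - int(0.2 * fs))
        baseline = float(np.median(x[base_lo:s + 1])) if s > base_lo else float(x[s])
        seg = np.abs(x[s:i_off + 1] - baseline)
        if seg.size == 0 or seg.max() < params.pm_threshold:
            b.pm_onset = None
            continue
        k = int(np.argmax(seg >= params.pm_threshold))
        b.pm_onset = float(pm.index_to_ms(s + k))
        kp = int(np.argmax(seg))
        b.peak_pm = float(x[s + kp])
        b.t_peak_pm = float(pm.index_to_ms(s + kp))
    return breaths


def breaths_to_frame(breaths: list[Breath]) -> pd.DataFrame:
    """Tabulate breaths (one row per breath, times in ms)."""
    rows = [{
        "breath_index": b.index,
        "insp_onset": b.insp_onset,
        "insp_offset": b.insp_offset,
        "ti": b.ti,
        "ttot": b.ttot,
        "fr": b.fr,
        "peak_flow": b.peak_flow,
        "vt": b.vt,
        "peak_pm": b.peak_pm,
        "pm_onset": b.pm_onset,
        "t_peak_pm": b.t_peak_pm,
    } for b in breaths]
    cols = ["breath_index", "insp_onset", "insp_offset", "ti", "ttot", "fr",
            "peak_flow", "vt", "peak_pm", "pm_onset", "t_peak_pm"]
    return pd.DataFrame(rows, columns=cols)
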