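"""Synthetic respiratory-EMG sessions with exact ground-truth event times.

The generator emulates a paced inspiratory-loading recording: half-sine
inspiratory flow pulses at 10 breaths/min, per-muscle surface-EMG bursts
(band-limited noise carriers amplitude-modulated by trapezoidal envelopes)
whose onsets lead or lag the flow onset by configurable offsets, a
QRS-dominated ECG template train coupled into every EMG channel, mouth
pressure deflections leading the flow, and white baseline noise. Every
programmed event is recorded in a ground-truth table exact to the sample,
so each pipeline stage can be tested without any external data.

Ground-truth conventions
------------------------
``true_onset`` is the programmed burst start — the instant muscle activity
begins, which the 5%-of-rise criterion is designed to approximate.
``true_offset`` is the analytic 30%-drop time on the ideal trapezoid
(fall start + 0.3 x fall time), because the offset criterion deliberately
marks a point inside the decay rather than the end of activity.

The default burst rise time is 200 ms. Inspiratory-muscle recruitment ramps
over a few hundred milliseconds, and for a linear rise of duration R viewed
through a centered RMS window of width W the expected 5%-of-rise crossing of
the windowed envelope lies at (0.0075 R^2 W)^(1/3) - W/2 relative to burst
start — about -0.3 ms for R = 200 ms with the detector's default W = 50 ms,
so the recovered onset is an essentially unbiased estimate of the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signals import MUSCLES, SampledSignal, SessionRecording

__all__ = [
    "BurstSpec", "EcgSpec", "PmSpec", "NoiseSpec", "SimSpec", "GroundTruth",
    "simulate_session", "assessor_emulator", "truth_to_event_table",
    "default_sim_spec",
]


@dataclass
class BurstSpec:
    """One muscle's per-breath activity burst.

    onset_offset_ms is the burst start relative to the breath's flow onset
    (negative = the muscle leads the flow, the usual physiological case).
    The envelope is a trapezoid: linear rise over rise_ms, plateau, linear
    fall over fall_ms, total duration_ms. amplitude_uv sets the plateau RMS.

    carrier='noise' (the realistic default) modulates band-limited Gaussian
    noise, whose windowed RMS ripples by ~10-20% as real surface EMG does.
    carrier='sine' modulates a unit-RMS sinusoid (constant instantaneous
    envelope), producing a deterministic RMS trace — the genuinely
    noise-free condition, for which event recovery is analytically exact.
    """

    onset_offset_ms: float = -100.0
    jitter_sd_ms: float = 40.0
    duration_ms: float = 1800.0
    rise_ms: float = 200.0
    fall_ms: float = 200.0
    amplitude_uv: float = 40.0
    carrier: str = "noise"
    carrier_band_hz: tuple[float, float] = (20.0, 450.0)
    carrier_freq_hz: float = 100.0


@dataclass
class EcgSpec:
    """QRS-dominated artifact train: sum-of-Gaussians template, ~110 ms wide
    (inside the 0.10-0.12 s QRS span), repeated at heart_rate_bpm. The 75 bpm
    default is deliberately incommensurate with 10 breaths/min so QRS-onset
    collisions occur in a known fraction of breaths. coupling_uv_per_mv maps
    the template (peak 1 mV on the ECG channel) into each EMG channel."""

    heart_rate_bpm: float = 75.0
    amplitude_mv: float = 1.0
    qrs_width_ms: float = 110.0
    coupling_uv_per_mv: dict[str, float] = field(default_factory=dict)


@dataclass
class PmSpec:
    """Mouth-pressure deflections: rounded square pulses (edge_ms cosine
    ramps) at -amplitude, starting lead_ms before each flow onset and ending
    at the inspiratory offset. Loading at ~50% of a typical maximal
    inspiratory pressure gives the 50 cmH2O default."""

    enabled: bool = True
    lead_ms: float = 150.0
    amplitude_cmh2o: float = 50.0
    edge_ms: float = 5.0


@dataclass
class NoiseSpec:
    """Baseline white-noise SDs per channel kind."""

    emg_uv: float = 2.0
    ecg_mv: float = 0.01
    flow_lps: float = 0.0
    pm_cmh2o: float = 0.0


@dataclass
class SimSpec:
    """Full synthetic-session specification. Identical seed + spec gives
    bit-identical output."""

    duration_s: float = 600.0
    sampling_rate: float = 1000.0
    breath_rate_per_min: float = 10.0
    ti_s: float = 1.5
    flow_amplitude_lps: float = 1.0
    flow_amplitude_cv: float = 0.05
    start_offset_s: float = 1.0
    muscles: dict[str, BurstSpec] = field(default_factory=dict)
    ecg: EcgSpec = field(default_factory=EcgSpec)
    pm: PmSpec = field(default_factory=PmSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    undetectable_fraction: float = 0.0
    undetectable_scale: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration must be positive")
        if not self.muscles:
            raise ValueError("at least one muscle burst spec required")
        for name, b in self.muscles.items():
            if b.rise_ms + b.fall_ms > b.duration_ms:
                raise ValueError(f"{name}: rise+fall exceeds burst duration")
            if b.jitter_sd_ms < 0:
                raise ValueError(f"{name}: jitter SD must be >= 0")
        if not 0 <= self.undetectable_fraction < 1:
            raise ValueError("undetectable_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Exact programmed event times: per-breath flow/pressure landmarks and
    per-muscle-per-breath burst onset/offset with a detectability flag."""

    breaths: pd.DataFrame   # breath_index, insp_onset, insp_offset, pm_onset
    events: pd.DataFrame    # muscle, breath_index, true_onset, true_offset, detectable


def default_sim_spec(**overrides) -> SimSpec:
    """Study-condition defaults: 10-min paced session, 10 breaths/min,
    four muscles with realistic amplitude differences and flow leads,
    75 bpm ECG coupled most strongly into the chest-wall channels."""
    muscles = {
        # the diaphragm/intercostal channel fires latest and most variably;
        # the accessory muscles lead the flow onset by ~100-150 ms
        "diaphragm_intercostal": BurstSpec(onset_offset_ms=-50.0, amplitude_uv=25.0,
                                           jitter_sd_ms=50.0),
        "scalene": BurstSpec(onset_offset_ms=-150.0, amplitude_uv=50.0,
                             jitter_sd_ms=35.0),
        "parasternal": BurstSpec(onset_offset_ms=-120.0, amplitude_uv=40.0,
                                 jitter_sd_ms=35.0),
        "sternocleidomastoid": BurstSpec(onset_offset_ms=-130.0, amplitude_uv=45.0,
                                         jitter_sd_ms=40.0),
    }
    coupling = {"diaphragm_intercostal": 200.0, "scalene": 50.0,
                "parasternal": 100.0, "sternocleidomastoid": 50.0}
    spec = SimSpec(muscles=muscles, ecg=EcgSpec(coupling_uv_per_mv=coupling))
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


def _qrs_template(fs: float, width_ms: float, amplitude: float) -> np.ndarray:
    """Sum-of-Gaussians QRS: dominant R wave with smaller Q and S lobes."""
    half = width_ms / 2.0 / 1000.0
    t = np.arange(-half, half + 0.5 / fs, 1.0 / fs)
    w = width_ms / 110.0  # scale lobe widths with the requested QRS span
    r = np.exp(-0.5 * (t / (0.012 * w)) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.025 * w) / (0.008 * w)) ** 2)
    s = -0.25 * np.exp(-0.5 * ((t - 0.030 * w) / (0.010 * w)) ** 2)
    tpl = r + q + s
    return amplitude * tpl / np.max(np.abs(tpl))


def _bandlimited_carrier(n: int, fs: float, band: tuple[float, float],
                         rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (the surface-EMG carrier)."""
    lo, hi = band
    hi = min(hi, 0.999 * fs / 2)
    white = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, white)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _trapezoid(n_total: int, fs: float, start_idx: int, duration_ms: float,
               rise_ms: float, fall_ms: float) -> tuple[np.ndarray, int, int]:
    """Add-ready trapezoid envelope (unit plateau) and its index span."""
    dur = int(round(duration_ms * fs / 1000.0))
    rise = max(1, int(round(rise_ms * fs / 1000.0)))
    fall = max(1, int(round(fall_ms * fs / 1000.0)))
    plateau = dur - rise - fall
    # sampled so that env[start+j] matches the continuous trapezoid exactly:
    # rise j/R for j<R, plateau 1, fall 1-j/F ending at 0
    env = np.concatenate([
        np.arange(rise) / rise,
        np.ones(max(plateau, 0)),
        1.0 - np.arange(1, fall + 1) / fall,
    ])
    end = min(start_idx + env.size, n_total)
    return env[: end - start_idx], start_idx, end


def simulate_session(spec: SimSpec, seed: int | None = None
                     ) -> tuple[SessionRecording, GroundTruth]:
    """Generate one multi-channel session plus its ground-truth table.

    Raises a spec error when a muscle's bursts would overlap across breaths.
    """
    spec.validate()
    fs = spec.sampling_rate
    n = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    period_s = 60.0 / spec.breath_rate_per_min
    ti = spec.ti_s
    onsets_s = np.arange(spec.start_offset_s, spec.duration_s - ti - 0.5, period_s)

    # flow: half-sine inspiratory pulses, inspiration positive
    flow = np.zeros(n)
    breath_rows = []
    amps = spec.flow_amplitude_lps * np.maximum(
        1.0 + spec.flow_amplitude_cv * rng.standard_normal(onsets_s.size), 0.1)
    for bi, (t_on, amp) in enumerate(zip(onsets_s, amps)):
        i0 = int(round(t_on * fs))
        ni = int(round(ti * fs))
        tt = np.arange(ni) / fs
        flow[i0:i0 + ni] += amp * np.sin(np.pi * tt / ti)
        breath_rows.append({"breath_index": bi,
                            "insp_onset": i0 / fs * 1000.0,
                            "insp_offset": (i0 + ni - 1) / fs * 1000.0,
                            "pm_onset": (i0 / fs - spec.pm.lead_ms / 1000.0) * 1000.0
                            if spec.pm.enabled else np.nan})

    # ECG template train
    tpl = _qrs_template(fs, spec.ecg.qrs_width_ms, spec.ecg.amplitude_mv)
    ecg_clean = np.zeros(n)
    rr = 60.0 / spec.ecg.heart_rate_bpm
    beat_times = np.arange(0.3, spec.duration_s, rr)
    half = tpl.size // 2
    for tb in beat_times:
        c = int(round(tb * fs))
        lo, hi = c - half, c - half + tpl.size
        s0, s1 = max(lo, 0), min(hi, n)
        ecg_clean[s0:s1] += tpl[s0 - lo:s1 - lo]

    channels: dict[str, SampledSignal] = {}
    event_rows = []
    for muscle, bspec in spec.muscles.items():
        if muscle not in MUSCLES:
            raise ValueError(f"unknown muscle role: {muscle}")
        if bspec.carrier == "sine":
            phase0 = rng.uniform(0, 2 * np.pi)
            carrier = np.sqrt(2.0) * np.sin(
                2 * np.pi * bspec.carrier_freq_hz * np.arange(n) / fs + phase0)
        elif bspec.carrier == "noise":
            carrier = _bandlimited_carrier(n, fs, bspec.carrier_band_hz, rng)
        else:
            raise ValueError(f"{muscle}: carrier must be 'noise' or 'sine'")
        env = np.zeros(n)
        prev_end = -1
        for bi, t_on in enumerate(onsets_s):
            jitter = rng.normal(0.0, bspec.jitter_sd_ms) if bspec.jitter_sd_ms > 0 else 0.0
            start_ms = t_on * 1000.0 + bspec.onset_offset_ms + jitter
            start_idx = int(round(start_ms * fs / 1000.0))
            if start_idx < 0:
                continue
            detectable = rng.random() >= spec.undetectable_fraction
            amp = bspec.amplitude_uv * (1.0 if detectable else spec.undetectable_scale)
            seg, s0, s1 = _trapezoid(n, fs, start_idx, bspec.duration_ms,
                                     bspec.rise_ms, bspec.fall_ms)
            if s0 <= prev_end:
                raise ValueError(
                    f"{muscle}: burst for breath {bi} overlaps the previous burst")
            prev_end = s1
            env[s0:s1] += amp * seg
            true_onset = s0 / fs * 1000.0
            fall_start_ms = true_onset + bspec.duration_ms - bspec.fall_ms
            event_rows.append({
                "muscle": muscle, "breath_index": bi,
                "true_onset": true_onset,
                "true_offset": fall_start_ms + 0.3 * bspec.fall_ms,
                "detectable": detectable,
            })
        emg = env * carrier
        gain = spec.ecg.coupling_uv_per_mv.get(muscle, 0.0)
        emg = emg + gain * ecg_clean
        if spec.noise.emg_uv > 0:
            emg = emg + rng.normal(0.0, spec.noise.emg_uv, n)
        channels[muscle] = SampledSignal(emg, fs)

    ecg = ecg_clean + (rng.normal(0.0, spec.noise.ecg_mv, n)
                       if spec.noise.ecg_mv > 0 else 0.0)
    channels["ecg"] = SampledSignal(ecg, fs)

    if spec.noise.flow_lps > 0:
        flow = flow + rng.normal(0.0, spec.noise.flow_lps, n)
    channels["flow"] = SampledSignal(flow, fs)

    if spec.pm.enabled:
        pm = np.zeros(n)
        edge = max(1, int(round(spec.pm.edge_ms * fs / 1000.0)))
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
        for row in breath_rows:
            i0 = int(round(row["pm_onset"] * fs / 1000.0))
            i1 = int(round(row["insp_offset"] * fs / 1000.0))
            if i0 < 0 or i1 <= i0:
                continue
            pulse = np.ones(i1 - i0)
            m = min(edge, pulse.size // 2)
            pulse[:m] = ramp[:m]
            pulse[-m:] = ramp[:m][::-1]
            pm[i0:i1] += -spec.pm.amplitude_cmh2o * pulse
        if spec.noise.pm_cmh2o > 0:
            pm = pm + rng.normal(0.0, spec.noise.pm_cmh2o, n)
        channels["pm"] = SampledSignal(pm, fs)

    recording = SessionRecording(channels, metadata={
        "seed": spec.seed if seed is None else seed,
        "breath_rate_per_min": spec.breath_rate_per_min,
        "sampling_rate": fs,
    })
    truth = GroundTruth(
        breaths=pd.DataFrame(breath_rows,
                             columns=["breath_index", "insp_onset",
                                      "insp_offset", "pm_onset"]),
        events=pd.DataFrame(event_rows,
                            columns=["muscle", "breath_index", "true_onset",
                                     "true_offset", "detectable"]),
    )
    return recording, truth


def truth_to_event_table(truth: GroundTruth, participant: str = "sim",
                         source: str = "truth") -> pd.DataFrame:
    """Ground truth in the events-CSV schema (undetectable bursts -> NA)."""
    rows = []
    for _, r in truth.events.iterrows():
        for kind, col in (("onset", "true_onset"), ("offset", "true_offset")):
            missing = not bool(r["detectable"])
            rows.append({"participant": participant, "muscle": r["muscle"],
                         "breath_index": int(r["breath_index"]),
                         "event_kind": kind,
                         "time_ms": np.nan if missing else float(r[col]),
                         "source": source, "missing": missing})
    return pd.DataFrame(rows, columns=["participant", "muscle", "breath_index",
                                       "event_kind", "time_ms", "source", "missing"])


def assessor_emulator(truth: GroundTruth, error_sd_ms: float, miss_rate: float,
                      source: str = "assessor1", participant: str = "sim",
                      seed: int = 0) -> pd.DataFrame:
    """Emulate a human rater: truth onsets/offsets perturbed by Gaussian
    error and thinned by random misses, returned in the events-CSV schema."""
    if error_sd_ms < 0:
        raise ValueError("error_sd_ms must be >= 0")
    if not 0 <= miss_rate < 1:
        raise ValueError("miss_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    table = truth_to_event_table(truth, participant=participant, source=source)
    times = table["time_ms"].to_numpy(dtype=float)
    missing = table["missing"].to_numpy(dtype=bool)
    if error_sd_ms > 0:
        times = times + rng.normal(0.0, error_sd_ms, times.size)
    missed = rng.random(times.size) < miss_rate
    missing = missing | missed
    times[missing] = np.nan
    table["time_ms"] = times
    table["missing"] = missing
    return table
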