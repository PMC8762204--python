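"""Phase segmentation, onset/offset thresholds, timing metrics, windows."""

import numpy as np
import pandas as pd
import pytest

from respitiming import (DetectionSpec, MuscleEvent, compute_timing_metrics,
                         detect_emg_offset, detect_emg_onset, isotime_minutes,
                         segment_phases, summarize_windows)
from respitiming.breaths import Breath
from respitiming.signals import SampledSignal

FS = 1000.0

#: no smoothing/persistence: exposes the pure threshold geometry of the
#: deterministic closed-form examples
GEOM = DetectionSpec(derivative_smooth_ms=1.0, min_phase_ms=1.0,
                     min_rise_amplitude=0.0)


def env_signal(values):
    return SampledSignal(np.asarray(values, float), FS)


def triangle_envelope():
    """Flat, linear rise 2->3 s, linear fall 3->4 s, flat to 6 s."""
    t = np.arange(0, 6, 1 / FS)
    env = np.zeros_like(t)
    rise = (t >= 2) & (t < 3)
    fall = (t >= 3) & (t < 4)
    env[rise] = t[rise] - 2.0
    env[fall] = 4.0 - t[fall]
    return env_signal(env)


class TestSegmentPhases:
    def test_triangle_single_phase(self):
        phases = segment_phases(triangle_envelope(), GEOM)
        assert len(phases) == 1
        p = phases[0]
        assert abs(p.rise_start - 2000) <= 2
        assert abs(p.peak_index - 3000) <= 2
        assert abs(p.fall_end - 4000) <= 2

    def test_flat_envelope_empty(self):
        assert segment_phases(env_signal(np.full(3000, 1.5)), GEOM) == []

    def test_two_bursts_two_ordered_phases(self):
        t = np.arange(0, 10, 1 / FS)
        env = (np.exp(-0.5 * ((t - 2.5) / 0.3) ** 2)
               + 0.8 * np.exp(-0.5 * ((t - 7.0) / 0.3) ** 2))
        phases = segment_phases(env_signal(env), GEOM)
        assert len(phases) == 2
        assert phases[0].peak_index < phases[1].rise_start
        assert abs(phases[0].peak_index - 2500) <= 5
        assert abs(phases[1].peak_index - 7000) <= 5

    def test_small_rises_discarded(self):
        t = np.arange(0, 6, 1 / FS)
        env = np.exp(-0.5 * ((t - 3.0) / 0.3) ** 2)
        env += 0.01 * np.sin(2 * np.pi * 0.7 * t).clip(0)  # sub-threshold bumps
        spec = DetectionSpec(derivative_smooth_ms=1.0, min_phase_ms=1.0,
                             min_rise_amplitude=0.1)
        phases = segment_phases(env_signal(env), spec)
        assert len(phases) == 1


class TestOnset:
    def test_linear_ramp_closed_form(self):
        # baseline 0.1 at 2.000 s rising to 1.1 at 3.000 s: threshold
        # 0.1 + 0.05 * 1.0 = 0.15 crossed at t = 2.050 s
        t = np.arange(0, 5, 1 / FS)
        env = np.full_like(t, 0.1)
        rise = (t >= 2) & (t < 3)
        env[rise] = 0.1 + (t[rise] - 2.0)
        env[t >= 3] = 1.1
        sig = env_signal(env)
        phases = segment_phases(sig, GEOM)
        onset = detect_emg_onset(sig, phases[0], GEOM)
        assert onset == pytest.approx(2050.0, abs=1.0)

    def test_step_envelope(self):
        env = np.zeros(4000)
        env[1500:] = 1.0
        sig = env_signal(env)
        phases = segment_phases(sig, GEOM)
        onset = detect_emg_onset(sig, phases[0], GEOM)
        assert onset == pytest.approx(1500.0, abs=1.0)

    def test_flat_envelope_missing(self):
        sig = env_signal(np.full(3000, 0.2))
        assert detect_emg_onset(sig, None, GEOM) is None

    @pytest.mark.parametrize("seed", range(6))
    def test_onset_monotone_in_fraction(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 6, 1 / FS)
        env = np.abs(np.convolve(rng.standard_normal(t.size),
                                 np.ones(400) / 400, mode="same")) + 0.01
        sig = env_signal(env)
        spec_lo = DetectionSpec(onset_fraction=0.05)
        phases = segment_phases(sig, spec_lo)
        if not phases:
            pytest.skip("no phase in this draw")
        for frac_lo, frac_hi in [(0.05, 0.2), (0.2, 0.5)]:
            lo = detect_emg_onset(sig, phases[0], DetectionSpec(onset_fraction=frac_lo))
            hi = detect_emg_onset(sig, phases[0], DetectionSpec(onset_fraction=frac_hi))
            if lo is not None and hi is not None:
                assert hi >= lo


class TestOffset:
    def test_triangle_closed_form(self):
        # peak 1.0 at 3.000 s falling to 0 at 4.000 s: 30% drop crossed
        # where the envelope reaches 0.7, i.e. t = 3.300 s
        sig = triangle_envelope()
        phases = segment_phases(sig, GEOM)
        offset = detect_emg_offset(sig, phases[0], GEOM)
        assert offset == pytest.approx(3300.0, abs=1.5)

    def test_step_down(self):
        env = np.zeros(4000)
        env[1000:2500] = 1.0
        sig = env_signal(env)
        phases = segment_phases(sig, GEOM)
        offset = detect_emg_offset(sig, phases[0], GEOM)
        assert offset == pytest.approx(2500.0, abs=1.0)

    def test_plateau_through_window_missing(self):
        env = np.zeros(4000)
        env[1000:] = 1.0  # rises, never falls
        sig = env_signal(env)
        phases = segment_phases(sig, GEOM)
        assert detect_emg_offset(sig, phases[0], GEOM) is None

    def test_ripple_dips_do_not_end_burst(self):
        # a transient dip below 70% of peak mid-plateau must be ignored;
        # the durable drop on the final descent defines the offset
        t = np.arange(0, 6, 1 / FS)
        env = np.zeros_like(t)
        env[(t >= 1) & (t < 4)] = 1.0
        env[(t >= 2.0) & (t < 2.08)] = 0.6   # 80 ms ripple dip
        fall = (t >= 4) & (t < 5)
        env[fall] = 1.0 - (t[fall] - 4.0)
        sig = env_signal(env)
        phases = segment_phases(sig, GEOM)
        offset = detect_emg_offset(sig, phases[-1], GEOM, search_end_ms=5900.0)
        assert offset == pytest.approx(4300.0, abs=2.0)


def make_breath(insp_onset=1000.0, ti=1000.0, **kw):
    return Breath(index=0, insp_onset=insp_onset, insp_offset=insp_onset + ti,
                  peak_flow=1.0, vt=0.6, ttot=6000.0, **kw)


class TestTimingMetrics:
    def test_synchrony_is_zero(self):
        e = MuscleEvent("scalene", 0, emg_onset=1000.0, emg_offset=2100.0)
        compute_timing_metrics(e, make_breath())
        assert e.dPon == 0.0 and e.pct_ti_on == 0.0

    def test_worked_percentage_example(self):
        # a 100 ms phase difference over a 1 s inspiration is 10% of Ti
        e = MuscleEvent("scalene", 0, emg_onset=1100.0, emg_offset=2100.0)
        compute_timing_metrics(e, make_breath())
        assert e.pct_ti_on == pytest.approx(10.0, abs=1e-12)

    def test_negative_means_emg_leads(self):
        e = MuscleEvent("scalene", 0, emg_onset=900.0)
        compute_timing_metrics(e, make_breath())
        assert e.dPon == -100.0 and e.pct_ti_on == -10.0

    def test_missing_event_leaves_metrics_missing(self):
        e = MuscleEvent("scalene", 0, emg_onset=None, emg_offset=2100.0)
        compute_timing_metrics(e, make_breath())
        assert e.dPon is None and e.pct_ti_on is None and e.duration is None
        assert e.dPoff is not None

    def test_duration_identity(self):
        # duration = dPoff - dPon + Ti whenever all terms exist
        rng = np.random.default_rng(4)
        for _ in range(20):
            on = 1000.0 + rng.uniform(-300, 300)
            off = 2000.0 + rng.uniform(-300, 600)
            e = MuscleEvent("scalene", 0, emg_onset=on, emg_offset=off)
            b = make_breath()
            compute_timing_metrics(e, b)
            assert e.duration == pytest.approx(e.dPoff - e.dPon + b.ti, abs=1e-9)

    def test_pct_metrics_shift_invariant(self):
        shift = 12345.0
        e1 = MuscleEvent("scalene", 0, emg_onset=900.0, emg_offset=2300.0)
        e2 = MuscleEvent("scalene", 0, emg_onset=900.0 + shift,
                         emg_offset=2300.0 + shift)
        compute_timing_metrics(e1, make_breath())
        compute_timing_metrics(e2, make_breath(insp_onset=1000.0 + shift))
        assert e1.pct_ti_on == pytest.approx(e2.pct_ti_on)
        assert e1.pct_ti_off == pytest.approx(e2.pct_ti_off)

    def test_pressure_basis(self):
        b = make_breath(pm_onset=850.0, t_peak_pm=1500.0)
        e = MuscleEvent("scalene", 0, emg_onset=900.0, emg_offset=2300.0)
        compute_timing_metrics(e, b)
        assert e.dPon_pm == pytest.approx(50.0)
        ti_pm = b.insp_offset - b.pm_onset
        assert e.pct_ti_on_pm == pytest.approx(50.0 / ti_pm * 100.0)
        assert e.onset_to_peak_pm == pytest.approx(600.0)

    def test_pressure_basis_missing_pm(self):
        e = MuscleEvent("scalene", 0, emg_onset=900.0)
        compute_timing_metrics(e, make_breath())
        assert e.dPon_pm is None and e.pct_ti_on_pm is None


class TestWindows:
    def test_isotime_rounding_rule(self):
        assert isotime_minutes([20.4, 18.2, 25.0]) == 18

    def _frames(self, n_breaths=50, period_ms=6000.0, dpon=-120.0):
        breaths = pd.DataFrame({
            "breath_index": np.arange(n_breaths),
            "insp_onset": 1000.0 + period_ms * np.arange(n_breaths),
            "insp_offset": 2500.0 + period_ms * np.arange(n_breaths),
            "ti": 1500.0, "ttot": period_ms, "fr": 60000.0 / period_ms,
            "peak_flow": 1.0, "vt": 0.6, "peak_pm": -50.0,
        })
        metrics = pd.DataFrame({
            "muscle": "scalene", "breath_index": np.arange(n_breaths),
            "dPon": dpon, "dPoff": 150.0, "pct_ti_on": dpon / 15.0,
            "pct_ti_off": 10.0, "duration": 1770.0, "pct_ti_duration": 118.0,
            "dPon_pm": np.nan, "pct_ti_on_pm": np.nan, "onset_to_peak_pm": np.nan,
        })
        return metrics, breaths

    def test_constant_metric_constant_bins(self):
        metrics, breaths = self._frames()
        out = summarize_windows(metrics, breaths, isotime_min=4.0)
        sel = out[(out["variable"] == "dPon") & (out["muscle"] == "scalene")
                  & (out["window"] != "task_failure")]
        assert len(sel) == 2  # 4 min of data -> two 2-min bins
        assert np.allclose(sel["mean"], -120.0)
        assert np.allclose(sel["sd"], 0.0)

    def test_ten_minute_session_five_bins(self):
        metrics, breaths = self._frames(n_breaths=99)  # ~10 min at 10/min
        out = summarize_windows(metrics, breaths)
        bins = [w for w in out["window"].unique() if w != "task_failure"]
        assert len(bins) == 5
        n_per_bin = out[(out["variable"] == "dPon")
                        & (out["window"] == bins[1])]["n"].iloc[0]
        assert 18 <= n_per_bin <= 21

    def test_task_failure_window_present(self):
        metrics, breaths = self._frames()
        out = summarize_windows(metrics, breaths)
        tf = out[out["window"] == "task_failure"]
        assert not tf.empty
        assert not tf[tf["variable"] == "dPon"]["empty"].iloc[0]

    def test_empty_bin_flagged_not_dropped(self):
        metrics, breaths = self._frames(n_breaths=5)  # 30 s of breaths
        # claim a 4-min isotime: later bins have no breaths
        out = summarize_windows(metrics, breaths, isotime_min=4.0,
                                session_duration_ms=240_000.0)
        late = out[(out["window"] == "min_2_4") & (out["variable"] == "dPon")]
        assert not late.empty
        assert bool(late["empty"].iloc[0])
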