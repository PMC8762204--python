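# Methods

`respitiming` detects the onset and offset of respiratory-muscle surface-EMG
activity breath by breath, with one-sample (±1 ms at 1000 Hz) resolution,
and computes the timing metrics and agreement statistics used to validate
such detections against human raters. This note describes the processing
model, its assumptions, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Signal model and processing chain

A session is a set of synchronously sampled channels (default 1000 Hz):
surface EMG of up to four inspiratory muscles (diaphragm/intercostal,
scalene, parasternal intercostal, sternocleidomastoid; µV), ECG (mV),
airflow (L/s, inspiration positive), and optionally mouth pressure
(Pm, cmH2O). Each EMG channel is conditioned in three steps, all of which
preserve sample count and timebase:

1. **Zero-phase high-pass.** A 2nd-order Butterworth high-pass at 20 Hz is
   applied forward and backward (`sosfiltfilt`, odd-symmetric padding of 3×
   the section length). Forward-backward application squares the magnitude
   response — gain |H(ω)|² = (ω/ωc)⁴ / (1 + (ω/ωc)⁴) for this order — and
   cancels the phase response, so no spectral component is lagged or led
   and event timing is unaffected. A causal filter would delay low-frequency
   envelope energy by tens of milliseconds, directly biasing onsets.

2. **Adaptive ECG removal (NLMS).** ECG artifact couples strongly into
   chest-wall EMG electrodes. A normalized least-mean-squares filter
   (length 120 samples ≈ one QRS complex at 1000 Hz; step size µ = 0.05)
   learns the linear mapping from the time-aligned ECG reference onto the
   artifact in each EMG channel and subtracts its prediction sample by
   sample. Nothing is excised, unlike QRS-gating approaches that cut
   0.10–0.12 s holes in the signal and can shift apparent onsets by the
   same amount. The reference is high-passed identically to the EMG before
   adaptation so both share a spectral baseline, and adaptation state never
   carries across calls.

   *Regularization.* The normalized update divides by the reference window
   energy, which for an ECG reference is near zero between beats; an
   unregularized NLMS therefore takes enormous steps exactly where there is
   no artifact to learn, pumping noise into the output (we measured +44%
   output RMS on an uncorrelated input). The denominator is floored at
   δ = 0.1 · L · mean(x²) — a fixed fraction of the reference's average
   window energy — which confines adaptation to artifact-rich segments
   (uncorrelated pass-through +0.8%; pure-artifact residual < 5% of input
   RMS after the first seconds of adaptation).

3. **RMS envelope.** A centered moving root-mean-square, default 50 ms
   (configurable 10–250 ms). The window length trades ripple (see below)
   against temporal smearing; centered windows add no systematic onset
   bias, unlike trailing windows which delay the envelope by half a window.

## Breath segmentation

Inspiratory onsets are found on the flow channel: a crossing of a small
positive threshold (2% of the session's median per-breath peak flow,
floored at 0.02 L/s) back-tracked to the preceding zero-crossing. A pure
zero-crossing rule is noise-fragile; the threshold-then-backtrack rule is
robust yet lands within ~1 ms of the true start for realistic flow slopes.
The inspiratory offset is the return of flow to the zero band. Candidates
shorter than 200 ms (Ti) or integrating to less than 0.05 L (vt, trapezoidal
integral of inspiratory flow) are rejected as blips; candidates starting
within 300 ms of the previous offset are merged into it. All thresholds are
configurable; a flag inverts the sign convention for reversed pneumotachs.

Pressure-based inspiratory onsets (for loaded breathing, where the EMG-to-
flow delay includes the time needed to overcome the load) are the first
deflection of Pm from its local pre-inspiratory baseline exceeding
2 cmH2O, searched from 1 s before the flow onset; the deflection magnitude
is used, so transducer polarity does not matter.

## Onset and offset detection

The first derivative of the envelope (smoothed by a 25 ms centered mean;
a derivative sign must persist ≥ 25 ms) partitions it into rising and
descending phases. Working on derivative sign rather than absolute level
matters because baseline EMG differs between subjects and the envelope
does not always return to baseline between bursts.

Raw sign segmentation fragments a sustained burst: the RMS of a
noise-driven EMG signal ripples with relative SD ≈ 1/√(4·B·T) (≈ 11% for a
430 Hz bandwidth and a 50 ms window), so a single burst plateau yields many
small alternating phases. Adjacent phases are therefore fused when the
trough between them retains at least half of the smaller adjacent
peak-to-trough excursion — ripples on one burst merge, while a genuine
return toward baseline between bursts fails the test and keeps bursts
separate. Phases whose rise amplitude falls below 3× the envelope SD over
the session's quietest second are discarded as undetectable, mirroring a
human rater's "NA".

Each breath searches a window from the midpoint of the preceding expiration
to its inspiratory offset. A rising phase is eligible when its rising
interval overlaps the window — the peak itself may fall after the
inspiratory offset, since inspiratory-muscle activity routinely outlasts
the inspiratory airflow. Among eligible phases the greatest envelope peak
wins; ties go to the peak nearest the inspiratory onset.

* **Onset** = earliest time in the rising phase at which the envelope
  reaches baseline + 5% of the rise (baseline = envelope at the rise
  start, rise = peak − baseline). Referencing the threshold to the rise —
  rather than to the absolute peak — is what keeps baseline variability
  from being read as activation; a config switch
  (`onset_reference: rise|peak`) selects the absolute-peak reading.
* **Offset** = earliest *durable* drop of 30% from the phase's peak: the
  first post-peak crossing below 70% of peak after which the envelope does
  not rise back above the threshold within the search window (up to the
  next breath's window). On a monotone descent this is exactly the first
  crossing; on a rippled plateau it rejects transient dips that would end
  the burst hundreds of milliseconds early. The 30%-drop criterion is the
  conventional cycling-off rule for inspiratory EMG.

Thresholds crossed exactly at a sample take that sample's time (earliest-
crossing convention). A breath with no qualifying phase yields a missing
event, and every metric that depends on it stays missing.

## Timing metrics

Per breath and muscle, with all times in ms:

    dPon  = EMG,onset  − INSP,onset
    dPoff = EMG,offset − INSP,offset
    %Ti,on  = dPon  / Ti × 100
    %Ti,off = dPoff / Ti × 100
    duration = EMG,offset − EMG,onset        %Ti,duration = duration / Ti × 100

Zero indicates synchrony; negative values mean the EMG change preceded the
reference signal. The identity duration = dPoff − dPon + Ti holds whenever
all terms exist. The pressure-based variants use pm_onset as the reference
and Ti(pm) = INSP,offset − pm_onset; onset-to-peak-pressure is the time
from EMG onset to the breath's peak Pm deflection.

Windowed summaries average every metric in 2-minute bins from the session
start up to isotime, plus a task-failure window covering the final
2 minutes (which may overlap the last bin). Isotime across participants is
the minimum session duration after rounding each to the nearest minute
(half-up). Empty bins are flagged, never silently dropped.

## Agreement statistics

The intraclass correlation is the two-way mixed-effects, single-rater form
computed from the two-way ANOVA mean squares. The default is the
consistency form, ICC(3,1) = (MSR − MSE) / (MSR + MSE) for two raters:
the raters (algorithm, human assessors) are fixed, and a systematic offset
between them is reported separately as the Bland–Altman bias rather than
folded into the ICC. An `agreement` switch selects the absolute-agreement
form. The p-value is the F test of MSR against MSE. Reliability bands:
poor < 0.5 ≤ moderate < 0.75 ≤ good < 0.9 ≤ excellent (boundary values go
to the higher band). Bland–Altman bias is the mean paired difference with
95% limits at ±1.96 SD of the differences. Pairs with a missing member are
dropped pairwise and their count reported. Agreement should be computed on
phase differences (dP), not absolute session times — between-breath spacing
would otherwise inflate any ICC to ≈ 1; `relative_to_breaths` performs the
conversion. Pearson correlations carry the conventional strength labels
(small 0.1–0.3, medium 0.3–0.5, large 0.5–1 on |r|).

## The synthetic-session generator

The generator emulates a paced inspiratory-threshold-loading recording so
every stage is testable without external data: half-sine inspiratory flow
pulses at 10 breaths/min (Ti 1.5 s); per-muscle bursts whose onsets lead
the flow onset by 50–150 ms with per-breath Gaussian jitter of 35–50 ms
(largest for the diaphragm/intercostal channel, which is the most variable
in practice); a sum-of-Gaussians QRS template (110 ms wide, 75 bpm —
deliberately incommensurate with the breathing rate so QRS-onset
collisions occur in a known fraction of breaths) coupled at 50–200 µV/mV
into the EMG channels; rounded-square mouth-pressure pulses of 50 cmH2O
leading the flow by 150 ms with 5 ms edges (a threshold valve opens
abruptly); and white baseline noise. All randomness flows from one seeded
generator; identical seed and spec give bit-identical output.

Burst envelopes are trapezoids: linear rise (default 200 ms), plateau,
linear fall (200 ms), total 1.8 s — activity outlasting Ti, as observed
under load. Two carriers are available:

* `carrier='noise'` (default): band-limited Gaussian noise, 20–450 Hz,
  unit RMS — realistic surface EMG, whose windowed RMS ripples ±10–20%.
* `carrier='sine'`: a unit-RMS sinusoid at 100 Hz (whole periods per 50 ms
  window), i.e. a constant-envelope carrier whose RMS trace is
  deterministic. This is the genuinely noise-free condition used for
  exact-recovery checks.

**Ground-truth conventions and the rise-time choice.** `true_onset` is the
programmed burst start — the instant activity begins, which the 5% rise
threshold is designed to approximate. `true_offset` is the analytic
30%-drop time on the ideal trapezoid (fall start + 0.3 × fall time),
because the offset criterion intentionally marks a point inside the decay.
For a linear rise of duration R seen through a centered RMS window of
width W, the expected 5%-of-rise crossing of the windowed envelope lies at
(0.0075 · R² · W)^⅓ − W/2 relative to the burst start: the window's
look-ahead cancels the threshold's delay when W ≈ R/4. With the detector's
default W = 50 ms, the default R = 200 ms makes the recovered onset an
essentially unbiased estimate of the truth (−0.3 ms analytically; ±1 ms
measured); R = 200 ms is also the physiological scale of inspiratory
recruitment ramps. On noise-carrier sessions the residual ±15 ms median
onset bias comes from ripple inflating the measured peak and the noise
floor raising the absolute threshold — intrinsic behaviour of a 5%-of-rise
rule on noisy envelopes, not an implementation artifact.

The generator does **not** emulate: motor-unit structure or firing
statistics, fatigue-induced spectral compression, electrode motion
artifacts, crosstalk between muscles, baseline wander, or breath-to-breath
flow-shape variability beyond amplitude jitter. Passing recovery tests on
synthetic sessions therefore demonstrates the correctness and calibration
of the detection chain, not its field performance on pathological signals.

An assessor emulator perturbs truth onsets/offsets with Gaussian error and
random misses to exercise the agreement machinery; with 30 ms rater error
and realistic onset jitter, algorithm-vs-rater ICCs land in the
moderate-to-excellent range typical of human inter-rater comparisons.

## Numerical choices and degenerate inputs

* Windows are converted to samples by rounding; the derivative-smoothing
  window is forced odd so the centered mean is symmetric.
* Derivative sign uses a deadband of 1e-12 × the envelope maximum; exact
  plateaus count as flat, so a constant envelope yields no phases and a
  flat channel yields missing events rather than errors.
* All-zero or all-expiratory flow yields an empty breath list, not an
  error. Mismatched channel lengths, non-finite samples, and invalid spec
  values raise immediately with the offending quantity named.
* ICC mean squares clamp a catastrophically cancelled residual (MSE below
  1e-12 of the larger mean squares) to zero so that identical series give
  ICC = 1 and p = 0 rather than NaN. Zero variance in both series is
  undefined and flagged.
* Session text files are written with 9 significant digits; write-read
  round trips are exact to ≤ 1e-6 relative error per sample. Event tables
  write missing times as the literal `NA`.

## Problem sizes

Default verification sizes: 10-minute sessions (100 breaths × 4 muscles)
for end-to-end recovery, 60–300 s sessions for unit and property tests.
The full suite runs in about half a minute on one CPU; the acceptance
script in about ten seconds.

## Known limitations

* The NLMS canceller assumes the artifact is a (slowly varying) linear
  filtering of the ECG reference; heavy electrode motion or reference
  saturation violates this.
* Onset detection on noise-carrier envelopes carries a small positive
  median bias (~15 ms at realistic contamination) from envelope ripple;
  narrower RMS windows reduce smearing but increase ripple, and vice
  versa.
* The 5%-of-rise interpretation is the baseline-referenced reading; the
  absolute-peak reading is available but shifts onsets on elevated
  baselines.
* Agreement machinery assumes a shared breath universe between sources;
  it aligns on breath indices, not on times.
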