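# Analysis configuration for `respitiming detect`.
# channels: maps roles to the column names (or 0-based indices) of the
# delimited text export. At least one muscle and a flow channel are
# required; ecg enables adaptive artifact removal, pm enables
# pressure-based onsets.
channels:
  time: time
  diaphragm_intercostal: diaphragm_intercostal
  scalene: scalene
  parasternal: parasternal
  sternocleidomastoid: sternocleidomastoid
  ecg: ecg
  flow: flow
  pm: pm

sampling_rate: 1000.0
skip_header: 0          # extra header lines before the column row
ecg_removal_enabled: true

filter:                 # zero-phase Butterworth high-pass
  cutoff_hz: 20.0
  order: 2

ecg_removal:            # normalized LMS canceller
  filter_length: 120    # samples; spans one QRS complex at 1000 Hz
  step_size: 0.05

envelope:
  window_ms: 50.0       # moving-RMS window
  centered: true

breaths:
  min_ti_ms: 200.0
  min_vt_l: 0.05
  inspiration_positive: true

detection:
  onset_fraction: 0.05  # onset at 5% of the breath-wise envelope rise
  offset_drop: 0.30     # offset when the envelope drops 30% from its peak
  onset_reference: rise # or "peak" for the absolute-peak reading
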