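"""Adaptive ECG-artifact removal and its effect on onset accuracy.

Shows the NLMS canceller shrinking the ECG artifact in a contaminated EMG
channel without deleting any samples, and the resulting improvement in
onset-detection error when contamination is strong.
"""

import numpy as np

from respitiming import (AnalysisConfig, analyze_session, default_sim_spec,
                         highpass_bidirectional, lms_ecg_removal,
                         simulate_session)

spec = default_sim_spec(duration_s=180.0, seed=3)
spec.ecg.coupling_uv_per_mv = {m: 500.0 for m in spec.muscles}  # heavy artifact
recording, truth = simulate_session(spec)

emg = highpass_bidirectional(recording["diaphragm_intercostal"])
ref = highpass_bidirectional(recording["ecg"])
cleaned = lms_ecg_removal(emg, ref)
quiet = slice(4000, 5500)  # expiratory window: artifact + noise only
before = np.sqrt(np.mean(emg.values[quiet] ** 2))
after = np.sqrt(np.mean(cleaned.values[quiet] ** 2))
print(f"expiratory-window RMS: {before:.1f} uV before, {after:.1f} uV after "
      f"removal ({100 * (1 - after / before):.0f}% artifact suppressed)")
print(f"samples in = samples out: {len(emg)} == {len(cleaned)}")

for lms in (False, True):
    res = analyze_session(recording, AnalysisConfig(ecg_removal_enabled=lms))
    m = res.events.merge(truth.events, on=["muscle", "breath_index"])
    err = (m["emg_onset"] - m["true_onset"]).dropna()
    print(f"median |onset error| with ECG removal {'on ' if lms else 'off'}: "
          f"{np.median(np.abs(err)):5.1f} ms")
# the canceller restores millisecond-scale onset detection that heavy QRS
# contamination would otherwise corrupt.
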