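# respitiming

Millisecond-accurate, semi-automated timing of respiratory-muscle surface
EMG activity.

Respiratory physiologists routinely ask not just *how strongly* an
inspiratory muscle is activated but *when*: does the diaphragm fire before
or after the scalene, does activation precede inspiratory flow, and does
that coordination change under load or disease? Answering those questions
by eyeballing EMG traces is slow and subjective. `respitiming` implements
an objective pipeline for multi-muscle recordings (diaphragm/intercostal,
scalene, parasternal intercostal, sternocleidomastoid + ECG + airflow +
mouth pressure, sampled at 1000 Hz):

1. **zero-phase filtering** — bidirectional 2nd-order Butterworth high-pass
   at 20 Hz, so no spectral component is lagged or led;
2. **adaptive ECG removal** — a normalized LMS filter learns the artifact
   from the time-aligned ECG channel and subtracts it *without deleting any
   samples*, avoiding the 0.10–0.12 s timing holes of QRS-gating methods;
3. **RMS envelope** (centered 50 ms window) and **derivative-based phase
   segmentation** into rising/descending phases, robust to baseline level;
4. **event detection** — per breath, EMG onset at 5% of the envelope rise
   (EMG,onset) and offset at a durable 30% drop from the peak (EMG,offset),
   both at ±1 ms resolution;
5. **breath segmentation** from airflow (INSP,onset / INSP,offset, Ti,
   Ttot, peak flow, tidal volume) and optional pressure-based onsets;
6. **timing metrics** per breath and muscle:

       dPon  = EMG,onset  − INSP,onset        %Ti,on  = dPon  / Ti × 100
       dPoff = EMG,offset − INSP,offset       %Ti,off = dPoff / Ti × 100

   (zero = synchrony; negative = the muscle leads the airflow), activation
   duration, 2-minute windowed summaries up to isotime and at task failure;
7. **agreement statistics** — two-way mixed-effects ICC (consistency,
   single rater) with poor/moderate/good/excellent bands, Bland–Altman
   bias and 95% limits of agreement, detection counts per source, Pearson
   correlations;
8. a **synthetic-session generator** producing multi-channel recordings
   with exact ground-truth event times, so the entire pipeline is testable
   without any recorded data, plus an assessor emulator for agreement
   experiments.

## Worked example

```python
import numpy as np
from respitiming import (AnalysisConfig, analyze_session,
                         default_sim_spec, simulate_session)

spec = default_sim_spec(duration_s=180.0, seed=2)   # 3 min, 10 breaths/min
recording, truth = simulate_session(spec)
result = analyze_session(recording, AnalysisConfig(ecg_removal_enabled=True))

for muscle, grp in result.metrics.groupby("muscle"):
    print(muscle, grp["dPon"].median(), grp["pct_ti_on"].median())
```

prints (see `examples/02_detect_timing.py`):

```
breaths detected: 30 (truth 30)

per-muscle timing (medians over breaths):
  diaphragm_intercostal  dPon   -35.0 ms  %Ti,on   -2.3%  duration  1601.0 ms
  parasternal            dPon  -107.0 ms  %Ti,on   -7.1%  duration  1614.5 ms
  scalene                dPon  -137.0 ms  %Ti,on   -9.1%  duration  1616.5 ms
  sternocleidomastoid    dPon  -115.0 ms  %Ti,on   -7.7%  duration  1604.5 ms

onset recovery vs truth: median |error| 15.0 ms over 120 bursts
```

Every muscle's EMG onset precedes the inspiratory flow (negative dPon), as
expected when breathing against an inspiratory load — the muscles must
build pressure before flow can start — with the diaphragm/intercostal
firing latest and activity outlasting the inspiratory time. The recovery
line compares detections against the generator's programmed truth under
realistic ECG contamination.

The `examples/` directory holds one short script per capability:
simulation, end-to-end detection, ECG removal, rater agreement, and
windowed summaries. A thin CLI wraps the same library:

```bash
respitiming simulate --seed 1 --out session.txt --truth truth.csv
respitiming detect session.txt --config cfg.yaml --out events.csv
respitiming agree events_A.csv events_B.csv --out agreement.csv
```

where `cfg.yaml` maps channel roles to the columns of the text export and
optionally overrides filter/detection parameters (see
`examples/analysis_config.yaml`).

## Documentation

`docs/methods.md` describes the signal model, every threshold and default
with its rationale, the ground-truth conventions of the generator, and
known limitations.
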