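"""Generate a synthetic loaded-breathing session with ground truth.

Builds a 2-minute recording: four inspiratory muscles at 10 breaths/min,
ECG coupled into every EMG channel, airflow and mouth pressure, plus the
exact programmed event times for every burst.
"""

from respitiming import default_sim_spec, simulate_session

spec = default_sim_spec(duration_s=120.0, seed=1)
recording, truth = simulate_session(spec)

print(f"channels: {sorted(recording.channels)}")
print(f"duration: {recording.duration_s:.0f} s at {recording.sampling_rate:.0f} Hz")
print(f"breaths simulated: {len(truth.breaths)}")
print("\nfirst three ground-truth bursts (times in ms):")
print(truth.events.head(3).to_string(index=False))
# true_onset is when each muscle's activity starts; negative lead vs the
# breath's insp_onset means the muscle fires before inspiratory flow begins.
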