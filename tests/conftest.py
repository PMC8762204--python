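"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from respitiming import (AnalysisConfig, EcgSpec, NoiseSpec, analyze_session,
                         default_sim_spec, simulate_session)


def clean_sim_spec(duration_s=60.0, seed=7, **overrides):
    """Noise-free study condition: deterministic sinusoidal carriers, no
    baseline noise, no ECG coupling."""
    spec = default_sim_spec(duration_s=duration_s, seed=seed,
                            noise=NoiseSpec(0.0, 0.0, 0.0, 0.0),
                            ecg=EcgSpec(coupling_uv_per_mv={}), **overrides)
    for b in spec.muscles.values():
        b.carrier = "sine"
    return spec


@pytest.fixture(scope="session")
def clean_session():
    """60 s noise-free four-muscle session with ground truth."""
    return simulate_session(clean_sim_spec())


@pytest.fixture(scope="session")
def clean_result(clean_session):
    rec, _ = clean_session
    return analyze_session(rec, AnalysisConfig(ecg_removal_enabled=False))


@pytest.fixture(scope="session")
def noisy_session():
    """120 s session with ECG contamination and baseline noise."""
    return simulate_session(default_sim_spec(duration_s=120.0, seed=11))


def merged_errors(result, truth):
    """Join detections to ground truth and return the merged frame."""
    m = result.events.merge(truth.events, on=["muscle", "breath_index"])
    m["onset_error"] = m["emg_onset"] - m["true_onset"]
    m["offset_error"] = m["emg_offset"] - m["true_offset"]
    return m
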