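"""EMG conditioning: zero-phase high-pass, adaptive ECG removal, RMS envelope.

The conditioning chain turns a raw surface-EMG channel into an ECG-free RMS
amplitude envelope on which onset/offset detection operates:

1. bidirectional (forward-backward) 20 Hz 2nd-order Butterworth high-pass —
   zero net phase shift, so event timing is not lagged or led by the filter;
2. normalized least-mean-squares (NLMS) adaptive cancellation of the ECG
   artifact using the time-aligned ECG channel as reference — no samples are
   excised, so the timebase is untouched;
3. centered moving root-mean-square envelope.

Every stage preserves sample count and timebase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .signals import SampledSignal

__all__ = [
    "FilterSpec",
    "LmsSpec",
    "EnvelopeSpec",
    "highpass_bidirectional",
    "lms_ecg_removal",
    "rms_envelope",
    "preprocess_emg",
]


@dataclass
class FilterSpec:
    """Butterworth high-pass settings (defaults: 20 Hz, 2nd order, zero-phase)."""

    cutoff_hz: float = 20.0
    order: int = 2
    bidirectional: bool = True

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.cutoff_hz < sampling_rate / 2:
            raise ValueError("cutoff must lie in (0, Nyquist)")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass
class LmsSpec:
    """Adaptive ECG-canceller settings.

    filter_length spans the artifact's impulse response; the default of 120
    samples covers a full QRS complex (0.10-0.12 s) at 1000 Hz. step_size is
    the NLMS adaptation rate (must be in (0, 2) when normalized).
    regularization sets the NLMS denominator floor as a fraction of the
    reference's average window energy — essential for an ECG reference,
    which is near-silent between beats and would otherwise make normalized
    steps explode there. reference_alignment allows the ECG reference to be
    shifted by up to that many samples to maximize cross-correlation with
    the contaminated EMG before adaptation (0 disables the search).
    """

    filter_length: int = 120
    step_size: float = 0.05
    normalized: bool = True
    regularization: float = 0.1
    reference_alignment: int = 0
    eps: float = 1e-12

    def validate(self) -> None:
        if self.filter_length < 1:
            raise ValueError("filter_length must be >= 1")
        if not self.step_size > 0:
            raise ValueError("step_size must be positive")
        if self.normalized and not self.step_size < 2:
            raise ValueError("normalized LMS requires step_size < 2")


@dataclass
class EnvelopeSpec:
    """Moving-RMS window. Centered by default so the envelope is not skewed
    toward earlier or later times relative to the underlying activity."""

    window_ms: float = 50.0
    centered: bool = True

    def validate(self) -> None:
        if not 0 < self.window_ms <= 500:
            raise ValueError("window_ms must be in (0, 500]")


def _window_samples(window_ms: float, fs: float, odd: bool = True) -> int:
    n = max(1, int(round(window_ms * fs / 1000.0)))
    if odd and n % 2 == 0:
        n += 1
    return n


def highpass_bidirectional(signal: SampledSignal, spec: FilterSpec | None = None) -> SampledSignal:
    """Zero-phase Butterworth high-pass of one channel.

    Forward-backward application squares the magnitude response and cancels
    the phase response, so no spectral component is lagged or led. Edge
    transients are suppressed by odd-symmetric padding.
    """
    spec = spec or FilterSpec()
    spec.validate(signal.sampling_rate)
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="highpass",
                     fs=signal.sampling_rate, output="sos")
    if spec.bidirectional:
        # default sosfiltfilt padding is odd-symmetric extension
        padlen = 3 * (2 * spec.order + 1)
        if len(signal) <= padlen:
            raise ValueError(
                f"signal of {len(signal)} samples too short for stable "
                f"bidirectional filtering (needs > {padlen})")
        out = sps.sosfiltfilt(sos, signal.values, padtype="odd", padlen=padlen)
    else:
        out = sps.sosfilt(sos, signal.values)
    return signal.copy_with(out)


def _nlms_cancel(d: np.ndarray, x: np.ndarray, L: int, mu: float,
                 normalized: bool, regularization: float, eps: float) -> np.ndarray:
    """Sequential (N)LMS: adaptively predict d from the last L samples of x
    and return the prediction error (the cleaned signal)."""
    n = d.size
    # xmat[i] = x[i-L+1 .. i] (zero-padded before t=0), newest sample last
    xp = np.concatenate([np.zeros(L - 1), x])
    xmat = np.lib.stride_tricks.sliding_window_view(xp, L)
    w = np.zeros(L)
    out = np.empty(n)
    if normalized:
        energies = np.einsum("ij,ij->i", xmat, xmat)
        delta = regularization * L * float(np.mean(x ** 2)) + eps
        for i in range(n):
            xi = xmat[i]
            e = d[i] - w @ xi
            out[i] = e
            w += (mu / (delta + energies[i])) * e * xi
    else:
        for i in range(n):
            xi = xmat[i]
            e = d[i] - w @ xi
            out[i] = e
            w += mu * e * xi
    return out


def lms_ecg_removal(emg: SampledSignal, ecg: SampledSignal,
                    spec: LmsSpec | None = None) -> SampledSignal:
    """Remove ECG artifact from an EMG channel by NLMS adaptive cancellation.

    The canceller learns, sample by sample, the linear filter mapping the
    ECG reference onto the artifact present in the EMG channel and subtracts
    its prediction. The cleaned output has identical length — no part of the
    EMG signal is deleted, unlike gating/excision approaches that can shift
    apparent onset times by the width of a QRS complex. Adaptation state is
    reset on every call.
    """
    spec = spec or LmsSpec()
    spec.validate()
    if len(emg) != len(ecg):
        raise ValueError("emg and ecg must have equal length")
    if emg.sampling_rate != ecg.sampling_rate:
        raise ValueError("emg and ecg must share sampling_rate")
    x = ecg.values
    d = emg.values
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(d))):
        raise ValueError("non-finite samples in input")
    if spec.reference_alignment > 0:
        x = _align_reference(d, x, spec.reference_alignment)
    out = _nlms_cancel(d, x, spec.filter_length, spec.step_size,
                       spec.normalized, spec.regularization, spec.eps)
    return emg.copy_with(out)


def _align_reference(d: np.ndarray, x: np.ndarray, max_lag: int) -> np.ndarray:
    """Shift the reference by the integer lag (|lag| <= max_lag) maximizing
    its cross-correlation with the target; zero-pad the exposed edge."""
    lags = np.arange(-max_lag, max_lag + 1)
    cc = [np.dot(np.roll(x, k), d) for k in lags]
    best = int(lags[int(np.argmax(cc))])
    shifted = np.roll(x, best)
    if best > 0:
        shifted[:best] = 0.0
    elif best < 0:
        shifted[best:] = 0.0
    return shifted


def rms_envelope(signal: SampledSignal, spec: EnvelopeSpec | None = None) -> SampledSignal:
    """Moving RMS amplitude envelope, same length and timebase as the input."""
    spec = spec or EnvelopeSpec()
    spec.validate()
    n = _window_samples(spec.window_ms, signal.sampling_rate, odd=False)
    if n < 3:
        raise ValueError("RMS window must span at least 3 samples")
    if n > len(signal):
        raise ValueError("RMS window longer than the signal")
    sq = signal.values ** 2
    origin = 0 if spec.centered else (n - 1) // 2  # trailing window when causal
    ms = uniform_filter1d(sq, size=n, mode="nearest", origin=origin)
    return signal.copy_with(np.sqrt(np.maximum(ms, 0.0)))


def preprocess_emg(emg: SampledSignal, ecg: SampledSignal | None = None,
                   filter_spec: FilterSpec | None = None,
                   lms_spec: LmsSpec | None = None,
                   envelope_spec: EnvelopeSpec | None = None) -> SampledSignal:
    """Full conditioning chain: high-pass -> (optional) ECG removal -> RMS.

    The ECG reference receives the same high-pass as the EMG channel before
    adaptation so both share a spectral baseline.
    """
    filt = highpass_bidirectional(emg, filter_spec)
    if ecg is not None:
        ref = highpass_bidirectional(ecg, filter_spec)
        filt = lms_ecg_removal(filt, ref, lms_spec)
    return rms_envelope(filt, envelope_spec)
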