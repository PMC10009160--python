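"""Signal conditioning and envelope extraction.

The force model regresses on the *envelope* of each muscle's surface EMG:
the slowly varying amplitude obtained by full-wave rectifying the
band-pass-conditioned EMG and low-pass filtering it (2nd-order zero-lag
Butterworth, 2 Hz cutoff by default, appropriate for slow/quasi-static
contractions). When a muscle is recorded with several channels, the
per-sample median envelope across channels serves as the muscle's
representative envelope.

All zero-lag filtering is forward-backward (``scipy.signal.filtfilt``) with
reflective padding, so no group delay is introduced between EMG and force.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .signals import DataError, Envelope, FilterSpec, SignalMatrix

__all__ = [
    "butterworth_filter",
    "full_wave_rectify",
    "estimate_envelope",
    "median_envelope",
    "condition_force",
]


def _design(spec: FilterSpec, fs: float):
    spec.validate_against(fs)
    wn = np.array(spec.cutoffs_hz) / (fs / 2.0)
    btype = "bandpass" if spec.kind == "bandpass" else "lowpass"
    return sps.butter(spec.order, wn if wn.size > 1 else wn[0], btype=btype)


def butterworth_filter(sig: SignalMatrix, spec: FilterSpec) -> SignalMatrix:
    """Apply a Butterworth filter per channel.

    With ``spec.zero_lag`` the stated-order design is run forward and
    backward (zero net phase; magnitude response squared). Reflective
    padding of 3*(order+1) samples suppresses startup transients, falling
    back to the longest admissible padding on short signals.
    """
    b, a = _design(spec, sig.fs)
    x = sig.data
    if spec.zero_lag:
        padlen = min(3 * (spec.order + 1), x.shape[0] - 1)
        y = sps.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)
    else:
        y = sps.lfilter(b, a, x, axis=0)
    return sig.with_data(y)


def full_wave_rectify(sig: SignalMatrix) -> SignalMatrix:
    """Elementwise absolute value of the signal.

    Rectification by |x| (rather than x^2) is the amplitude demodulator of
    choice for EMG whose amplitude distribution is centrally peaked
    (Laplacian-like), and has lower variance than squaring.
    """
    return sig.with_data(np.abs(sig.data))


def estimate_envelope(sig: SignalMatrix, cutoff_hz: float = 2.0) -> SignalMatrix:
    """Envelope of a band-pass-conditioned EMG: rectify, then 2nd-order
    zero-lag Butterworth low-pass at ``cutoff_hz``, clipped at zero.

    The low-pass can ring slightly below zero near sharp amplitude onsets;
    negative excursions are clipped so the result is a valid envelope (and
    safe for the log transform downstream).
    """
    spec = FilterSpec(kind="lowpass", order=2, cutoffs_hz=(cutoff_hz,), zero_lag=True)
    smoothed = butterworth_filter(full_wave_rectify(sig), spec)
    return sig.with_data(np.clip(smoothed.data, 0.0, None))


def median_envelope(envelopes: SignalMatrix) -> Envelope:
    """Per-sample median across envelope channels of one muscle.

    For an even channel count the mean of the two middle order statistics is
    used (the standard median convention). A single channel is returned
    unchanged.
    """
    if envelopes.n_channels < 1 or envelopes.n_samples < 1:
        raise DataError("median_envelope needs at least one channel of data")
    if np.any(envelopes.data < 0):
        raise DataError("envelope channels must be nonnegative")
    med = np.median(envelopes.data, axis=1)
    return Envelope(values=med, fs=envelopes.fs, muscle_id=envelopes.muscle_id or "")


def condition_force(force: SignalMatrix, cutoff_hz: float = 1.0) -> SignalMatrix:
    """Condition the measured force/target: zero-lag 4th-order Butterworth
    low-pass at ``cutoff_hz`` (default 1 Hz)."""
    spec = FilterSpec(kind="lowpass", order=4, cutoffs_hz=(cutoff_hz,), zero_lag=True)
    return butterworth_filter(force, spec)


def extract_muscle_envelope(
    emg: SignalMatrix,
    cutoff_hz: float = 2.0,
    channel: int | None = None,
) -> Envelope:
    """Full envelope recipe for one muscle's (conditioned) EMG channels.

    Computes per-channel envelopes and reduces them to one representative
    envelope: the per-sample median across channels, or — when ``channel``
    is given — the envelope of that single channel.
    """
    env = estimate_envelope(emg, cutoff_hz=cutoff_hz)
    if channel is not None:
        return Envelope(env.data[:, channel], fs=emg.fs, muscle_id=emg.muscle_id or "")
    return median_envelope(env)
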