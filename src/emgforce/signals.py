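"""Core signal containers.

A recording session is a set of time-aligned, uniformly sampled signals:
multi-channel surface EMG per muscle and a scalar force (or force-like)
target. Everything downstream — filtering, envelope extraction, model
fitting — passes these containers around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DataError(ValueError):
    """Raised when input data violate a container invariant (non-finite
    values, empty matrices, negative envelopes, ...)."""


class AlignmentError(ValueError):
    """Raised when signals that must share length/sampling rate do not."""


@dataclass
class SignalMatrix:
    """Uniformly sampled multi-channel signal (N samples x C channels).

    Parameters
    ----------
    data : ndarray, shape (N, C) or (N,)
        Sample values; a 1-D array is promoted to a single column.
    fs : float
        Sampling rate in Hz, > 0.
    channel_labels : list of str, optional
    muscle_id : str, optional
        Identifier of the muscle the channels were recorded from.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] | None = None
    muscle_id: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise DataError(f"signal must be a nonempty N x C matrix, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise DataError("signal contains non-finite values")
        if not self.fs > 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_labels is not None and len(self.channel_labels) != arr.shape[1]:
            raise DataError("channel_labels length does not match channel count")
        self.data = arr

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def column(self, j: int) -> np.ndarray:
        return self.data[:, j]

    def with_data(self, data: np.ndarray) -> "SignalMatrix":
        """Copy of this container carrying new sample values."""
        return SignalMatrix(data, self.fs, self.channel_labels, self.muscle_id)


@dataclass
class Envelope:
    """Per-muscle representative sEMG envelope: a nonnegative time series.

    This is the regressor of the force model — the low-pass-filtered,
    full-wave-rectified EMG amplitude of one muscle.
    """

    values: np.ndarray
    fs: float
    muscle_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 1:
            raise DataError("envelope must be nonempty")
        if not np.all(np.isfinite(v)):
            raise DataError("envelope contains non-finite values")
        if np.any(v < 0):
            raise DataError("envelope values must be nonnegative")
        if not self.fs > 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        self.values = v

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FilterSpec:
    """Butterworth filter specification.

    ``order`` is the order of the underlying design; when ``zero_lag`` is
    true the filter is applied forward and backward (zero net phase, squared
    magnitude response).
    """

    kind: str  # {"bandpass", "lowpass"}
    order: int
    cutoffs_hz: tuple[float, ...]
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be a positive integer")
        cut = tuple(float(c) for c in np.atleast_1d(self.cutoffs_hz))
        n_expected = 2 if self.kind == "bandpass" else 1
        if len(cut) != n_expected:
            raise ValueError(f"{self.kind} filter needs {n_expected} cutoff(s), got {len(cut)}")
        if any(c <= 0 for c in cut):
            raise ValueError("cutoff frequencies must be positive")
        if self.kind == "bandpass" and not cut[0] < cut[1]:
            raise ValueError("bandpass edges must be strictly increasing")
        self.cutoffs_hz = cut

    def validate_against(self, fs: float) -> None:
        nyq = fs / 2.0
        if any(c >= nyq for c in self.cutoffs_hz):
            raise ValueError(
                f"cutoff(s) {self.cutoffs_hz} must lie below the Nyquist frequency {nyq} Hz"
            )


# Band-pass presets matching the two recording configurations the model was
# developed for: lower-limb bipolar recordings (15-350 Hz) and upper-limb
# monopolar high-density grids (20-450 Hz), both 4th-order designs.
LOWER_LIMB_BANDPASS = FilterSpec(kind="bandpass", order=4, cutoffs_hz=(15.0, 350.0))
UPPER_LIMB_BANDPASS = FilterSpec(kind="bandpass", order=4, cutoffs_hz=(20.0, 450.0))

DEFAULT_FS = 2048.0
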