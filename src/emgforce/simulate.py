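"""Synthetic multi-muscle sEMG and force generation.

The generator emulates the statistical structure the force model assumes:
each muscle's EMG channel is a band-limited (15-450 Hz by default)
stochastic carrier — band-pass-filtered white noise, Laplacian by default
because measured sEMG amplitude distributions are centrally peaked —
amplitude-modulated by a slow nonnegative activation profile (force ramps
to a set of %MVC targets, sway-like slow drifts, or constant effort). The
force target is the log-linear model itself applied to the true profiles,
plus white noise scaled to a fraction of the force range. The true weights
travel with the dataset, so parameter-recovery tests have an exact oracle.

What this does *not* emulate: motor-unit structure (recruitment, firing
statistics, action-potential shapes), electrode geometry, crosstalk, or
electromechanical delay. It is a test harness for the estimator, not a
physiological simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .model import RELATIVE_EPSILON
from .signals import DataError, Envelope, FilterSpec, SignalMatrix

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_profile", "generate_emg", "generate_force", "make_dataset"]

_UPPER_LIMB_MUSCLES = ["BB", "BR", "TBL", "TBM"]  # biceps, brachioradialis, triceps lat/med


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic recording.

    Defaults follow the recording setup the model targets: 2048 Hz
    sampling, 15-450 Hz Laplacian carriers, four muscles (the elbow
    flexor/extensor roster) with eight channels each, ramp profiles to
    30/50/70 %MVC over a 0.05 resting tone, signed true weights
    (antagonists pull the force negative), and force noise at 5% of the
    force range.
    """

    n_muscles: int = 4
    n_channels_per_muscle: int = 8
    fs: float = 2048.0
    duration_s: float = 20.0
    carrier_band_hz: tuple[float, float] = (15.0, 450.0)
    carrier_dist: str = "laplacian"  # or "gaussian"
    profile: str = "ramp"  # {"ramp", "sway", "constant"}
    mvc_levels: tuple[float, ...] = (0.3, 0.5, 0.7)
    baseline: float = 0.05
    true_weights: tuple[float, ...] | None = None
    noise_sd: float = 0.05
    seed: int = 0
    muscle_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_muscles < 1 or self.n_channels_per_muscle < 1:
            raise DataError("need at least one muscle and one channel")
        lo, hi = self.carrier_band_hz
        if not (0 < lo < hi < self.fs / 2):
            raise DataError("carrier band must lie inside (0, fs/2)")
        if self.duration_s * self.fs < 100:
            raise DataError("recording too short (< 100 samples)")
        if self.carrier_dist not in ("gaussian", "laplacian"):
            raise DataError(f"unknown carrier distribution {self.carrier_dist!r}")
        if self.profile not in ("ramp", "sway", "constant"):
            raise DataError(f"unknown profile mode {self.profile!r}")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be nonnegative")
        if self.true_weights is None:
            # alternating agonist/antagonist weights, intercept 1.0
            w = [1.0] + [(2.0 if i % 2 == 0 else -1.0) * (1.0 + 0.25 * i) for i in range(self.n_muscles)]
            self.true_weights = tuple(w)
        if len(self.true_weights) != self.n_muscles + 1:
            raise DataError(
                f"true_weights needs {self.n_muscles + 1} entries (w0 + one per muscle)"
            )
        if not self.muscle_ids:
            if self.n_muscles == 4:
                self.muscle_ids = list(_UPPER_LIMB_MUSCLES)
            else:
                self.muscle_ids = [f"m{i + 1}" for i in range(self.n_muscles)]
        if len(self.muscle_ids) != self.n_muscles:
            raise DataError("muscle_ids length must equal n_muscles")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class SyntheticDataset:
    emg: list[SignalMatrix]
    true_envelopes: list[Envelope]
    force: SignalMatrix
    config: SyntheticConfig

    @property
    def true_weights(self) -> np.ndarray:
        return np.asarray(self.config.true_weights, dtype=float)


def _child_seeds(seed: int, n: int, tag: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence([seed, tag])
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def generate_profile(config: SyntheticConfig) -> list[np.ndarray]:
    """Per-muscle nonnegative activation profiles.

    ramp: repeated up-hold-down ramps cycling through ``mvc_levels`` over a
    resting baseline; each muscle's level order is rotated so profiles are
    linearly independent across muscles. sway: a seeded random walk
    low-pass filtered below 0.5 Hz, shifted/scaled into [baseline, ~1] —
    a quiet-standing-like slow drift. constant: flat at the first MVC
    level. Deterministic given the seed.
    """
    n = config.n_samples
    rngs = _child_seeds(config.seed, config.n_muscles, tag=1)
    profiles: list[np.ndarray] = []
    for i in range(config.n_muscles):
        if config.profile == "constant":
            profiles.append(np.full(n, config.mvc_levels[0]))
            continue
        if config.profile == "ramp":
            levels = np.roll(np.asarray(config.mvc_levels, dtype=float), i)
            n_cycles = len(levels)
            cycle_len = n // n_cycles
            prof = np.full(n, config.baseline)
            for c, level in enumerate(levels):
                s = c * cycle_len
                e = n if c == n_cycles - 1 else (c + 1) * cycle_len
                seg = e - s
                up, hold = seg // 3, seg // 3
                down = seg - up - hold
                ramp_up = np.linspace(config.baseline, level, up, endpoint=False)
                plateau = np.full(hold, level)
                ramp_down = np.linspace(level, config.baseline, down)
                prof[s:e] = np.concatenate([ramp_up, plateau, ramp_down])
            # per-muscle time shift keeps profiles linearly independent
            # even when the level rotation wraps around
            prof = np.roll(prof, i * (n // (2 * config.n_muscles + 1)))
            profiles.append(prof)
            continue
        # sway
        rng = rngs[i]
        walk = np.cumsum(rng.standard_normal(n))
        b, a = sps.butter(2, 0.5 / (config.fs / 2), btype="lowpass")
        slow = sps.filtfilt(b, a, walk)
        slow = slow - slow.min()
        peak = slow.max() or 1.0
        prof = config.baseline + (1.0 - config.baseline) * slow / peak
        profiles.append(np.clip(prof, 0.0, None))
    return profiles


def _carrier(rng: np.random.Generator, n: int, config: SyntheticConfig) -> np.ndarray:
    if config.carrier_dist == "gaussian":
        white = rng.standard_normal(n)
    else:
        white = rng.laplace(0.0, 1.0 / np.sqrt(2.0), n)  # unit variance
    lo, hi = config.carrier_band_hz
    b, a = sps.butter(4, np.array([lo, hi]) / (config.fs / 2), btype="bandpass")
    x = sps.filtfilt(b, a, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_emg(
    config: SyntheticConfig, profiles: Sequence[np.ndarray] | None = None
) -> list[SignalMatrix]:
    """Per-muscle EMG: each channel is profile(t) times an independent
    unit-RMS band-limited carrier; channels of one muscle share the
    profile."""
    if profiles is None:
        profiles = generate_profile(config)
    n = config.n_samples
    out: list[SignalMatrix] = []
    rngs = _child_seeds(config.seed, config.n_muscles * config.n_channels_per_muscle, tag=2)
    k = 0
    for i, prof in enumerate(profiles):
        channels = np.empty((n, config.n_channels_per_muscle))
        for c in range(config.n_channels_per_muscle):
            if np.all(prof == 0):
                channels[:, c] = 0.0
            else:
                channels[:, c] = prof * _carrier(rngs[k], n, config)
            k += 1
        out.append(
            SignalMatrix(
                channels, fs=config.fs, muscle_id=config.muscle_ids[i],
                channel_labels=[f"{config.muscle_ids[i]}_ch{c}" for c in range(config.n_channels_per_muscle)],
            )
        )
    return out


def generate_force(
    config: SyntheticConfig, true_envelopes: Sequence[Envelope]
) -> SignalMatrix:
    """Force target from the log-linear model applied to the true
    envelopes, plus white noise with SD = noise_sd * force range.

    The log floor equals the fitter's relative epsilon, so the generative
    and fitted model classes coincide exactly at zero noise.
    """
    w = np.asarray(config.true_weights, dtype=float)
    if w.size != len(true_envelopes) + 1:
        raise DataError("true_weights arity must be n_muscles + 1")
    global_max = max(float(np.max(e.values)) for e in true_envelopes)
    eps = RELATIVE_EPSILON * (global_max if global_max > 0 else 1.0)
    f = np.full(len(true_envelopes[0]), w[0])
    for wi, env in zip(w[1:], true_envelopes):
        f += wi * np.log(np.maximum(env.values, eps))
    if config.noise_sd > 0:
        rng = _child_seeds(config.seed, 1, tag=3)[0]
        scale = config.noise_sd * (np.ptp(f) if np.ptp(f) > 0 else 1.0)
        f = f + scale * rng.standard_normal(f.size)
    return SignalMatrix(f, fs=config.fs, muscle_id="force")


def make_dataset(config: SyntheticConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Compose profiles, EMG and force into one dataset; optionally write
    it to ``out_dir`` in the delimited-file layout with a JSON manifest
    carrying the true weights and seed (the oracle for recovery tests)."""
    profiles = generate_profile(config)
    true_envelopes = [
        Envelope(p, fs=config.fs, muscle_id=mid) for p, mid in zip(profiles, config.muscle_ids)
    ]
    emg = generate_emg(config, profiles)
    force = generate_force(config, true_envelopes)
    ds = SyntheticDataset(emg=emg, true_envelopes=true_envelopes, force=force, config=config)
    if out_dir is not None:
        from .io import write_dataset

        write_dataset(ds, out_dir)
    return ds
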