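"""Dataset and configuration I/O.

On-disk layout of a recording session (all plain text):

    <dir>/manifest.json          sampling rate, muscle grouping, force file,
                                 and — for synthetic data — true weights + seed
    <dir>/emg_<muscle>.csv       samples x channels, header = channel labels
    <dir>/force.csv              single-column force/target signal
    <dir>/true_envelope_<m>.csv  (synthetic only) generative profiles

Floats are written with 17 significant digits so a write/read round trip is
numerically exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import Envelope, SignalMatrix

__all__ = ["write_dataset", "read_dataset", "ParseError", "load_config", "write_provenance"]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed dataset file; the message names the file and location."""


def _write_matrix(path: Path, data: np.ndarray, header: list[str]) -> None:
    np.savetxt(path, data, fmt=_FLOAT_FMT, delimiter=",", header=",".join(header), comments="")


def write_dataset(dataset, out_dir: str | Path) -> Path:
    """Write a (synthetic or assembled) dataset in the delimited layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    muscles = []
    for sig in dataset.emg:
        fname = f"emg_{sig.muscle_id}.csv"
        labels = sig.channel_labels or [f"ch{c}" for c in range(sig.n_channels)]
        _write_matrix(out / fname, sig.data, labels)
        muscles.append({"id": sig.muscle_id, "file": fname, "n_channels": sig.n_channels})
    _write_matrix(out / "force.csv", dataset.force.data, ["force"])
    for env in dataset.true_envelopes:
        _write_matrix(out / f"true_envelope_{env.muscle_id}.csv", env.values[:, None], [env.muscle_id])
    manifest = {
        "fs": cfg.fs,
        "muscles": muscles,
        "force_file": "force.csv",
        "true_weights": [float(w) for w in cfg.true_weights],
        "true_envelope_files": {e.muscle_id: f"true_envelope_{e.muscle_id}.csv" for e in dataset.true_envelopes},
        "seed": cfg.seed,
        "config": {
            "n_muscles": cfg.n_muscles,
            "n_channels_per_muscle": cfg.n_channels_per_muscle,
            "duration_s": cfg.duration_s,
            "carrier_band_hz": list(cfg.carrier_band_hz),
            "carrier_dist": cfg.carrier_dist,
            "profile": cfg.profile,
            "mvc_levels": list(cfg.mvc_levels),
            "baseline": cfg.baseline,
            "noise_sd": cfg.noise_sd,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _read_matrix(path: Path, fs: float, muscle_id: str | None = None) -> SignalMatrix:
    if not path.exists():
        raise ParseError(f"dataset file missing: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"{path}: {exc}") from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at data row {r + 1}, "
            f"column {df.columns[c]!r}"
        )
    return SignalMatrix(
        numeric.to_numpy(dtype=float), fs=fs,
        channel_labels=[str(c) for c in df.columns], muscle_id=muscle_id,
    )


def read_dataset(path: str | Path) -> tuple[list[SignalMatrix], SignalMatrix, dict]:
    """Read a dataset directory; returns (per-muscle EMG, force, manifest).

    All signals are validated for alignment against the manifest.
    """
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise ParseError(f"manifest missing: {mpath}")
    manifest = json.loads(mpath.read_text())
    fs = float(manifest["fs"])
    emg = [
        _read_matrix(root / m["file"], fs, muscle_id=m["id"]) for m in manifest["muscles"]
    ]
    force = _read_matrix(root / manifest["force_file"], fs, muscle_id="force")
    n = force.n_samples
    for sig, m in zip(emg, manifest["muscles"]):
        if sig.n_samples != n:
            raise ParseError(
                f"{root / m['file']}: {sig.n_samples} samples, expected {n} (force length)"
            )
        if sig.n_channels != m["n_channels"]:
            raise ParseError(
                f"{root / m['file']}: {sig.n_channels} channels, manifest says {m['n_channels']}"
            )
    return emg, force, manifest


def read_true_envelopes(path: str | Path) -> list[Envelope]:
    """Generative envelope profiles of a synthetic dataset (oracle for
    parameter-recovery tests)."""
    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    fs = float(manifest["fs"])
    out = []
    for mid, fname in manifest.get("true_envelope_files", {}).items():
        sig = _read_matrix(root / fname, fs, muscle_id=mid)
        out.append(Envelope(sig.column(0), fs=fs, muscle_id=mid))
    return out


# ------------------------------------------------------------- run config

_CONFIG_SCHEMA = {
    "seed": int,
    "split_fractions": list,
    "split_scheme": str,
    "envelope_cutoff_hz": (int, float),
    "force_cutoff_hz": (int, float),
    "models": list,
    "ann_hidden": int,
    "ridge_lambda": (int, float),
    "epsilon_floor": (int, float, type(None)),
}

_CONFIG_DEFAULTS = {
    "seed": 0,
    "split_fractions": [0.5, 0.5],
    "split_scheme": "contiguous",
    "envelope_cutoff_hz": 2.0,
    "force_cutoff_hz": 1.0,
    "models": ["proposed"],
    "ann_hidden": 10,
    "ridge_lambda": 0.01,
    "epsilon_floor": None,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load and validate a run configuration (JSON or YAML), filling
    defaults; unknown keys or wrong types raise before any computation."""
    cfg = dict(_CONFIG_DEFAULTS)
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            user = yaml.safe_load(text)
        else:
            user = json.loads(text)
        if not isinstance(user, dict):
            raise ParseError(f"{path}: config must be a mapping")
        cfg.update(user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    for key, val in cfg.items():
        if key not in _CONFIG_SCHEMA:
            raise ParseError(f"unknown config key {key!r}")
        if not isinstance(val, _CONFIG_SCHEMA[key]):
            raise ParseError(f"config key {key!r} has wrong type {type(val).__name__}")
    fr = cfg["split_fractions"]
    if abs(sum(fr) - 1.0) > 1e-9:
        raise ParseError("split_fractions must sum to 1")
    return cfg


def write_provenance(out_dir: str | Path, config: dict, seed: int) -> Path:
    """Provenance record: config hash, seed and library versions —
    everything needed to reproduce a deterministic run byte-identically."""
    import scipy

    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(config, sort_keys=True, default=str)
    record = {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": config,
        "seed": seed,
        "versions": {
            "emgforce": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
    return path
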