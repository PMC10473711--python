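"""File interfaces: HDF5 trial containers, CSV tables, WAV, montages.

The canonical on-disk form of a cohort is an HDF5 container with one group
per trial::

    /trials/<k>/eeg        (channels x samples)
    /trials/<k>/env_att    attended-stream target envelope
    /trials/<k>/env_unatt  unattended-stream target envelope
    /trials/<k>/v_att      visual drive, attended face (optional)
    /trials/<k>/v_unatt    visual drive, unattended face (optional)

with condition labels (modality, gaze, attended side, congruence), the
sampling rate and the experiment id stored as attributes. Schedules,
behavioral events and result tables travel as CSV with a comment header
recording the configuration hash and seed.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synthetic import Trial

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_decoder",
    "load_decoder",
    "write_csv",
    "read_csv",
    "read_wav",
    "read_electrode_locations",
    "read_raw_eeg",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def save_cohort(path, trials: list[Trial], seed: int | None = None, meta: dict | None = None) -> None:
    """Write trials to the HDF5 container layout."""
    with h5py.File(path, "w") as f:
        if seed is not None:
            f.attrs["seed"] = seed
        for k, v in (meta or {}).items():
            f.attrs[k] = v
        grp = f.create_group("trials")
        for k, t in enumerate(trials):
            g = grp.create_group(str(k))
            g.create_dataset("eeg", data=t.eeg)
            g.create_dataset("env_att", data=t.env_att)
            g.create_dataset("env_unatt", data=t.env_unatt)
            if t.v_att is not None:
                g.create_dataset("v_att", data=t.v_att)
            if t.v_unatt is not None:
                g.create_dataset("v_unatt", data=t.v_unatt)
            g.attrs.update(
                fs=t.fs,
                modality=t.modality,
                gaze=t.gaze,
                attended_side=t.attended_side,
                congruent=t.congruent,
                trial_index=t.trial_index,
                experiment=t.experiment,
            )
            if t.mastoid_idx is not None:
                g.attrs["mastoid_idx"] = list(t.mastoid_idx)


def load_cohort(path) -> list[Trial]:
    """Read a cohort container back into Trial objects (index order)."""
    trials = []
    with h5py.File(path, "r") as f:
        keys = sorted(f["trials"].keys(), key=int)
        for k in keys:
            g = f["trials"][k]
            trials.append(
                Trial(
                    eeg=g["eeg"][()],
                    fs=float(g.attrs["fs"]),
                    modality=str(g.attrs["modality"]),
                    gaze=str(g.attrs["gaze"]),
                    attended_side=str(g.attrs["attended_side"]),
                    congruent=bool(g.attrs["congruent"]),
                    env_att=g["env_att"][()],
                    env_unatt=g["env_unatt"][()],
                    v_att=g["v_att"][()] if "v_att" in g else None,
                    v_unatt=g["v_unatt"][()] if "v_unatt" in g else None,
                    trial_index=int(g.attrs["trial_index"]),
                    experiment=int(g.attrs["experiment"]),
                    mastoid_idx=tuple(g.attrs["mastoid_idx"]) if "mastoid_idx" in g.attrs else None,
                )
            )
    return trials


def save_decoder(path, decoder) -> None:
    """Serialize a fitted decoder (weights, lag grid, lambda, labels)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("coef", data=decoder.coef_)
        f.attrs["intercept"] = decoder.intercept_
        f.attrs["lambda"] = decoder.lambda_
        f.attrs["tau_min_ms"] = decoder.tau_min_ms
        f.attrs["tau_max_ms"] = decoder.tau_max_ms
        f.attrs["fs"] = decoder.fs
        f.attrs["n_channels"] = decoder.n_channels_
        f.attrs["kind"] = type(decoder).__name__
        for k, v in getattr(decoder, "condition_", {}).items():
            if v is not None:
                f.attrs[f"condition_{k}"] = v
        if getattr(decoder, "cv_scores_", None) is not None:
            f.create_dataset("cv_scores", data=decoder.cv_scores_)


def load_decoder(path):
    """Reload a serialized decoder as a fitted estimator."""
    from .decoding import EnvelopeDecoder, LagGrid, SumCovarianceDecoder

    with h5py.File(path, "r") as f:
        cls = SumCovarianceDecoder if f.attrs["kind"] == "SumCovarianceDecoder" else EnvelopeDecoder
        dec = cls(
            tau_min_ms=float(f.attrs["tau_min_ms"]),
            tau_max_ms=float(f.attrs["tau_max_ms"]),
            fs=float(f.attrs["fs"]),
        )
        dec.coef_ = f["coef"][()]
        dec.intercept_ = float(f.attrs["intercept"])
        dec.lambda_ = float(f.attrs["lambda"])
        dec.n_channels_ = int(f.attrs["n_channels"])
        dec.lag_grid_ = LagGrid(dec.tau_min_ms, dec.tau_max_ms, dec.fs)
        if "cv_scores" in f:
            dec.cv_scores_ = f["cv_scores"][()]
        cond = {
            k.removeprefix("condition_"): str(v)
            for k, v in f.attrs.items()
            if k.startswith("condition_")
        }
        if cond:
            dec.condition_ = cond
    return dec


def write_csv(path, df: pd.DataFrame, config: dict | None = None, seed: int | None = None) -> None:
    """Write a table with a comment header embedding config hash and seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={config_hash(config or {})} seed={seed}\n"
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a PCM WAV file as float64 in [-1, 1]; returns (samples, fs)."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:  # average to mono
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return data, float(fs)


def read_electrode_locations(path) -> tuple[list[str], np.ndarray]:
    """Read a whitespace/comma separated ``label x y z`` montage file."""
    labels, rows = [], []
    text = Path(path).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 4:
            raise ValueError(f"malformed electrode line: {line!r}")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:4]])
    return labels, np.asarray(rows)


def read_raw_eeg(path):
    """Optional BDF/EDF import; returns (data channels x samples, fs, names).

    Requires the ``mne`` package (``pip install avmsi[eeg-import]``).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("BDF/EDF import requires the optional mne dependency") from exc
    path = str(path)
    if path.lower().endswith(".bdf"):
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)
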