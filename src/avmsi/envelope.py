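"""Broadband speech-envelope extraction.

The stimulus feature tracked by the decoders is the broadband acoustic
envelope: the audio is passed through a gammatone filter bank (128
logarithmically spaced bands between 100 and 6500 Hz by default), the
magnitude of the analytic signal gives each band's narrowband envelope,
the narrowband envelopes are averaged across bands, anti-alias filtered,
resampled to the EEG rate (64 Hz), and z-scored per trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from ._exceptions import DegenerateSignalError

__all__ = [
    "SpeechEnvelope",
    "gammatone_filterbank",
    "hilbert_envelope",
    "broadband_envelope",
    "extract_envelope",
    "log_center_frequencies",
]


@dataclass
class SpeechEnvelope:
    """Broadband acoustic envelope at the EEG rate.

    ``values`` is the z-scored envelope the decoders see; ``nonneg``
    optionally keeps the pre-z-score nonnegative envelope (the synthetic
    generator needs it for the multiplicative audiovisual interaction).
    """

    values: np.ndarray
    fs: float
    nonneg: np.ndarray | None = None
    trial_id: int | None = None
    role: str | None = None

    def __len__(self) -> int:
        return len(self.values)


def log_center_frequencies(f_lo: float, f_hi: float, n_bands: int) -> np.ndarray:
    """Logarithmically spaced center frequencies, endpoints inclusive."""
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if n_bands == 1:
        return np.array([np.sqrt(f_lo * f_hi)])
    return np.geomspace(f_lo, f_hi, n_bands)


def gammatone_filterbank(
    audio: np.ndarray,
    fs_audio: float,
    n_bands: int = 128,
    f_lo: float = 100.0,
    f_hi: float = 6500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Filter audio into gammatone bands; returns (band_signals, centers).

    Fourth-order IIR gammatone filters with ERB-style bandwidths at
    log-spaced center frequencies. ``band_signals`` has shape
    (n_bands, n_samples).
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be one-dimensional")
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio must be finite")
    if not (0 < f_lo < f_hi):
        raise ValueError("require 0 < f_lo < f_hi")
    if f_hi >= fs_audio / 2:
        raise ValueError("band edge at or above Nyquist frequency")
    centers = log_center_frequencies(f_lo, f_hi, n_bands)
    bands = np.empty((n_bands, audio.size))
    for i, fc in enumerate(centers):
        b, a = sps.gammatone(fc, "iir", fs=fs_audio)
        # second-order sections keep the tight 8-pole cluster numerically
        # stable at low center frequencies
        sos = sps.tf2sos(b, a)
        bands[i] = sps.sosfilt(sos, audio)
    return bands, centers


def hilbert_envelope(band_signal: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal of a (real, finite) band signal."""
    x = np.asarray(band_signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    return np.abs(sps.hilbert(x, axis=-1))


def _resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    frac = Fraction(fs_out / fs_in).limit_denominator(10**6)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def broadband_envelope(
    band_envelopes: np.ndarray,
    fs_in: float,
    fs_out: float = 64.0,
    zscore: bool = True,
) -> SpeechEnvelope:
    """Average narrowband envelopes, anti-alias, resample, z-score.

    The band average is low-pass filtered at 32 Hz before resampling to
    ``fs_out`` so the decoder-rate envelope is alias-free.

    Raises
    ------
    DegenerateSignalError
        For a silent (zero-variance) envelope, where the z-score is
        undefined.
    """
    bands = np.atleast_2d(np.asarray(band_envelopes, dtype=float))
    mean_env = bands.mean(axis=0)
    if fs_in > 2 * 32.0:
        sos = sps.butter(8, 32.0, btype="low", fs=fs_in, output="sos")
        mean_env = sps.sosfiltfilt(sos, mean_env)
    if fs_out != fs_in:
        mean_env = _resample_to(mean_env, fs_in, fs_out)
    nonneg = np.clip(mean_env, 0.0, None)
    if not zscore:
        return SpeechEnvelope(values=mean_env, fs=fs_out, nonneg=nonneg)
    sd = mean_env.std()
    if sd == 0:
        raise DegenerateSignalError("silent stimulus: envelope z-score undefined")
    return SpeechEnvelope(values=(mean_env - mean_env.mean()) / sd, fs=fs_out, nonneg=nonneg)


def extract_envelope(
    audio: np.ndarray,
    fs_audio: float,
    n_bands: int = 128,
    f_lo: float = 100.0,
    f_hi: float = 6500.0,
    fs_out: float = 64.0,
) -> SpeechEnvelope:
    """Full pipeline from a PCM waveform to the z-scored 64 Hz envelope."""
    bands, _ = gammatone_filterbank(audio, fs_audio, n_bands, f_lo, f_hi)
    band_envs = hilbert_envelope(bands)
    return broadband_envelope(band_envs, fs_audio, fs_out)
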