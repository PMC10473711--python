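"""Synthetic audiovisual cocktail-party cohorts.

The experiments this package analyzes present two concurrent audiovisual
speakers and manipulate the attended modality (AV, A-only, V-only), the
attended side, and gaze (crosshair ``c``, direct looking ``d``,
eavesdropping ``e``). The raw EEG is not publicly distributed, so this
module provides a generative stand-in with exactly the statistical
structure the analysis assumes: envelope-driven cortical responses that are
linear-convolutional per stream, an attention gain on the attended stream,
a gaze-dependent visual-fidelity gain, and an optional *nonlinear*
audiovisual interaction term whose strength ``kappa`` switches the additive
null (kappa = 0) on and off. With kappa = 0 the generative law is exactly a
sum of independent auditory and visual linear responses, so the
multisensory-integration index AV - (A+V) has ground truth zero; with
kappa > 0 on attended congruent streams it becomes a recoverable effect.

Every generator output is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm

from .envelope import SpeechEnvelope

__all__ = [
    "SpeechEnvelope",
    "Kernel",
    "ForwardModel",
    "Trial",
    "BehavioralEvents",
    "make_forward_model",
    "make_schedule",
    "simulate_envelope",
    "simulate_visual_signal",
    "simulate_trial_eeg",
    "simulate_trial",
    "simulate_subject",
    "simulate_behavior",
]

GAZE_CONDITIONS = ("c", "d", "e")
MODALITIES = ("AV", "A", "V")
#: Hit windows for the two visual target kinds (seconds).
TARGET_WINDOWS = {"glitch": 2.0, "slowmotion": 4.0}

# Gaze condition of the *unattended* face implied by the instructed gaze:
# direct looking leaves the distractor in the periphery, eavesdropping
# fixates it, crosshair treats both faces symmetrically.
_COMPLEMENT_GAZE = {"d": "e", "c": "c", "e": "d"}


def _zscore(x: np.ndarray, axis=-1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


@dataclass(frozen=True)
class Kernel:
    """Forward convolutional kernel: ``weights[n, j]`` acts at ``lags[j]``.

    Positive lags are causal: the EEG response at channel ``n`` and time
    ``t`` receives ``weights[n, j] * x(t - lags[j])``.
    """

    weights: np.ndarray  # (n_channels, n_lags)
    lags: np.ndarray  # integer samples, may be negative

    def __post_init__(self):
        if self.weights.shape[1] != len(self.lags):
            raise ValueError("kernel weights and lags disagree")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("kernel weights must be finite")

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Convolve a 1-D drive signal; zero boundary conditions."""
        x = np.asarray(x, dtype=float)
        n_t = len(x)
        if np.max(np.abs(self.lags)) >= n_t:
            raise ValueError("kernel support exceeds trial length")
        out = np.zeros((self.weights.shape[0], n_t))
        for j, lag in enumerate(self.lags):
            if lag >= 0:
                out[:, lag:] += np.outer(self.weights[:, j], x[: n_t - lag])
            else:
                out[:, : n_t + lag] += np.outer(self.weights[:, j], x[-lag:])
        return out


def _smooth_topography(n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Random spatially smooth channel profile with unit RMS."""
    raw = rng.standard_normal(n_channels + 8)
    topo = gaussian_filter1d(raw, sigma=max(n_channels / 10.0, 1.0))[4:-4]
    rms = np.sqrt(np.mean(topo**2))
    return topo / (rms if rms > 0 else 1.0)


def _gamma_bump(t: np.ndarray, peak_s: float, shape: float = 3.0) -> np.ndarray:
    theta = peak_s / (shape - 1.0)
    k = np.where(t >= 0, (np.maximum(t, 0) / theta) ** (shape - 1.0) * np.exp(-t / theta), 0.0)
    return k


@dataclass(frozen=True)
class ForwardModel:
    """Generative model parameters for one simulated participant.

    ``gain_att``/``gain_unatt`` scale the auditory response to the attended
    and unattended stream; ``gain_visual_by_gaze`` scales visual fidelity by
    the instructed gaze (direct >= crosshair >= eavesdrop); ``kappa`` scales
    the nonlinear audiovisual interaction on attended congruent streams
    (``kappa = 0`` is the additive null) and ``kappa_unattended`` the same
    for the unattended congruent stream. Noise is Gaussian with exponential
    spatial correlation across channel index and optional AR(1) temporal
    shaping; ``noise_sd`` is relative to the unit-scale per-channel signal.
    """

    n_channels: int
    fs: float
    h_A: Kernel
    h_V: Kernel
    h_I: Kernel
    gain_att: float = 1.0
    gain_unatt: float = 0.4
    gain_visual_by_gaze: Mapping[str, float] = field(
        default_factory=lambda: {"d": 1.0, "c": 0.5, "e": 0.2}
    )
    kappa: float = 0.0
    kappa_unattended: float = 0.0
    noise_sd: float = 3.0
    noise_spatial_corr: float = 0.3
    noise_ar: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if not (self.gain_att > self.gain_unatt > 0):
            raise ValueError("require gain_att > gain_unatt > 0")
        g = self.gain_visual_by_gaze
        if not (g["d"] >= g["c"] >= g["e"] >= 0):
            raise ValueError("require gaze gains direct >= crosshair >= eavesdrop >= 0")
        if not (0 <= self.noise_spatial_corr < 1):
            raise ValueError("noise_spatial_corr must be in [0, 1)")

    def with_(self, **kw) -> "ForwardModel":
        return replace(self, **kw)


def make_forward_model(
    n_channels: int = 128,
    fs: float = 64.0,
    seed: int = 0,
    auditory_peak_ms: float = 100.0,
    visual_peak_ms: float = -50.0,
    auditory_undershoot: float = 0.5,
    **overrides,
) -> ForwardModel:
    """Construct a participant's forward model with randomized topographies.

    Kernels are rank-one (channel topography x temporal profile): the
    auditory kernel is a gamma bump with an undershoot on support 0-400 ms;
    the visual kernel lives on support -200..300 ms relative to its drive
    (``visual_peak_ms`` may be negative — visual speech responses precede
    the acoustics; combined with the default 120 ms drive lead, the default
    peak of -50 ms puts the visual response ~170 ms before the acoustic
    envelope); the interaction kernel is a delayed 200-400 ms bump sharing
    the auditory topography. Temporal profiles have unit L2 norm so
    ``noise_sd`` has consistent units across configurations.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs

    lags_a = np.arange(0, int(round(0.400 * fs)) + 1)
    t_a = lags_a * dt
    k_a = _gamma_bump(t_a, auditory_peak_ms / 1000.0)
    k_a = k_a - auditory_undershoot * _gamma_bump(t_a, 2.2 * auditory_peak_ms / 1000.0)
    k_a /= np.linalg.norm(k_a)

    lags_v = np.arange(int(round(-0.200 * fs)), int(round(0.300 * fs)) + 1)
    t_v = lags_v * dt
    k_v = _gamma_bump(t_v - t_v[0] + dt, visual_peak_ms / 1000.0 - t_v[0] + dt)
    k_v /= np.linalg.norm(k_v)

    lags_i = np.arange(int(round(0.200 * fs)), int(round(0.400 * fs)) + 1)
    k_i = _gamma_bump((lags_i - lags_i[0]) * dt + dt, 0.08)
    k_i /= np.linalg.norm(k_i)

    topo_a = _smooth_topography(n_channels, rng)
    topo_v = _smooth_topography(n_channels, rng)

    return ForwardModel(
        n_channels=n_channels,
        fs=fs,
        h_A=Kernel(np.outer(topo_a, k_a), lags_a),
        h_V=Kernel(np.outer(topo_v, k_v), lags_v),
        h_I=Kernel(np.outer(topo_a, k_i), lags_i),
        seed=seed,
        **overrides,
    )


def make_schedule(
    experiment_id: int,
    seed: int = 0,
    trials_per_cell: int | None = None,
    duration_s: float = 60.0,
) -> pd.DataFrame:
    """Trial schedule for one participant of one experiment.

    Experiment 1: crosshair gaze only, 20 trials per attended modality
    (60 total). Experiment 2: direct-looking and eavesdropping gaze, 14
    trials per modality x gaze cell (84 total). The attended side is
    balanced within each cell (left/right differ by at most one).
    """
    if experiment_id == 1:
        gazes = ("c",)
        n_cell = 20 if trials_per_cell is None else trials_per_cell
    elif experiment_id == 2:
        gazes = ("d", "e")
        n_cell = 14 if trials_per_cell is None else trials_per_cell
    else:
        raise ValueError(f"unknown experiment_id {experiment_id!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for modality in MODALITIES:
        for gaze in gazes:
            sides = ["L", "R"] * (n_cell // 2) + (["L"] if n_cell % 2 else [])
            rng.shuffle(sides)
            for side in sides:
                rows.append(
                    dict(
                        experiment=experiment_id,
                        modality=modality,
                        gaze=gaze,
                        attended_side=side,
                        congruent=modality == "AV",
                        duration_s=float(duration_s),
                    )
                )
    df = pd.DataFrame(rows)
    df = df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    df.insert(0, "trial_index", np.arange(len(df)))
    return df


@lru_cache(maxsize=32)
def _lowpass_sos(fs: float, cutoff: float, order: int = 4):
    return sps.butter(order, cutoff, btype="low", fs=fs, output="sos")


def simulate_envelope(
    duration_s: float,
    fs: float = 64.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SpeechEnvelope:
    """Speech-envelope surrogate: low-pass-filtered rectified noise.

    Modulation energy is concentrated below ~8 Hz, matching the syllabic
    dynamics of natural speech envelopes; the output is z-scored (the
    nonnegative pre-z-score version is kept alongside).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    n = int(round(duration_s * fs))
    pad = 256
    white = rng.standard_normal(n + 2 * pad)
    sos = _lowpass_sos(fs, 8.0)
    x = sps.sosfiltfilt(sos, white)
    x = np.abs(x)
    x = sps.sosfiltfilt(sos, x)
    x = np.clip(x, 0.0, None)[pad : pad + n]
    return SpeechEnvelope(values=_zscore(x), fs=fs, nonneg=x)


def simulate_visual_signal(
    envelope: SpeechEnvelope,
    lead_ms: float = 120.0,
    smooth_ms: float = 60.0,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SpeechEnvelope:
    """Visual speech drive: the envelope advanced in time, smoothed, jittered.

    Mouth and face kinematics correlate with the acoustic envelope but lead
    it; ``lead_ms`` advances the signal (cross-correlation with the source
    peaks at minus the lead), ``smooth_ms`` is the FWHM of Gaussian temporal
    smoothing, and ``jitter_sd`` adds independent low-pass noise in units of
    the signal SD.
    """
    if lead_ms < 0:
        raise ValueError("lead_ms must be nonnegative")
    fs = envelope.fs
    vals = np.asarray(envelope.values, dtype=float)
    nonneg = envelope.nonneg if envelope.nonneg is not None else np.clip(vals, 0, None)
    n = len(vals)
    shift = int(round(lead_ms * fs / 1000.0))
    if shift >= n:
        raise ValueError("lead longer than trial")

    def _advance(x):
        out = np.empty_like(x)
        out[: n - shift] = x[shift:]
        out[n - shift :] = x.mean()
        return out

    v = _advance(vals)
    v_nn = _advance(nonneg)
    if smooth_ms > 0:
        sigma = smooth_ms / 1000.0 * fs / 2.355  # FWHM -> sigma
        v = gaussian_filter1d(v, sigma)
        v_nn = gaussian_filter1d(v_nn, sigma)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed) if rng is None else rng
        sos = _lowpass_sos(fs, min(8.0, 0.45 * fs))
        noise = sps.sosfiltfilt(sos, rng.standard_normal(n))
        noise = noise / noise.std()
        v = v + jitter_sd * v.std() * noise
        v_nn = np.clip(v_nn + jitter_sd * v_nn.std() * noise, 0.0, None)
    return SpeechEnvelope(values=v, fs=fs, nonneg=v_nn, role="visual")


@dataclass
class Trial:
    """One simulated (or imported) trial: EEG plus its analysis targets.

    ``env_att``/``env_unatt`` are the decoder target envelopes for the
    attended and unattended stream in this trial's modality cell: the
    congruent audio for AV trials, the heard audio for A trials, and the
    unheard audio matched to the visible face for V trials.
    """

    eeg: np.ndarray  # (n_channels, n_samples), z-scored per channel
    fs: float
    modality: str
    gaze: str
    attended_side: str
    congruent: bool
    env_att: np.ndarray
    env_unatt: np.ndarray
    v_att: np.ndarray | None = None
    v_unatt: np.ndarray | None = None
    trial_index: int = 0
    experiment: int = 0
    mastoid_idx: tuple[int, int] | None = None


def _spatial_noise(
    n_channels: int,
    n_t: int,
    rho: float,
    ar: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian noise, spatially correlated (corr rho^|i-j|)
    across channel index and optionally AR(1) in time."""
    z = rng.standard_normal((n_channels, n_t))
    if ar > 0:
        z = sps.lfilter([np.sqrt(1 - ar**2)], [1.0, -ar], z, axis=1)
    if rho > 0:
        idx = np.arange(n_channels)
        C = rho ** np.abs(idx[:, None] - idx[None, :])
        z = np.linalg.cholesky(C) @ z
    return z


def simulate_trial_eeg(
    schedule_row,
    streams: Mapping[str, SpeechEnvelope],
    fm: ForwardModel,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    return_components: bool = False,
):
    """Generate one trial's EEG from its stimulus streams.

    ``streams`` maps roles to envelopes: ``s_att``/``s_unatt`` are the heard
    audio envelopes and ``v_att``/``v_unatt`` the visual drive signals (omit
    a role to silence that pathway). The EEG is the superposition of the
    convolutional responses, the attended-congruent interaction term scaled
    by ``kappa`` times the gaze-dependent visual gain, and spatially
    correlated noise; each channel is z-scored at the end.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    row = schedule_row
    modality = row["modality"] if not hasattr(row, "modality") else row.modality
    gaze = row["gaze"] if not hasattr(row, "gaze") else row.gaze
    congruent = bool(row["congruent"] if not hasattr(row, "congruent") else row.congruent)

    # attention acts per modality: in V-only trials the heard audio is
    # ignored (auditory pathway at the unattended gain), in A-only trials
    # the visible face is ignored; the unattended stream is ignored in both
    # modalities
    g_aud_att = fm.gain_att if modality in ("AV", "A") else fm.gain_unatt
    g_vis_mod = fm.gain_att if modality in ("AV", "V") else fm.gain_unatt
    g_vis_att = g_vis_mod * fm.gain_visual_by_gaze[gaze]
    g_vis_unatt = fm.gain_unatt * fm.gain_visual_by_gaze[_COMPLEMENT_GAZE[gaze]]

    def vals(key):
        s = streams.get(key)
        return None if s is None else np.asarray(s.values, dtype=float)

    s_att, s_unatt = vals("s_att"), vals("s_unatt")
    v_att, v_unatt = vals("v_att"), vals("v_unatt")
    if s_att is None:
        raise ValueError("attended audio stream 's_att' is required")
    n_t = len(s_att)

    components: dict[str, np.ndarray] = {}
    components["aud_att"] = g_aud_att * fm.h_A.apply(s_att)
    if s_unatt is not None and fm.gain_unatt > 0:
        components["aud_unatt"] = fm.gain_unatt * fm.h_A.apply(s_unatt)
    if v_att is not None and g_vis_att > 0:
        components["vis_att"] = g_vis_att * fm.h_V.apply(v_att)
    if v_unatt is not None and g_vis_unatt > 0:
        components["vis_unatt"] = g_vis_unatt * fm.h_V.apply(v_unatt)

    def _interaction(s_env: SpeechEnvelope, v_env: SpeechEnvelope) -> np.ndarray:
        s_nn = s_env.nonneg if s_env.nonneg is not None else np.clip(s_env.values, 0, None)
        v_nn = v_env.nonneg if v_env.nonneg is not None else np.clip(v_env.values, 0, None)
        return _zscore(np.asarray(s_nn) * np.asarray(v_nn))

    if congruent and fm.kappa != 0 and "s_att" in streams and "v_att" in streams:
        drive = _interaction(streams["s_att"], streams["v_att"])
        components["interaction_att"] = fm.kappa * g_vis_att * fm.h_I.apply(drive)
    if congruent and fm.kappa_unattended != 0 and "s_unatt" in streams and "v_unatt" in streams:
        drive = _interaction(streams["s_unatt"], streams["v_unatt"])
        components["interaction_unatt"] = (
            fm.kappa_unattended * g_vis_unatt * fm.h_I.apply(drive)
        )

    eeg = sum(components.values())
    if fm.noise_sd > 0:
        noise = fm.noise_sd * _spatial_noise(
            fm.n_channels, n_t, fm.noise_spatial_corr, fm.noise_ar, rng
        )
        components["noise"] = noise
        eeg = eeg + noise
    eeg = _zscore(eeg)

    trial = Trial(
        eeg=eeg,
        fs=fm.fs,
        modality=modality,
        gaze=gaze,
        attended_side=str(row["attended_side"] if not hasattr(row, "attended_side") else row.attended_side),
        congruent=congruent,
        env_att=s_att,
        env_unatt=s_unatt if s_unatt is not None else np.zeros(n_t),
        v_att=v_att,
        v_unatt=v_unatt,
        trial_index=int(row["trial_index"] if not hasattr(row, "trial_index") else row.trial_index),
        experiment=int(row["experiment"] if not hasattr(row, "experiment") else row.experiment),
    )
    if return_components:
        return trial, components
    return trial


def simulate_trial(
    schedule_row,
    fm: ForwardModel,
    rng: np.random.Generator,
    visual_lead_ms: float = 120.0,
    visual_jitter_sd: float = 0.3,
) -> Trial:
    """Generate a full trial: stimulus streams, visual drives, then EEG.

    For congruent (AV) trials the visible faces match the heard audio; for
    incongruent (A, V) trials each face articulates an independent *unheard*
    stream, whose envelope is the analysis target of V decoders.
    """
    row = schedule_row
    duration = float(row["duration_s"])
    fs = fm.fs
    s_att = simulate_envelope(duration, fs, rng=rng)
    s_unatt = simulate_envelope(duration, fs, rng=rng)
    if bool(row["congruent"]):
        face_att, face_unatt = s_att, s_unatt
    else:
        face_att = simulate_envelope(duration, fs, rng=rng)
        face_unatt = simulate_envelope(duration, fs, rng=rng)
    v_att = simulate_visual_signal(
        face_att, lead_ms=visual_lead_ms, jitter_sd=visual_jitter_sd, rng=rng
    )
    v_unatt = simulate_visual_signal(
        face_unatt, lead_ms=visual_lead_ms, jitter_sd=visual_jitter_sd, rng=rng
    )
    streams = {"s_att": s_att, "s_unatt": s_unatt, "v_att": v_att, "v_unatt": v_unatt}
    trial = simulate_trial_eeg(row, streams, fm, rng=rng)
    if row["modality"] == "V":
        # target of attended/unattended V decoding is the unheard envelope
        # matched to the corresponding visible face
        trial.env_att = face_att.values
        trial.env_unatt = face_unatt.values
    return trial


def simulate_subject(
    experiment_id: int,
    fm: ForwardModel,
    seed: int,
    trials_per_cell: int | None = None,
    duration_s: float = 60.0,
    visual_lead_ms: float = 120.0,
) -> tuple[pd.DataFrame, list[Trial]]:
    """Schedule plus simulated trials for one participant."""
    schedule = make_schedule(experiment_id, seed, trials_per_cell, duration_s)
    rng = np.random.default_rng(np.random.SeedSequence([seed, experiment_id, 7]))
    trials = [
        simulate_trial(row, fm, rng, visual_lead_ms=visual_lead_ms)
        for row in schedule.to_dict("records")
    ]
    return schedule, trials


@dataclass
class BehavioralEvents:
    """Target/response event streams and comprehension scores per trial."""

    targets: pd.DataFrame  # trial_index, target_time, target_kind
    responses: pd.DataFrame  # trial_index, response_time
    comprehension: pd.DataFrame  # trial_index, n_questions, n_correct


def simulate_behavior(
    schedule: pd.DataFrame,
    dprime_target: float = 2.0,
    fa_rate: float = 0.1,
    comprehension_p: float = 0.7,
    seed: int = 0,
) -> BehavioralEvents:
    """Generate visual-target detections and comprehension answers.

    The hit rate is derived from ``dprime_target`` and ``fa_rate`` through
    the equal-variance signal-detection model, so scoring the output with
    the d-prime scorer recovers the target within sampling error. Visual
    targets appear 1-6 times per trial in AV (glitch, 2 s hit window) and
    V (slow-motion, 4 s window) trials; false alarms occur independently in
    each non-target window. Comprehension (two four-choice questions) is
    answered on AV and A trials with per-question accuracy
    ``comprehension_p``.
    """
    if not (0 < fa_rate < 1):
        raise ValueError("fa_rate must be in (0, 1)")
    hit_rate = norm.cdf(dprime_target + norm.ppf(fa_rate))
    if not (1e-12 < hit_rate < 1 - 1e-12):
        raise ValueError("infeasible (dprime_target, fa_rate) pair")
    rng = np.random.default_rng(seed)
    targets, responses, comp = [], [], []
    for row in schedule.to_dict("records"):
        ti = row["trial_index"]
        dur = float(row["duration_s"])
        modality = row["modality"]
        if modality in ("AV", "V"):
            kind = "glitch" if modality == "AV" else "slowmotion"
            window = TARGET_WINDOWS[kind]
            n_windows = int(dur // window)
            n_targets = int(rng.integers(1, min(6, n_windows - 1) + 1))
            target_windows = rng.choice(n_windows, size=n_targets, replace=False)
            for w in range(n_windows):
                t0 = w * window
                if w in target_windows:
                    targets.append(dict(trial_index=ti, target_time=t0, target_kind=kind))
                    if rng.random() < hit_rate:
                        responses.append(
                            dict(trial_index=ti, response_time=t0 + rng.uniform(0.05, 0.9) * window)
                        )
                elif rng.random() < fa_rate:
                    responses.append(
                        dict(trial_index=ti, response_time=t0 + rng.uniform(0, 1) * window)
                    )
        if modality in ("AV", "A"):
            comp.append(
                dict(
                    trial_index=ti,
                    n_questions=2,
                    n_correct=int(rng.binomial(2, comprehension_p)),
                )
            )
    return BehavioralEvents(
        targets=pd.DataFrame(targets, columns=["trial_index", "target_time", "target_kind"]),
        responses=pd.DataFrame(responses, columns=["trial_index", "response_time"]),
        comprehension=pd.DataFrame(comp, columns=["trial_index", "n_questions", "n_correct"]),
    )
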