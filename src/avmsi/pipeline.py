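"""End-to-end orchestration of the two-experiment analysis.

``run_full`` ties the stages together on a synthetic cohort (or previously
saved containers): simulate -> decode (full inventory of AV, A, V and A+V
decoders, attended and unattended, per gaze condition) -> MSI -> group
statistics -> behavior scoring -> combined-experiment mixed models. Stages
communicate through tidy CSV tables stamped with the configuration hash
and seed, so a run is resumable stage by stage and two runs with the same
configuration are byte-comparable.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._exceptions import AvmsiError
from .decoding import fit_condition_decoder, fit_sum_decoder
from .inference import comprehension_test, dprime, signed_rank
from .io import config_hash, read_csv, save_cohort, write_csv
from .lme import LmeSpec, encode_gaze, fit_lme, llr_test
from .msi import msi_gain_contrast
from .synthetic import make_forward_model, simulate_behavior, simulate_subject

logger = logging.getLogger("avmsi")

__all__ = ["RunConfig", "PipelineStageError", "run_full", "validate_container", "DECODER_INVENTORY"]

#: The full decoder inventory: 4 model kinds x 2 attention states x 3 gaze
#: conditions (crosshair from experiment 1; direct looking and
#: eavesdropping from experiment 2) = 24 decoders.
DECODER_INVENTORY = [
    (exp, modality, attention, gaze)
    for exp, gazes in ((1, ("c",)), (2, ("d", "e")))
    for gaze in gazes
    for modality in ("AV", "A", "V", "A+V")
    for attention in ("attended", "unattended")
]


class PipelineStageError(AvmsiError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative configuration of a full run."""

    experiments: tuple[int, ...] = (1, 2)
    n_subjects: int = 16
    n_shared_subjects: int = 7
    n_channels: int = 32
    trials_per_cell: int | None = None  # None -> 20 (exp 1) / 14 (exp 2)
    duration_s: float = 60.0
    tau_min_ms: float = 0.0
    tau_max_ms: float = 500.0
    single_lag: bool = False
    n_perm: int = 0
    fdr_q: float = 0.05
    kappa: float = 0.0
    noise_sd: float = 30.0
    seed: int = 0
    out_dir: str | None = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if isinstance(cfg.experiments, list):
            cfg.experiments = tuple(cfg.experiments)
        return cfg

    @property
    def hash(self) -> str:
        return config_hash(asdict(self))


def _participants(config: RunConfig, experiment: int) -> list[str]:
    """Participant ids; the first ``n_shared_subjects`` recur across
    experiments (same label, same simulated brain)."""
    n_shared = min(config.n_shared_subjects, config.n_subjects)
    if experiment == min(config.experiments):
        return [f"P{i:03d}" for i in range(config.n_subjects)]
    fresh = [f"P{i + 1000:04d}" for i in range(config.n_subjects - n_shared)]
    return [f"P{i:03d}" for i in range(n_shared)] + fresh


def _subject_seed(config: RunConfig, ptc: str) -> int:
    import hashlib

    stable = int.from_bytes(hashlib.sha256(ptc.encode()).digest()[:4], "big")
    return int(np.random.SeedSequence([config.seed, stable]).generate_state(1)[0] % (2**31))


def _simulate_stage(config: RunConfig):
    cohorts = {}
    for exp in config.experiments:
        for ptc in _participants(config, exp):
            sseed = _subject_seed(config, ptc)
            fm = make_forward_model(
                n_channels=config.n_channels,
                seed=sseed,
                kappa=config.kappa,
                noise_sd=config.noise_sd,
            )
            schedule, trials = simulate_subject(
                exp,
                fm,
                seed=sseed + exp,
                trials_per_cell=config.trials_per_cell,
                duration_s=config.duration_s,
            )
            events = simulate_behavior(schedule, seed=sseed + 17 * exp)
            cohorts[(exp, ptc)] = (schedule, trials, events)
    return cohorts


def _decode_stage(config: RunConfig, cohorts) -> pd.DataFrame:
    rows = []
    dec_params = dict(
        tau_min_ms=config.tau_min_ms, tau_max_ms=config.tau_max_ms, fs=64.0
    )
    for (exp, ptc), (schedule, trials, _) in cohorts.items():
        gazes = ("c",) if exp == 1 else ("d", "e")
        for gaze in gazes:
            for modality in ("AV", "A", "V"):
                for attention in ("attended", "unattended"):
                    dec = fit_condition_decoder(
                        trials, modality, attention, gaze=gaze, **dec_params
                    )
                    idx = int(np.flatnonzero(dec._lambdas() == dec.lambda_)[0])
                    r = dec.cv_fold_scores_[idx]
                    rows += [
                        dict(
                            experiment=exp, ptc=ptc, gaze=gaze, modality=modality,
                            attention=attention, trial=t, r=float(ri), lam=dec.lambda_,
                        )
                        for t, ri in enumerate(r)
                    ]
            for attention in ("attended", "unattended"):
                try:
                    sdec = fit_sum_decoder(trials, attention, gaze=gaze, **dec_params)
                except ValueError as exc:
                    raise PipelineStageError(f"stage 'decode' (A+V, gaze={gaze}): {exc}") from exc
                av_trials = [t for t in trials if t.modality == "AV" and t.gaze == gaze]
                r = sdec.score_trials(
                    [t.eeg for t in av_trials],
                    [t.env_att if attention == "attended" else t.env_unatt for t in av_trials],
                )
                rows += [
                    dict(
                        experiment=exp, ptc=ptc, gaze=gaze, modality="A+V",
                        attention=attention, trial=t, r=float(ri), lam=sdec.lambda_,
                    )
                    for t, ri in enumerate(r)
                ]
    return pd.DataFrame(rows)


def _msi_stage(acc_table: pd.DataFrame) -> pd.DataFrame:
    """Subject x gaze x attention MSI from the accuracy table."""
    keys = ["experiment", "ptc", "gaze", "attention"]
    av = (
        acc_table[acc_table.modality == "AV"]
        .groupby(keys, as_index=False)["r"].mean().rename(columns={"r": "r_av"})
    )
    sm = (
        acc_table[acc_table.modality == "A+V"]
        .groupby(keys, as_index=False)["r"].mean().rename(columns={"r": "r_sum"})
    )
    out = av.merge(sm, on=keys)
    out["msi"] = out.r_av - out.r_sum
    return out


def _stats_stage(msi_table: pd.DataFrame, fdr_q: float) -> pd.DataFrame:
    rows = []
    for gaze, sub in msi_table.groupby("gaze"):
        att = sub[sub.attention == "attended"].sort_values("ptc")
        un = sub[sub.attention == "unattended"].sort_values("ptc")
        if len(att) >= 5:
            s, p = signed_rank(att.msi.to_numpy())
            rows.append(dict(contrast="msi_attended_vs_0", gaze=gaze, statistic=s, p_raw=p))
            s, p = signed_rank(att.r_av.to_numpy(), un.r_av.to_numpy())
            rows.append(dict(contrast="av_attended_vs_unattended", gaze=gaze, statistic=s, p_raw=p))
            c = msi_gain_contrast(att.msi.to_numpy(), un.msi.to_numpy())
            rows.append(dict(contrast="msi_attended_vs_unattended", gaze=gaze,
                             statistic=c["statistic"], p_raw=c["p"]))
    return pd.DataFrame(rows, columns=["contrast", "gaze", "statistic", "p_raw"])


def _behavior_stage(config: RunConfig, cohorts) -> pd.DataFrame:
    rows = []
    for (exp, ptc), (schedule, _, events) in cohorts.items():
        for (modality, gaze), cell in schedule.groupby(["modality", "gaze"]):
            idx = cell.trial_index.to_numpy()
            rec = dict(experiment=exp, ptc=ptc, gaze=gaze, modality=modality,
                       dprime=np.nan, qa=np.nan)
            if modality in ("AV", "V"):
                rec["dprime"] = dprime(events, trial_indices=idx,
                                       duration_s=config.duration_s).dprime
            comp = events.comprehension[events.comprehension.trial_index.isin(idx)]
            if len(comp):
                rec["qa"] = float(comp.n_correct.sum() / comp.n_questions.sum())
            rows.append(rec)
    return pd.DataFrame(rows)


def _lme_stage(msi_table: pd.DataFrame, behavior: pd.DataFrame) -> pd.DataFrame:
    att = msi_table[msi_table.attention == "attended"].copy()
    un = msi_table[msi_table.attention == "unattended"]
    att = att.merge(
        un[["experiment", "ptc", "gaze", "r_av"]].rename(columns={"r_av": "r_av_unatt"}),
        on=["experiment", "ptc", "gaze"],
    )
    att["attention_benefit"] = att.r_av - att.r_av_unatt
    beh = behavior[behavior.modality == "AV"][["experiment", "ptc", "gaze", "dprime", "qa"]]
    data = att.merge(beh, on=["experiment", "ptc", "gaze"], how="left")
    data["gz"] = encode_gaze(data.gaze)
    data["exp"] = data.experiment.astype(float)
    rows = []
    for response in ("r_av", "msi", "attention_benefit", "dprime", "qa"):
        sub = data.dropna(subset=[response])
        if sub.ptc.nunique() < 2 or sub.gz.nunique() < 2:
            continue
        try:
            full = fit_lme(sub, LmeSpec(response, ("gz", "exp")))
            red = fit_lme(sub, LmeSpec(response, ("exp",)))
            llr = llr_test(full, red)
            rows.append(dict(
                response=response, beta_gz=float(full.params["gz"]),
                se=float(full.bse["gz"]), p_wald=float(full.pvalues["gz"]),
                llr=llr.llr, p_llr=llr.p,
            ))
        except AvmsiError:
            continue
    return pd.DataFrame(rows, columns=["response", "beta_gz", "se", "p_wald", "llr", "p_llr"])


def run_full(config: RunConfig, resume: bool = False, write_containers: bool = False) -> dict:
    """Run the full pipeline; returns the bundle of result tables.

    With an ``out_dir``, each stage's table is written as CSV (stamped with
    the config hash and seed); with ``resume=True``, stages whose output
    already exists are loaded instead of recomputed.
    """
    out = Path(config.out_dir) if config.out_dir else None
    cfg_dict = asdict(config)

    def _stage(name, fn):
        path = out / f"{name}.csv" if out else None
        if resume and path is not None and path.exists():
            logger.info("stage %s: resumed from %s", name, path)
            return read_csv(path)
        t0 = time.perf_counter()
        table = fn()
        logger.info("stage %s: %.1f s", name, time.perf_counter() - t0)
        if path is not None:
            write_csv(path, table, config=cfg_dict, seed=config.seed)
        return table

    cohorts = _simulate_stage(config)
    if write_containers and out is not None:
        for (exp, ptc), (schedule, trials, events) in cohorts.items():
            save_cohort(out / f"cohort_exp{exp}_{ptc}.h5", trials, seed=config.seed,
                        meta={"experiment": exp, "ptc": ptc, "config_hash": config.hash})

    accuracies = _stage("accuracies", lambda: _decode_stage(config, cohorts))
    msi_table = _stage("msi", lambda: _msi_stage(accuracies))
    stats = _stage("stats", lambda: _stats_stage(msi_table, config.fdr_q))
    behavior = _stage("behavior", lambda: _behavior_stage(config, cohorts))
    lme_table = _stage("lme", lambda: _lme_stage(msi_table, behavior))

    inventory = (
        accuracies.groupby(["experiment", "gaze", "modality", "attention"], as_index=False)
        .agg(mean_r=("r", "mean"), n_subjects=("ptc", "nunique"))
    )
    if out is not None:
        write_csv(out / "decoder_inventory.csv", inventory, config=cfg_dict, seed=config.seed)
    return dict(
        accuracies=accuracies,
        msi=msi_table,
        stats=stats,
        behavior=behavior,
        lme=lme_table,
        decoder_inventory=inventory,
        config=config,
    )


def validate_container(path, trials_per_cell: int | None = None) -> dict:
    """Schema and consistency report for an HDF5 trial container."""
    import h5py

    issues = []
    with h5py.File(path, "r") as f:
        if "trials" not in f:
            return {"ok": False, "issues": ["no /trials group"], "n_trials": 0}
        keys = sorted(f["trials"].keys(), key=int)
        exps = set()
        for k in keys:
            g = f["trials"][k]
            for req in ("eeg", "env_att", "env_unatt"):
                if req not in g:
                    issues.append(f"trial {k}: missing dataset {req}")
            for attr in ("fs", "modality", "gaze", "attended_side", "experiment"):
                if attr not in g.attrs:
                    issues.append(f"trial {k}: missing attribute {attr}")
            if "fs" in g.attrs and float(g.attrs["fs"]) != 64.0:
                issues.append(f"trial {k}: fs is {g.attrs['fs']}, expected 64")
            if "eeg" in g and "env_att" in g:
                n = g["eeg"].shape[-1]
                for ds in ("env_att", "env_unatt", "v_att", "v_unatt"):
                    if ds in g and g[ds].shape[-1] != n:
                        issues.append(f"trial {k}: {ds} length {g[ds].shape[-1]} != eeg {n}")
            if "experiment" in g.attrs:
                exps.add(int(g.attrs["experiment"]))
        for exp in exps:
            cells = 3 if exp == 1 else 6
            per_cell = trials_per_cell or (20 if exp == 1 else 14)
            expected = cells * per_cell
            if len(keys) != expected:
                issues.append(
                    f"experiment {exp}: expected {expected} trials, found {len(keys)}"
                )
    return {"ok": not issues, "issues": issues, "n_trials": len(keys)}
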