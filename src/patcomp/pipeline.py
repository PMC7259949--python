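"""End-to-end orchestration: QC, behaviour, MVPA, ERS, and the trial- and
participant-level analysis tables the statistical layers consume.

These helpers run each stage with per-participant seeds derived from one
master seed and assemble wide tables (one column per ROI, e.g.
``logit__VTC``) ready for :mod:`patcomp.trialwise` and
:mod:`patcomp.subject`.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._util import log, spawn_child_seeds
from .datatypes import ClassifierSpec, Condition, Phase
from . import behaviour as beh
from . import ers as ers_mod
from . import mvpa
from . import qc as qc_mod
from .simulate import SimulatedStudy


def apply_qc(study: SimulatedStudy) -> pd.DataFrame:
    """Artifact screening across participants: returns the trial table with
    flagged trials dropped (behavioural stages keep the full table)."""
    kept = []
    for pid, sub in study.trials.groupby("participant_id", sort=True):
        flags_by_run = {}
        keep_by_run = {}
        for phase in ("encoding", "retrieval"):
            for (ph, run), series in study.qc[pid].items():
                if ph != phase:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    flags = qc_mod.flag_artifact_volumes(series)
                flags_by_run[(phase, run)] = flags
                keep_by_run[(phase, run)] = qc_mod.apply_run_exclusion(flags, series)
        for phase in ("encoding", "retrieval"):
            block = sub.loc[sub["phase"] == phase]
            fbr = {run: flags_by_run[(phase, run)] for run in block["run"].unique()}
            kbr = {run: keep_by_run[(phase, run)] for run in block["run"].unique()}
            kept.append(
                qc_mod.exclude_artifact_trials(
                    block, fbr, study.trial_volume_map[pid], kbr
                )
            )
    return pd.concat(kept, ignore_index=True)


def run_mvpa(
    study: SimulatedStudy,
    trials: pd.DataFrame,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    with_ers: bool = True,
) -> dict:
    """Classify every participant and ROI; returns per-trial evidence and
    ERS tables (wide by ROI) plus per-participant encoding summaries."""
    spec = spec or ClassifierSpec()
    pids = sorted(study.patterns)
    child = spawn_child_seeds(seed, len(pids))
    evidence_frames, ers_frames, enc_rows = [], [], []
    cat_by_tid = dict(zip(trials["trial_id"], trials["category"]))
    for pid, ss in zip(pids, child):
        rng = np.random.default_rng(ss)
        sub = trials.loc[trials["participant_id"] == pid]
        enc_ids = set(sub.loc[sub["phase"] == "encoding", "trial_id"])
        ret_ids = set(sub.loc[sub["phase"] == "retrieval", "trial_id"])
        ev_by_roi, ers_by_roi = [], []
        enc_row = {"participant_id": pid}
        skip = False
        for roi in study.config.rois:
            enc_pm = study.patterns[pid][roi][Phase.ENCODING]
            ret_pm = study.patterns[pid][roi][Phase.RETRIEVAL]
            enc_pm = enc_pm.subset(np.isin(enc_pm.trial_ids, list(enc_ids)))
            ret_pm = ret_pm.subset(np.isin(ret_pm.trial_ids, list(ret_ids)))
            if (len(np.unique(enc_pm.run_labels)) < 2
                    or ret_pm.n_trials == 0):
                # excess motion left too few usable runs: the participant
                # is excluded from all neural analyses
                log.warning("participant %s excluded from MVPA: too few "
                            "usable runs after QC", pid)
                skip = True
                break
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                enc_s = mvpa.scale_within_run(enc_pm)
                ret_s = mvpa.scale_within_run(ret_pm)
            labels = np.array([cat_by_tid[t] for t in enc_s.trial_ids])
            cv = mvpa.encoding_cv(enc_s, labels, spec,
                                  seed=rng.integers(2**31))
            enc_row[f"encoding_accuracy__{roi}"] = cv["mean_accuracy"]
            enc_row[f"encoding_strength__{roi}"] = cv["mean_logit"]
            correct = np.array([cat_by_tid[t] for t in ret_s.trial_ids])
            ev = mvpa.retrieval_evidence(enc_s, labels, ret_s, correct, spec,
                                         seed=rng.integers(2**31))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = mvpa.select_category_voxels(
                    enc_s.values, labels, spec.n_features_per_category)
            act = pd.DataFrame({
                "trial_id": ret_s.trial_ids,
                f"roi_selected_activity__{roi}": ret_s.values[:, sel].mean(axis=1),
                f"roi_mean_activity__{roi}": ret_s.values.mean(axis=1),
            })
            ev = ev.rename(columns={
                "p_correct": f"p_correct__{roi}", "logit": f"logit__{roi}",
                "accuracy": f"accuracy__{roi}",
            }).drop(columns=["n_subsamples"]).merge(act, on="trial_id")
            ev_by_roi.append(ev)
            if with_ers:
                er = ers_mod.compute_ers(enc_s, ret_s, sub)
                er = er.rename(columns={
                    "within_event_z": f"within_event_z__{roi}",
                    "within_category_z": f"within_category_z__{roi}",
                    "between_category_z": f"between_category_z__{roi}",
                }).drop(columns=["condition"])
                ers_by_roi.append(er)
        if skip:
            continue
        merged = ev_by_roi[0]
        for other in ev_by_roi[1:]:
            merged = merged.merge(other, on="trial_id")
        evidence_frames.append(merged)
        if ers_by_roi:
            em = ers_by_roi[0]
            for other in ers_by_roi[1:]:
                em = em.merge(other, on="trial_id")
            ers_frames.append(em)
        enc_rows.append(enc_row)
    return {
        "evidence": pd.concat(evidence_frames, ignore_index=True),
        "ers": pd.concat(ers_frames, ignore_index=True) if ers_frames else None,
        "encoding": pd.DataFrame(enc_rows),
    }


def build_trialwise_table(
    study: SimulatedStudy,
    trials: pd.DataFrame,
    mvpa_out: dict,
) -> pd.DataFrame:
    """Analysis table for the trial-wise mixed models: one row per studied,
    artifact-free retrieval trial, with behaviour, hippocampal activity,
    per-ROI reinstatement evidence and nuisance columns."""
    ret = trials.loc[
        (trials["phase"] == "retrieval") & (~trials["is_foil"])
    ].copy()
    ret["associative_hit"] = (
        ret["condition"] == Condition.ASSOCIATIVE_HIT.value
    ).astype(float)
    ret = ret.merge(mvpa_out["evidence"], on="trial_id", how="left")
    if mvpa_out.get("ers") is not None:
        ret = ret.merge(mvpa_out["ers"], on="trial_id", how="left")
    ret = ret.merge(mvpa_out["encoding"], on="participant_id", how="left")
    cov = study.covariates[["participant_id", "age", "mean_fd"]].copy()
    cov["age"] = (cov["age"] - cov["age"].mean()) / cov["age"].std(ddof=1)
    ret = ret.merge(cov, on="participant_id", how="left")
    return ret.reset_index(drop=True)


def build_participant_summaries(
    study: SimulatedStudy,
    trials_full: pd.DataFrame,
    trials_clean: pd.DataFrame,
    mvpa_out: dict,
    adjust: bool = True,
) -> pd.DataFrame:
    """Participant-level table for the individual-differences layer.

    Behavioural rates use all trials; neural aggregates use artifact-free
    trials only.  With ``adjust=True`` each neural variable is
    residualised on mean FD (reinstatement strength also on the ROI's
    encoding classifier strength), with the grand mean restored.
    """
    from . import subject as subj

    behav = beh.summarize_behaviour(trials_full)
    ret_clean = trials_clean.loc[
        trials_clean["phase"] == "retrieval"
    ].reset_index(drop=True)
    neural = subj.summarize_neural(
        ret_clean, mvpa_out["evidence"], mvpa_out.get("ers")
    )
    out = behav.merge(neural, on="participant_id", how="left")
    out = out.merge(mvpa_out["encoding"], on="participant_id", how="left")
    out = out.merge(study.covariates, on="participant_id", how="left")
    out["sex_male"] = (out["sex"] == "M").astype(float)
    out["delayed_recall"] = [
        beh.delayed_recall_composite(a, b, c)
        for a, b, c in zip(out["lm_z"], out["hvlt_z"], out["bvmt_z"])
    ]
    if adjust:
        rois = study.config.rois
        ok = out["hippocampal_activity"].notna()
        out.loc[ok, "hippocampal_activity"] = subj.adjust_by_nuisance(
            out.loc[ok, "hippocampal_activity"], out.loc[ok, ["mean_fd"]]
        )
        for roi in rois:
            col = f"mean_logit__{roi}"
            if col not in out.columns:
                continue
            ok = out[col].notna()
            out.loc[ok, col] = subj.adjust_by_nuisance(
                out.loc[ok, col],
                out.loc[ok, ["mean_fd", f"encoding_strength__{roi}"]],
            )
            ecol = f"event_ers__{roi}"
            if ecol in out.columns:
                ok = out[ecol].notna()
                out.loc[ok, ecol] = subj.adjust_by_nuisance(
                    out.loc[ok, ecol], out.loc[ok, ["mean_fd"]]
                )
    return out
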