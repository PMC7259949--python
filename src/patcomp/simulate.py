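"""Synthetic associative-memory fMRI studies with known ground truth.

The generator emulates the study design the pipeline targets: five rounds
of alternating encoding and retrieval blocks, 24 word-picture pairs per
encoding block (12 word-face, 12 word-place) and 24 studied words plus 6
novel foils per retrieval block, a 4-way memory response (Face / Place /
Old / New), a self-paced post-scan exemplar recall outcome, per-volume QC
series and participant covariates.

Generative model (per participant i, ROI weight g_roi):

* age ~ U(60, 82); pattern fidelity f_i = max(0, 1 - delta * (age - 60));
  retrieval ability_i ~ N(0, ability_sd^2).
* Encoding pattern of trial t with category c:
  x_e = g_roi * (template_gain * T_c + event_gain * E_t) + N(0, noise_sd^2)
  with fixed unit-norm random templates T_face, T_place and event vectors
  E_t per participant and ROI.
* Trial latents: hippocampal drive h ~ N(0, 1); reinstatement strength
  r = a_h * h + sqrt(1 - a_h^2) * eta, eta ~ N(0, 1).
* Retrieval pattern: x_r = f_i * max(r, 0) * g_roi *
  (template_gain * T_c + event_gain * E_t) + noise; failed retrievals
  (r <= 0) carry no category or event signal.
* Associative success ~ Bernoulli(logistic(b0 + b_h h + b_r r + ability));
  on success the response is the correct category except for a small
  cross-category error rate (associative miss); on failure a fraction of
  trials are signal-free category guesses (correct by luck half the time)
  and the rest draw Old vs New from the familiarity parameters; foils
  draw CR / item FA / associative FA.  Associative misses therefore carry
  essentially no category signal, reproducing the chance-level classifier
  evidence that characterises failed associative retrieval.
* RT = rt0 - kappa * max(r, 0) + N(0, rt_sd^2), floored at 0.2 s.
* Post-test recall ~ Bernoulli(logistic(w0 + w1*assoc_hit + w2*r +
  w3*ability)).
* Measured hippocampal activity = h + N(0, hippo_noise_sd^2); foils carry
  an independent drive uncoupled from behaviour.

One RNG stream per participant is spawned from the master seed, so the
same (config, seed) regenerates the study bit-identically.
"""
from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._util import spawn_child_seeds
from .datatypes import PatternMatrix, Phase, QCSeries
from . import io as pio


@dataclass
class SimulationConfig:
    n_participants: int = 100
    n_runs: int = 5
    n_enc_trials_per_run: int = 24
    n_foils_per_run: int = 6
    n_voxels: int = 600
    seed: int = 0
    rois: tuple = ("VTC", "ANG")
    roi_signal: dict = field(default_factory=lambda: {"VTC": 1.0, "ANG": 0.7})
    template_gain: float = 2.5
    event_gain: float = 1.2
    noise_sd: float = 1.0
    a_h: float = 0.4                      # hippocampus -> reinstatement coupling
    beta0: float = 0.0                    # logistic link to associative success
    beta_h: float = 0.8
    beta_r: float = 0.8
    ability_sd: float = 0.8
    cross_category_error_rate: float = 0.02
    p_guess_given_failure: float = 0.15   # category guess despite failed retrieval
    p_old_given_failure: float = 0.45     # item hit vs miss on non-guessed failure
    foil_response_probs: tuple = (0.85, 0.10, 0.05)  # CR, item FA, associative FA
    rt0: float = 2.2
    kappa: float = 0.35
    rt_sd: float = 0.45
    age_range: tuple = (60.0, 82.0)
    age_slope: float = 0.015              # fidelity decline per year of age
    posttest_weights: tuple = (-2.2, 1.6, 0.5, 0.8)  # w0, w_assoc_hit, w_r, w_ability
    hippo_noise_sd: float = 0.5
    motion_log_mean: float = float(np.log(0.15))
    motion_log_sd: float = 0.4
    fd_volume_log_sd: float = 0.5
    n_volumes_per_trial: int = 6
    recall_loading: float = 0.6           # ability loading of delayed-recall subtests
    generate_patterns: bool = True        # skip voxel patterns for latent-only runs

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")
        if self.n_enc_trials_per_run % 2:
            raise ValueError("encoding trials per run must split evenly by category")
        if not (-1.0 <= self.a_h <= 1.0):
            raise ValueError("a_h must lie in [-1, 1]")
        if self.template_gain < 0 or self.event_gain < 0:
            raise ValueError("gains must be non-negative")


@dataclass
class GroundTruth:
    """Generative latents exported alongside every simulated dataset."""

    trial: pd.DataFrame        # trial_id, h, r, recollected (retrieval trials)
    participant: pd.DataFrame  # participant_id, age, ability, fidelity


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    trials: pd.DataFrame
    patterns: dict            # participant_id -> roi -> phase -> PatternMatrix
    qc: dict                  # participant_id -> (phase, run) -> QCSeries
    trial_volume_map: dict    # participant_id -> trial_id -> volume indices
    covariates: pd.DataFrame
    truth: GroundTruth


def _unit_vectors(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    v = rng.standard_normal((n, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a complete synthetic study from the configuration."""
    cfg = config or SimulationConfig()
    seeds = spawn_child_seeds(cfg.seed, cfg.n_participants)
    all_trials, truth_trial, truth_part, cov_rows = [], [], [], []
    patterns, qc_all, vol_maps = {}, {}, {}

    n_cat = cfg.n_enc_trials_per_run // 2
    n_studied = cfg.n_runs * cfg.n_enc_trials_per_run
    n_foils = cfg.n_runs * cfg.n_foils_per_run

    for p in range(cfg.n_participants):
        # independent streams so the behavioural draws are identical whether
        # or not voxel patterns are generated
        ss_beh, ss_pat, ss_qc = seeds[p].spawn(3)
        rng = np.random.default_rng(ss_beh)
        rng_pat = np.random.default_rng(ss_pat)
        rng_qc = np.random.default_rng(ss_qc)
        pid = f"sub{p + 1:03d}"
        age = float(rng.uniform(*cfg.age_range))
        fidelity = max(0.0, 1.0 - cfg.age_slope * (age - cfg.age_range[0]))
        ability = float(rng.normal(0.0, cfg.ability_sd))
        sex = "F" if rng.random() < 0.6 else "M"
        education = float(np.clip(np.round(rng.normal(17.0, 2.0)), 12, 20))
        mean_fd = float(rng.lognormal(cfg.motion_log_mean, cfg.motion_log_sd))

        # fixed spatial structure per ROI
        roi_vecs = {}
        if cfg.generate_patterns:
            for roi in cfg.rois:
                t_face, t_place = _unit_vectors(rng_pat, 2, cfg.n_voxels)
                events = _unit_vectors(rng_pat, n_studied, cfg.n_voxels)
                roi_vecs[roi] = (t_face, t_place, events)

        words = [f"w{w:03d}" for w in range(n_studied + n_foils)]
        studied_words = words[:n_studied]
        foil_words = words[n_studied:]
        # balanced category assignment within each run
        categories = []
        for _ in range(cfg.n_runs):
            cats = np.array(["face"] * n_cat + ["place"] * n_cat, dtype=object)
            categories.append(rng.permutation(cats))
        categories = np.concatenate(categories)
        cat_of_word = dict(zip(studied_words, categories))
        event_idx_of_word = {w: i for i, w in enumerate(studied_words)}

        rows = []
        enc_rows_order, ret_rows_order = [], []

        # ---------------- encoding phase -------------------------------
        for run in range(1, cfg.n_runs + 1):
            lo = (run - 1) * cfg.n_enc_trials_per_run
            run_words = studied_words[lo: lo + cfg.n_enc_trials_per_run]
            for idx, w in enumerate(run_words):
                tid = f"{pid}:encoding:{run}:{idx}"
                rows.append(
                    dict(participant_id=pid, run=run, trial_index=idx,
                         phase="encoding", word=w, category=cat_of_word[w],
                         is_foil=False, response="none", rt=np.nan,
                         condition="unclassified", artifact=False,
                         posttest_correct=np.nan, hippocampal_activity=np.nan,
                         trial_id=tid)
                )
                enc_rows_order.append((tid, run, w, cat_of_word[w]))

        # ---------------- retrieval phase ------------------------------
        latents = {}
        for run in range(1, cfg.n_runs + 1):
            lo = (run - 1) * cfg.n_enc_trials_per_run
            run_targets = studied_words[lo: lo + cfg.n_enc_trials_per_run]
            flo = (run - 1) * cfg.n_foils_per_run
            run_foils = foil_words[flo: flo + cfg.n_foils_per_run]
            order = rng.permutation(len(run_targets) + len(run_foils))
            probe_words = np.array(run_targets + run_foils, dtype=object)[order]
            for idx, w in enumerate(probe_words):
                tid = f"{pid}:retrieval:{run}:{idx}"
                is_foil = w in set(run_foils)
                h = float(rng.standard_normal())
                if is_foil:
                    r = np.nan
                    u = rng.random()
                    p_cr, p_ifa, _ = cfg.foil_response_probs
                    if u < p_cr:
                        response = "New"
                    elif u < p_cr + p_ifa:
                        response = "Old"
                    else:
                        response = "Face" if rng.random() < 0.5 else "Place"
                    recollected = False
                    rt = cfg.rt0 + float(rng.normal(0.0, cfg.rt_sd))
                    posttest = np.nan
                else:
                    eta = float(rng.standard_normal())
                    r = cfg.a_h * h + np.sqrt(max(0.0, 1.0 - cfg.a_h**2)) * eta
                    p_succ = _logistic(cfg.beta0 + cfg.beta_h * h
                                       + cfg.beta_r * r + ability)
                    recollected = bool(rng.random() < p_succ)
                    cat = cat_of_word[w]
                    if recollected:
                        if rng.random() < cfg.cross_category_error_rate:
                            response = "Place" if cat == "face" else "Face"
                        else:
                            response = "Face" if cat == "face" else "Place"
                    elif rng.random() < cfg.p_guess_given_failure:
                        # category guess without retrieval: no pattern signal,
                        # correct by luck half the time
                        response = "Face" if rng.random() < 0.5 else "Place"
                    else:
                        response = ("Old" if rng.random() < cfg.p_old_given_failure
                                    else "New")
                    rt = cfg.rt0 - cfg.kappa * max(r, 0.0) + float(
                        rng.normal(0.0, cfg.rt_sd))
                    assoc_hit = response in ("Face", "Place") and (
                        (response == "Face") == (cat == "face"))
                    w0, w1, w2, w3 = cfg.posttest_weights
                    p_post = _logistic(w0 + w1 * float(assoc_hit) + w2 * r
                                       + w3 * ability)
                    posttest = bool(rng.random() < p_post)
                hippo = h + float(rng.normal(0.0, cfg.hippo_noise_sd))
                rows.append(
                    dict(participant_id=pid, run=run, trial_index=idx,
                         phase="retrieval", word=w,
                         category=("none" if is_foil else cat_of_word[w]),
                         is_foil=is_foil, response=response,
                         rt=max(rt, 0.2), condition="unclassified",
                         artifact=False, posttest_correct=posttest,
                         hippocampal_activity=hippo, trial_id=tid)
                )
                ret_rows_order.append((tid, run, w, is_foil))
                latents[tid] = (h, r, recollected)
                truth_trial.append(
                    dict(participant_id=pid, trial_id=tid, h=h, r=r,
                         recollected=recollected)
                )

        # ---------------- pattern matrices -----------------------------
        patterns[pid] = {}
        for roi in (cfg.rois if cfg.generate_patterns else ()):
            g = cfg.roi_signal.get(roi, 1.0)
            t_face, t_place, events = roi_vecs[roi]
            enc_vals = np.empty((len(enc_rows_order), cfg.n_voxels))
            for i, (_, _, w, cat) in enumerate(enc_rows_order):
                tvec = t_face if cat == "face" else t_place
                signal = g * (cfg.template_gain * tvec
                              + cfg.event_gain * events[event_idx_of_word[w]])
                enc_vals[i] = signal + rng_pat.normal(0.0, cfg.noise_sd, cfg.n_voxels)
            ret_vals = np.empty((len(ret_rows_order), cfg.n_voxels))
            for i, (tid, _, w, is_foil) in enumerate(ret_rows_order):
                noise = rng_pat.normal(0.0, cfg.noise_sd, cfg.n_voxels)
                if is_foil:
                    ret_vals[i] = noise
                    continue
                h, r, _ = latents[tid]
                cat = cat_of_word[w]
                tvec = t_face if cat == "face" else t_place
                signal = g * (cfg.template_gain * tvec
                              + cfg.event_gain * events[event_idx_of_word[w]])
                ret_vals[i] = fidelity * max(r, 0.0) * signal + noise
            patterns[pid][roi] = {
                Phase.ENCODING: PatternMatrix(
                    roi=roi, phase=Phase.ENCODING, values=enc_vals,
                    run_labels=np.array([r for _, r, _, _ in enc_rows_order]),
                    trial_ids=np.array([t for t, _, _, _ in enc_rows_order],
                                       dtype=object),
                ),
                Phase.RETRIEVAL: PatternMatrix(
                    roi=roi, phase=Phase.RETRIEVAL, values=ret_vals,
                    run_labels=np.array([r for _, r, _, _ in ret_rows_order]),
                    trial_ids=np.array([t for t, _, _, _ in ret_rows_order],
                                       dtype=object),
                ),
            }

        # ---------------- QC series & trial-volume map ------------------
        qc_all[pid] = {}
        vol_map = {}
        for phase, order_rows, per_run in (
            ("encoding", enc_rows_order, cfg.n_enc_trials_per_run),
            ("retrieval", ret_rows_order,
             cfg.n_enc_trials_per_run + cfg.n_foils_per_run),
        ):
            for run in range(1, cfg.n_runs + 1):
                n_vol = per_run * cfg.n_volumes_per_trial
                fd = rng_qc.lognormal(np.log(mean_fd), cfg.fd_volume_log_sd, n_vol)
                intensity = rng_qc.normal(1000.0, 2.0, n_vol)
                qc_all[pid][(phase, run)] = QCSeries(
                    run=run, framewise_displacement=fd, global_intensity=intensity
                )
            i_in_run: dict = {}
            for tid, run, *_ in order_rows:
                k = i_in_run.get((run,), 0)
                i_in_run[(run,)] = k + 1
                start = k * cfg.n_volumes_per_trial
                vol_map[tid] = list(range(start, start + cfg.n_volumes_per_trial))
        vol_maps[pid] = vol_map

        # ---------------- covariates ------------------------------------
        sub_z = {}
        for test in ("lm", "hvlt", "bvmt"):
            sub_z[test] = (cfg.recall_loading * ability / max(cfg.ability_sd, 1e-12)
                           + 0.8 * float(rng.standard_normal()))
        cov_rows.append(
            dict(participant_id=pid, age=age, sex=sex, education=education,
                 mean_fd=mean_fd, lm_z=sub_z["lm"], hvlt_z=sub_z["hvlt"],
                 bvmt_z=sub_z["bvmt"])
        )
        truth_part.append(
            dict(participant_id=pid, age=age, ability=ability, fidelity=fidelity)
        )
        all_trials.extend(rows)

    trials = pd.DataFrame(all_trials)
    covariates = pd.DataFrame(cov_rows)
    # z-score the delayed-recall subtests across the generated cohort
    for c in ("lm_z", "hvlt_z", "bvmt_z"):
        covariates[c] = (covariates[c] - covariates[c].mean()) / covariates[c].std(ddof=1)
    truth = GroundTruth(
        trial=pd.DataFrame(truth_trial), participant=pd.DataFrame(truth_part)
    )
    return SimulatedStudy(
        config=cfg, trials=trials, patterns=patterns, qc=qc_all,
        trial_volume_map=vol_maps, covariates=covariates, truth=truth,
    )


def truth_regression_oracle(study_or_config) -> dict:
    """Generative effect sizes in the estimand parameterisation used by the
    trial-wise models over the ground-truth latents.

    With h ~ N(0,1) and r = a_h*h + sqrt(1-a_h^2)*eta, the population
    regression slope of r on h is exactly a_h (the mediation a-path on the
    latent scale); the logistic coefficient of r on associative success
    controlling h is beta_r (the b-path) and of h controlling r is beta_h.
    The values depend only on the configuration, never on the seed.
    """
    cfg = study_or_config.config if isinstance(study_or_config, SimulatedStudy) \
        else study_or_config
    return {
        "a_path": float(cfg.a_h),
        "b_path": float(cfg.beta_r),
        "indirect": float(cfg.a_h * cfg.beta_r),
        "beta_h": float(cfg.beta_h),
        "beta_r": float(cfg.beta_r),
        "beta0": float(cfg.beta0),
    }


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write a study in the layout the readers consume: trials.tsv,
    covariates.tsv, qc.tsv, patterns.h5 per participant, ground_truth.json."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_trial_table(study.trials, outdir / "trials.tsv")
    study.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    for pid, rois in study.patterns.items():
        path = outdir / f"patterns_{pid}.h5"
        if path.exists():
            path.unlink()
        for roi, phases in rois.items():
            for pm in phases.values():
                pio.write_pattern_matrix(pm, path)
    qc_frames = []
    for pid, runs in study.qc.items():
        for (phase, run), s in runs.items():
            qc_frames.append(pd.DataFrame({
                "participant_id": pid, "phase": phase, "run": run,
                "volume": np.arange(s.n_volumes),
                "framewise_displacement": s.framewise_displacement,
                "global_intensity": s.global_intensity,
            }))
    pd.concat(qc_frames, ignore_index=True).to_csv(
        outdir / "qc.tsv", sep="\t", index=False, float_format="%.17g")
    with open(outdir / "trial_volume_map.json", "w") as f:
        json.dump(study.trial_volume_map, f)
    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(study.config).items()},
        "oracle": truth_regression_oracle(study.config),
        "participant": study.truth.participant.to_dict(orient="records"),
        "trial": study.truth.trial.to_dict(orient="records"),
    }
    with open(outdir / "ground_truth.json", "w") as f:
        json.dump(truth, f, indent=1, default=float)
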