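"""Category classification of voxel patterns: encoding cross-validation,
encoding-to-retrieval transfer, signed-logit reinstatement evidence, and
permutation-based significance.

The classifier is an L2-penalised logistic regression (C = 1, liblinear).
Before classification, each voxel is standardised across trials within run
and the analysis is restricted to the top-k voxels most sensitive to each
category at encoding (two-sample t contrast, k per category, union of the
two sets).  Training sets are subsampled to balance face/place counts; the
probabilities from the subsample fits are averaged before a single logit
transform.  Evidence is signed toward the trial's correct associate, so a
positive logit means correct-category reinstatement whether the associate
was a face or a place.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._util import log, rng_from_seed
from .datatypes import Category, ClassifierSpec, PatternMatrix


def scale_within_run(pm: PatternMatrix) -> PatternMatrix:
    """Standardise each voxel to zero mean and unit variance within run.

    Uses the population (ddof=0) standard deviation so that each column has
    unit variance exactly; zero-variance voxels are mapped to all-zero with
    a warning.  A run with fewer than two trials is an error.
    """
    values = pm.values.copy()
    for run in np.unique(pm.run_labels):
        rows = pm.run_labels == run
        if rows.sum() < 2:
            raise ValueError(f"run {run} has fewer than 2 trials; cannot scale")
        block = values[rows]
        mu = block.mean(axis=0)
        sd = block.std(axis=0)  # ddof=0: unit variance after scaling
        dead = sd == 0.0
        if dead.any():
            warnings.warn(
                f"run {run}: {int(dead.sum())} zero-variance voxel(s) set to 0",
                stacklevel=2,
            )
            sd = np.where(dead, 1.0, sd)
        block = (block - mu) / sd
        block[:, dead] = 0.0
        values[rows] = block
    return PatternMatrix(
        roi=pm.roi,
        phase=pm.phase,
        values=values,
        run_labels=pm.run_labels.copy(),
        trial_ids=pm.trial_ids.copy(),
    )


def _category_tstats(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-voxel two-sample t statistic, positive toward the face category."""
    face = values[labels == Category.FACE.value]
    place = values[labels == Category.PLACE.value]
    if len(face) < 2 or len(place) < 2:
        raise ValueError("both categories need >= 2 trials for voxel selection")
    n1, n2 = len(face), len(place)
    v1 = face.var(axis=0, ddof=1)
    v2 = place.var(axis=0, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    denom = np.where(denom == 0.0, np.finfo(float).tiny, denom)
    return (face.mean(axis=0) - place.mean(axis=0)) / denom


def select_category_voxels(
    values: np.ndarray, labels: np.ndarray, k: int = 250
) -> np.ndarray:
    """Indices of the top-k face-preferring plus top-k place-preferring
    voxels at encoding (sorted union; the two sets cannot overlap because
    the rankings run in opposite directions).  If 2k exceeds the voxel
    count, all voxels are used with a warning."""
    n_voxels = values.shape[1]
    if 2 * k > n_voxels:
        warnings.warn(
            f"requested 2x{k} voxels but only {n_voxels} available; using all",
            stacklevel=2,
        )
        return np.arange(n_voxels)
    t = _category_tstats(values, labels)
    order = np.argsort(t, kind="stable")
    face_set = order[-k:]
    place_set = order[:k]
    return np.sort(np.concatenate([face_set, place_set]))


def _balanced_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Subsample trial indices so face and place counts are equal."""
    face_idx = np.where(labels == Category.FACE.value)[0]
    place_idx = np.where(labels == Category.PLACE.value)[0]
    n = min(len(face_idx), len(place_idx))
    if n == 0:
        raise ValueError("a category is absent from the training set")
    take_f = rng.choice(face_idx, size=n, replace=False)
    take_p = rng.choice(place_idx, size=n, replace=False)
    idx = np.concatenate([take_f, take_p])
    assert (labels[idx] == Category.FACE.value).sum() == (
        labels[idx] == Category.PLACE.value
    ).sum(), "training subsample must be category-balanced"
    return idx


def _new_classifier(spec: ClassifierSpec) -> LogisticRegression:
    # liblinear with an L2 penalty (the solver's default), C = 1
    return LogisticRegression(C=spec.inverse_regularization, solver="liblinear")


def _face_probability(
    clf: LogisticRegression, X: np.ndarray
) -> np.ndarray:
    p = clf.predict_proba(X)
    face_col = list(clf.classes_).index(Category.FACE.value)
    return p[:, face_col]


def _subsampled_face_prob(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    spec: ClassifierSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean face-probability on X_test over balanced subsample fits."""
    probs = np.zeros(len(X_test))
    for _ in range(spec.n_subsamples):
        idx = _balanced_indices(y_train, rng)
        clf = _new_classifier(spec)
        clf.fit(X_train[idx], y_train[idx])
        probs += _face_probability(clf, X_test)
    return probs / spec.n_subsamples


def _evidence_frame(
    trial_ids: np.ndarray,
    p_face: np.ndarray,
    correct_category: np.ndarray,
    spec: ClassifierSpec,
) -> pd.DataFrame:
    """Per-trial probability of the correct category, signed logit and
    binary accuracy (p = 0.5 counts as incorrect)."""
    p_correct = np.where(correct_category == Category.FACE.value, p_face, 1.0 - p_face)
    p_correct = np.clip(p_correct, spec.clip_eps, 1.0 - spec.clip_eps)
    logit = np.log(p_correct / (1.0 - p_correct))
    return pd.DataFrame(
        {
            "trial_id": trial_ids,
            "p_correct": p_correct,
            "logit": logit,
            "accuracy": p_correct > 0.5,
            "n_subsamples": spec.n_subsamples,
        }
    )


def encoding_cv(
    patterns: PatternMatrix,
    labels: np.ndarray,
    spec: ClassifierSpec | None = None,
    seed=0,
) -> dict:
    """Leave-one-run-out cross-validated category classification at encoding.

    Feature selection is recomputed inside each training fold by default
    (``spec.select_within_folds``); the subject-level variant selects once
    on all encoding data.  Returns per-trial records plus the participant's
    mean accuracy ("encoding accuracy") and mean signed logit ("encoding
    classifier strength").
    """
    spec = spec or ClassifierSpec()
    rng = rng_from_seed(seed)
    labels = np.asarray(labels)
    runs = np.unique(patterns.run_labels)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out CV requires >= 2 runs")
    global_sel = None
    if not spec.select_within_folds:
        global_sel = select_category_voxels(
            patterns.values, labels, spec.n_features_per_category
        )
    frames = []
    for run in runs:
        test = patterns.run_labels == run
        train = ~test
        y_train = labels[train]
        if len(np.unique(y_train)) < 2:
            log.error("training fold for run %s lacks a category; skipped", run)
            continue
        if global_sel is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = select_category_voxels(
                    patterns.values[train], y_train, spec.n_features_per_category
                )
        else:
            sel = global_sel
        p_face = _subsampled_face_prob(
            patterns.values[train][:, sel],
            y_train,
            patterns.values[test][:, sel],
            spec,
            rng,
        )
        frames.append(
            _evidence_frame(patterns.trial_ids[test], p_face, labels[test], spec)
        )
    records = pd.concat(frames, ignore_index=True)
    return {
        "records": records,
        "mean_accuracy": float(records["accuracy"].mean()),
        "mean_logit": float(records["logit"].mean()),
    }


def retrieval_evidence(
    encoding_patterns: PatternMatrix,
    encoding_labels: np.ndarray,
    retrieval_patterns: PatternMatrix,
    correct_category: np.ndarray,
    spec: ClassifierSpec | None = None,
    seed=0,
) -> pd.DataFrame:
    """Reinstatement evidence: train on all encoding data, test on all
    retrieval trials with a known correct category (foils are excluded
    with a log entry)."""
    spec = spec or ClassifierSpec()
    rng = rng_from_seed(seed)
    encoding_labels = np.asarray(encoding_labels)
    correct_category = np.asarray(correct_category)
    known = np.isin(correct_category, [Category.FACE.value, Category.PLACE.value])
    n_dropped = int((~known).sum())
    if n_dropped:
        log.info("retrieval_evidence: %d foil/unknown-category trials excluded", n_dropped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = select_category_voxels(
            encoding_patterns.values, encoding_labels, spec.n_features_per_category
        )
    p_face = _subsampled_face_prob(
        encoding_patterns.values[:, sel],
        encoding_labels,
        retrieval_patterns.values[known][:, sel],
        spec,
        rng,
    )
    return _evidence_frame(
        retrieval_patterns.trial_ids[known], p_face, correct_category[known], spec
    )


def permutation_pvalue(
    observed_accuracy: float,
    encoding_patterns: PatternMatrix,
    encoding_labels: np.ndarray,
    test_patterns: PatternMatrix,
    test_correct_category: np.ndarray,
    spec: ClassifierSpec | None = None,
    seed=0,
) -> float:
    """Permutation p-value for classifier accuracy on a set of test trials.

    For each of the ``n_subsamples`` balanced subsample iterations, the
    encoding-phase training labels are shuffled ``n_permutations`` times
    (test labels stay fixed) and the full pipeline - feature selection by
    default, then classifier fit - is re-run; the p-value for that
    iteration is the fraction of permuted accuracies that meet or exceed
    the observed accuracy, and the reported p is the mean over iterations.
    """
    spec = spec or ClassifierSpec()
    if spec.n_permutations < 100:
        warnings.warn(
            f"n_permutations = {spec.n_permutations} < 100: unstable p-value",
            stacklevel=2,
        )
    rng = rng_from_seed(seed)
    encoding_labels = np.asarray(encoding_labels)
    test_correct = np.asarray(test_correct_category)
    X_train_full = encoding_patterns.values
    X_test_full = test_patterns.values
    frozen_sel = None
    if not spec.refit_selection_in_permutation:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frozen_sel = select_category_voxels(
                X_train_full, encoding_labels, spec.n_features_per_category
            )
    p_per_subsample = []
    for _ in range(spec.n_subsamples):
        idx = _balanced_indices(encoding_labels, rng)
        X_sub, y_sub = X_train_full[idx], encoding_labels[idx]
        count = 0
        for _ in range(spec.n_permutations):
            y_perm = rng.permutation(y_sub)
            if frozen_sel is None:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sel = select_category_voxels(
                        X_sub, y_perm, spec.n_features_per_category
                    )
            else:
                sel = frozen_sel
            clf = _new_classifier(spec)
            clf.fit(X_sub[:, sel], y_perm)
            p_face = _face_probability(clf, X_test_full[:, sel])
            p_correct = np.where(
                test_correct == Category.FACE.value, p_face, 1.0 - p_face
            )
            perm_acc = float((p_correct > 0.5).mean())
            if perm_acc >= observed_accuracy:
                count += 1
        p_per_subsample.append(count / spec.n_permutations)
    return float(np.mean(p_per_subsample))
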