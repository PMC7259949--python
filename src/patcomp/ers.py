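"""Encoding-retrieval similarity (ERS).

For each retrieval trial the Pearson correlation between its voxel pattern
and encoding patterns is computed over the full ROI (no feature selection)
and Fisher-z transformed before any averaging.  Three cells are reported
per trial:

* within-event: the same word's encoding pattern;
* within-category: other encoding events of the same category, the
  same-event pair removed (diagonal of the correlation matrix);
* between-category: encoding events of the other category.

Comparison events are matched on associative retrieval success: a probe
trial is compared only with encoding events whose own retrieval outcome
falls in the same success state (associative hit vs. associative miss /
item hit / item miss).  Event- and category-level reinstatement contrasts
are differences between these cells.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import log
from .datatypes import Category, Condition, PatternMatrix

_R_CLIP = 1.0 - 1e-7

_SUCCESS = {Condition.ASSOCIATIVE_HIT.value}
_FAILURE = {
    Condition.ASSOCIATIVE_MISS.value,
    Condition.ITEM_HIT.value,
    Condition.ITEM_MISS.value,
}


def success_state(condition: str):
    """Binary associative-retrieval success state, or None for conditions
    outside the studied-word taxonomy (foils, unclassified)."""
    if condition in _SUCCESS:
        return True
    if condition in _FAILURE:
        return False
    return None


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher transform with |r| clipped below 1 to keep z finite."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def _rowwise_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlations between every row of a and every row of b."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    na = np.where(na == 0.0, np.finfo(float).tiny, na)
    nb = np.where(nb == 0.0, np.finfo(float).tiny, nb)
    return (a / na[:, None]) @ (b / nb[:, None]).T


def compute_ers(
    encoding_patterns: PatternMatrix,
    retrieval_patterns: PatternMatrix,
    trials: pd.DataFrame,
    exclude_same_run: bool = False,
) -> pd.DataFrame:
    """Per-retrieval-trial ERS records.

    ``trials`` is the classified trial table for this participant; the
    encoding and retrieval rows are linked by ``word``.  Returns one row
    per studied retrieval trial with columns ``within_event_z``,
    ``within_category_z``, ``between_category_z`` and ``condition``.
    Cells with no eligible comparison event are missing, with a log entry.
    """
    enc = trials.loc[trials["phase"] == "encoding"].set_index("trial_id")
    ret = trials.loc[trials["phase"] == "retrieval"].set_index("trial_id")

    enc_ids = list(encoding_patterns.trial_ids)
    word_of_enc = enc.loc[enc_ids, "word"].to_numpy()
    cat_of_enc = enc.loc[enc_ids, "category"].to_numpy()
    run_of_enc = np.asarray(encoding_patterns.run_labels)

    # retrieval outcome of each encoding event, via the shared word
    studied_ret = ret.loc[~ret["is_foil"]]
    cond_by_word = dict(zip(studied_ret["word"], studied_ret["condition"]))
    enc_state = np.array(
        [success_state(cond_by_word.get(w, "unclassified")) for w in word_of_enc],
        dtype=object,
    )

    zmat = fisher_z(
        _rowwise_correlation(retrieval_patterns.values, encoding_patterns.values)
    )

    rows = []
    for i, tid in enumerate(retrieval_patterns.trial_ids):
        meta = ret.loc[tid]
        if bool(meta["is_foil"]):
            continue
        cond = meta["condition"]
        state = success_state(cond)
        word = meta["word"]
        cat = meta["category"]
        same_event = word_of_enc == word
        if state is None:
            rows.append(
                {
                    "trial_id": tid,
                    "within_event_z": np.nan,
                    "within_category_z": np.nan,
                    "between_category_z": np.nan,
                    "condition": cond,
                }
            )
            continue
        matched = np.array([s == state for s in enc_state])
        if exclude_same_run:
            matched &= run_of_enc != int(meta["run"])
        within_evt = zmat[i, same_event]
        within_event_z = float(within_evt[0]) if within_evt.size else np.nan
        wc_mask = matched & (cat_of_enc == cat) & ~same_event
        bc_mask = matched & (cat_of_enc != cat) & (cat_of_enc != Category.NONE.value)
        within_category_z = float(zmat[i, wc_mask].mean()) if wc_mask.any() else np.nan
        between_category_z = float(zmat[i, bc_mask].mean()) if bc_mask.any() else np.nan
        if not wc_mask.any() or not bc_mask.any():
            log.info("trial %s: empty ERS comparison cell", tid)
        rows.append(
            {
                "trial_id": tid,
                "within_event_z": within_event_z,
                "within_category_z": within_category_z,
                "between_category_z": between_category_z,
                "condition": cond,
            }
        )
    return pd.DataFrame(rows)


def event_level_contrast(records: pd.DataFrame) -> pd.Series:
    """Event-level reinstatement: within-event z minus within-category z."""
    return records["within_event_z"] - records["within_category_z"]


def category_level_contrast(records: pd.DataFrame) -> pd.Series:
    """Category-level reinstatement: within-category z minus
    between-category z."""
    return records["within_category_z"] - records["between_category_z"]
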