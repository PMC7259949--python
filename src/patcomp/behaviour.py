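"""Memory-response classification and behavioural performance measures.

Retrieval responses are sorted into the six-condition taxonomy
(associative hit/miss, item hit/miss, item/associative false alarm,
correct rejection), from which two signal-detection indices are built:

* old/new d' = Z(Old+Face+Place | studied) - Z(Old+Face+Place | foil)
* associative d' = Z(correct category | studied) - Z(Face or Place | foil)

Perfect rates are corrected by the 1/(2N) convention before the inverse
normal CDF.  Post-scan exemplar recall is scored by exact (normalised)
match to the studied image's name; non-matching responses are routed to a
review list for manual rating.
"""
from __future__ import annotations

import re
import unicodedata
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Category, Condition, Phase, Response


def classify_response(is_foil: bool, category, response) -> Condition:
    """Map one retrieval trial's (is_foil, category, response) to its
    memory condition.  Missing responses are ``unclassified``."""
    category = Category(category)
    response = Response(response)
    if response is Response.NONE:
        return Condition.UNCLASSIFIED
    if is_foil:
        if response is Response.NEW:
            return Condition.CORRECT_REJECTION
        if response is Response.OLD:
            return Condition.ITEM_FALSE_ALARM
        return Condition.ASSOCIATIVE_FALSE_ALARM
    # studied word
    if response is Response.OLD:
        return Condition.ITEM_HIT
    if response is Response.NEW:
        return Condition.ITEM_MISS
    correct = (response is Response.FACE and category is Category.FACE) or (
        response is Response.PLACE and category is Category.PLACE
    )
    return Condition.ASSOCIATIVE_HIT if correct else Condition.ASSOCIATIVE_MISS


def classify_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``condition`` column for retrieval rows of a trial table."""
    out = trials.copy()
    is_ret = out["phase"] == Phase.RETRIEVAL.value
    conditions = [
        classify_response(bool(r.is_foil), r.category, r.response).value
        for r in out.loc[is_ret].itertuples()
    ]
    out.loc[is_ret, "condition"] = conditions
    out.loc[~is_ret, "condition"] = Condition.UNCLASSIFIED.value
    return out


def _boundary_rate(count: int, n: int, rule: str = "half_count") -> float:
    """Hit/FA rate with boundary correction applied before the z-transform."""
    if n <= 0:
        raise ValueError("rate denominator must be positive")
    if count < 0 or count > n:
        raise ValueError("count must lie in [0, n]")
    rate = count / n
    if rule == "half_count":
        if rate == 0.0:
            rate = 1.0 / (2 * n)
        elif rate == 1.0:
            rate = 1.0 - 1.0 / (2 * n)
    elif rule == "loglinear":
        rate = (count + 0.5) / (n + 1)
    else:
        raise ValueError(f"unknown boundary rule {rule!r}")
    return rate


def compute_dprime(
    hit_count: int,
    hit_n: int,
    fa_count: int,
    fa_n: int,
    boundary_rule: str = "half_count",
) -> float:
    """d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate)."""
    hr = _boundary_rate(hit_count, hit_n, boundary_rule)
    fr = _boundary_rate(fa_count, fa_n, boundary_rule)
    return float(stats.norm.ppf(hr) - stats.norm.ppf(fr))


_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Lowercase, strip diacritics and punctuation, collapse whitespace."""
    text = unicodedata.normalize("NFKD", str(text))
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = _PUNCT_RE.sub(" ", text.lower())
    return _WS_RE.sub(" ", text).strip()


def score_posttest(
    response_text, target_name: str, review: list | None = None
) -> bool:
    """True iff the normalised response contains the normalised target name.

    Non-matching, non-empty responses are appended to ``review`` (if
    given) for the out-of-band human-rating pass.
    """
    if target_name is None or str(target_name) == "":
        raise ValueError("target name must be non-empty")
    if response_text is None or (isinstance(response_text, float) and np.isnan(response_text)):
        return False
    resp = normalize_text(response_text)
    if not resp:
        return False
    if normalize_text(target_name) in resp:
        return True
    if review is not None:
        review.append((str(response_text), str(target_name)))
    return False


def delayed_recall_composite(lm_z, hvlt_z, bvmt_z):
    """Composite delayed-recall score: the mean of the three z-scored
    delayed-recall subtests (logical memory, HVLT-R, BVMT-R).  Any missing
    subtest yields a missing composite with a warning."""
    vals = np.asarray([lm_z, hvlt_z, bvmt_z], dtype=float)
    if not np.all(np.isfinite(vals)):
        warnings.warn("missing delayed-recall subtest; composite is missing", stacklevel=2)
        return np.nan
    return float(vals.mean())


def summarize_behaviour(
    trials: pd.DataFrame,
    boundary_rule: str = "half_count",
) -> pd.DataFrame:
    """Per-participant behavioural block: old/new d', associative d' and
    exemplar-specific recall.

    Expects a classified retrieval-phase trial table.  Behavioural rates
    are computed on all retrieval trials (the fMRI artifact exclusion
    applies to neural aggregates only); exemplar recall is the proportion
    of studied words whose post-test response matched exactly, over
    studied words with a recorded post-test outcome.
    """
    ret = trials.loc[trials["phase"] == Phase.RETRIEVAL.value]
    rows = []
    for pid, sub in ret.groupby("participant_id", sort=True):
        studied = sub.loc[~sub["is_foil"]]
        foils = sub.loc[sub["is_foil"]]
        if len(studied) == 0:
            raise ValueError(f"participant {pid}: no studied retrieval trials")
        cond = studied["condition"]
        n_assoc_hit = int((cond == Condition.ASSOCIATIVE_HIT.value).sum())
        n_old = int(
            cond.isin(
                [
                    Condition.ASSOCIATIVE_HIT.value,
                    Condition.ASSOCIATIVE_MISS.value,
                    Condition.ITEM_HIT.value,
                ]
            ).sum()
        )
        fcond = foils["condition"]
        n_fa_old = int(
            fcond.isin(
                [Condition.ITEM_FALSE_ALARM.value, Condition.ASSOCIATIVE_FALSE_ALARM.value]
            ).sum()
        )
        n_fa_assoc = int((fcond == Condition.ASSOCIATIVE_FALSE_ALARM.value).sum())
        oldnew = compute_dprime(n_old, len(studied), n_fa_old, len(foils), boundary_rule)
        assoc = compute_dprime(
            n_assoc_hit, len(studied), n_fa_assoc, len(foils), boundary_rule
        )
        if "posttest_correct" in studied.columns and studied["posttest_correct"].notna().any():
            pt = studied["posttest_correct"].dropna().astype(bool)
            recall = float(pt.mean())
        else:
            recall = np.nan
        rows.append(
            {
                "participant_id": pid,
                "oldnew_dprime": oldnew,
                "associative_dprime": assoc,
                "exemplar_recall": recall,
                "n_studied": len(studied),
                "n_foils": len(foils),
                "n_associative_hits": n_assoc_hit,
            }
        )
    return pd.DataFrame(rows)
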