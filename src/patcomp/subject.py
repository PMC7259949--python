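"""Individual-differences layer: per-participant neural aggregates,
nuisance adjustment, standardized regressions, age models and hierarchical
model comparison.

Neural summaries are means over artifact-free associative-hit trials
(hippocampal activity additionally baselined by correct-rejection
activity).  Before regression each neural variable is adjusted by head
motion (mean framewise displacement) and, for reinstatement strength, by
the ROI's encoding classifier strength; all continuous variables are
z-scored across participants, so coefficients are standardized betas.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._util import log
from .datatypes import Condition, RegressionResult


def summarize_neural(
    trials: pd.DataFrame,
    evidence: pd.DataFrame | None = None,
    ers_records: pd.DataFrame | None = None,
    hippo_col: str = "hippocampal_activity",
    min_trials: int = 1,
) -> pd.DataFrame:
    """Per-participant neural block.

    ``trials`` is the classified, artifact-excluded retrieval trial table;
    if present, ``evidence``/``ers_records`` are merged in by ``trial_id``
    (wide per-ROI columns like ``logit__VTC`` are averaged per ROI).
    Returns one row per participant with ``hippocampal_activity`` (mean
    associative-hit minus mean correct-rejection activity), per-ROI mean
    associative-hit logits and event-level ERS contrasts.  A participant
    lacking the required trial cells gets a missing aggregate.
    """
    df = trials.copy()
    if evidence is not None:
        df = df.merge(evidence, on="trial_id", how="left", suffixes=("", "_ev"))
    if ers_records is not None:
        df = df.merge(
            ers_records.drop(columns=["condition"], errors="ignore"),
            on="trial_id", how="left", suffixes=("", "_ers"),
        )
    logit_cols = [c for c in df.columns if c == "logit" or c.startswith("logit__")]
    we_cols = [c for c in df.columns if c.startswith("within_event_z")]
    rows = []
    for pid, sub in df.groupby("participant_id", sort=True):
        hits = sub.loc[sub["condition"] == Condition.ASSOCIATIVE_HIT.value]
        crs = sub.loc[sub["condition"] == Condition.CORRECT_REJECTION.value]
        row = {"participant_id": pid, "n_associative_hits": len(hits), "n_cr": len(crs)}
        if hippo_col in sub.columns:
            if len(hits) >= min_trials and len(crs) >= min_trials:
                row["hippocampal_activity"] = float(
                    hits[hippo_col].mean() - crs[hippo_col].mean()
                )
            else:
                log.info("participant %s: too few trials for hippocampal contrast", pid)
                row["hippocampal_activity"] = np.nan
        for c in logit_cols:
            name = c.replace("logit", "mean_logit", 1)
            row[name] = float(hits[c].mean()) if len(hits) >= min_trials else np.nan
        for c in we_cols:
            suffix = c[len("within_event_z"):]
            wc = "within_category_z" + suffix
            if wc in sub.columns:
                contrast = hits[c] - hits[wc]
                row["event_ers" + suffix] = (
                    float(contrast.mean()) if len(hits) >= min_trials else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def adjust_by_nuisance(values, covariates) -> np.ndarray:
    """Residualise ``values`` on the covariate columns, restoring the grand
    mean.  Collinear covariates are an error."""
    y = np.asarray(values, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    X = np.column_stack([np.ones(len(y)), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "rank-deficient covariate matrix (collinear column(s) present)"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid + y.mean()


def fit_subject_regression(
    data: pd.DataFrame,
    outcome: str,
    predictors,
    standardize: bool = True,
) -> RegressionResult:
    """OLS of ``outcome`` on ``predictors`` with all continuous variables
    z-scored across participants (standardized betas).  Missing rows are
    dropped listwise with the count logged."""
    predictors = list(predictors)
    cols = [outcome, *predictors]
    d = data[cols].astype(float)
    n_before = len(d)
    d = d.dropna()
    if len(d) < n_before:
        log.info("listwise deletion dropped %d row(s)", n_before - len(d))
    n = len(d)
    if n <= len(predictors) + 2:
        raise ValueError("too few complete cases for regression")
    if standardize:
        d = (d - d.mean()) / d.std(ddof=1)
    X = sm.add_constant(d[predictors].to_numpy())
    res = sm.OLS(d[outcome].to_numpy(), X).fit()
    coefs = {}
    for i, name in enumerate(["Intercept", *predictors]):
        coefs[name] = (float(res.params[i]), float(res.bse[i]), float(res.pvalues[i]))
    return RegressionResult(
        coefficients=coefs,
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        n=n,
    )


def hierarchical_compare(
    data: pd.DataFrame, outcome: str, steps, standardize: bool = True
) -> pd.DataFrame:
    """Hierarchical regression ladder with F tests for the change in R^2.

    ``steps`` is a sequence of predictor lists, each nesting the previous
    (each step adds terms).  Rows are restricted to cases complete for the
    final step so every model sees the same n.  Returns one row per step
    with R^2, adjusted R^2, delta-R^2, F and p, plus the coefficient
    tables via the ``fits`` attribute of the frame.
    """
    steps = [list(dict.fromkeys(s)) for s in steps]  # drop literal duplicates
    for prev, cur in zip(steps, steps[1:]):
        if not set(prev) <= set(cur):
            raise ValueError("each step must nest the previous one")
    all_terms = steps[-1]
    d = data[[outcome, *all_terms]].astype(float).dropna().reset_index(drop=True)
    n = len(d)
    rows = []
    fits = []
    prev_r2, prev_p = 0.0, 0
    for k, terms in enumerate(steps):
        fit = fit_subject_regression(d, outcome, terms, standardize=standardize)
        p_full = np.linalg.matrix_rank(
            sm.add_constant(d[terms].to_numpy())
        ) - 1  # effective predictor count after rank reduction
        dp = p_full - prev_p
        if dp <= 0 or fit.r2 >= 1.0:
            F = 0.0 if fit.r2 - prev_r2 <= 1e-12 else np.inf
            p_val = 1.0 if F == 0.0 else 0.0
        else:
            F = ((fit.r2 - prev_r2) / dp) / ((1.0 - fit.r2) / (n - p_full - 1))
            F = max(F, 0.0)
            p_val = float(stats.f.sf(F, dp, n - p_full - 1))
        rows.append(
            {
                "step": k + 1,
                "terms": "+".join(terms),
                "r2": fit.r2,
                "adjusted_r2": fit.adjusted_r2,
                "delta_r2": fit.r2 - prev_r2,
                "F": float(F),
                "df1": int(max(dp, 0)),
                "df2": int(n - p_full - 1),
                "p": p_val,
                "n": n,
            }
        )
        fits.append(fit)
        prev_r2, prev_p = fit.r2, p_full
    out = pd.DataFrame(rows)
    out.attrs["fits"] = fits
    return out


def age_models(
    summaries: pd.DataFrame,
    measures,
    age_col: str = "age",
    extra_covariates=None,
    moderation_outcome: str | None = None,
) -> pd.DataFrame:
    """Standardized age effect on each measure (optionally controlling for
    additional covariates, e.g. sex for delayed recall).

    With ``moderation_outcome`` set, each row instead tests whether age
    moderates the measure's relation to that outcome: the outcome is
    regressed on the measure, age, and their product (built from the
    z-scored variables), and the reported effect is the interaction term.
    """
    extra = list(extra_covariates or [])
    rows = []
    for m in measures:
        if moderation_outcome is None:
            fit = fit_subject_regression(summaries, m, [age_col, *extra])
            est, se, p = fit.coefficients[age_col]
        else:
            cols = [moderation_outcome, m, age_col, *extra]
            d = summaries[cols].astype(float).dropna()
            d = (d - d.mean()) / d.std(ddof=1)
            inter = f"{age_col}_x_{m}"
            d[inter] = d[age_col] * d[m]
            fit = fit_subject_regression(
                d, moderation_outcome, [m, age_col, *extra, inter],
                standardize=False)
            est, se, p = fit.coefficients[inter]
        rows.append(
            {"measure": m, "age_beta": est, "se": se, "p": p,
             "adjusted_r2": fit.adjusted_r2, "n": fit.n}
        )
    return pd.DataFrame(rows)
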