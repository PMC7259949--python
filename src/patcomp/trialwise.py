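"""Trial-level inference: mixed-effects brain-behaviour models, likelihood
ratio tests, age moderation, and bootstrap mediation.

Every model carries a participant random intercept and an uncorrelated
random slope of the predictor of interest, the structure used for all
trial-wise analyses.  Continuous variables are z-scored within participant
across trials before modelling; significance of a fixed effect comes from
a log-likelihood ratio test against the nested model without that term
(the random slope is retained in the reduced model), with Wald z reported
for simultaneous inference within a model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from ._util import log, rng_from_seed
from .datatypes import LRTResult, MediationResult, MixedModelResult
from .glmm import LogisticGLMM

TRIAL_FILTERS = ("all_studied", "associative_hits_only", "excl_item_miss")

#: Nuisance-regressor sets by analysis kind.  ``encoding_strength`` is the
#: participant's mean cross-validated encoding logit in the ROI;
#: ``roi_selected_activity`` is univariate activity over the
#: feature-selected voxels; ``roi_mean_activity`` is activity over the full
#: ROI (ERS uses no feature selection); ``within_category_ers`` guards
#: event-level ERS effects against category-level reinstatement.
_NUISANCE_SETS = {
    "logit_iv": ["category", "age", "encoding_strength", "roi_selected_activity"],
    "logit_dv": ["category", "age", "encoding_strength"],
    "ers_iv": ["category", "age", "roi_mean_activity"],
    "event_ers": ["category", "age", "within_category_ers"],
    "hippo_iv": ["category", "age"],
}


def build_nuisance_set(analysis_kind: str) -> list[str]:
    """Rule-mandated nuisance regressors for one analysis kind."""
    try:
        return list(_NUISANCE_SETS[analysis_kind])
    except KeyError:
        raise ValueError(
            f"unknown analysis kind {analysis_kind!r}; "
            f"expected one of {sorted(_NUISANCE_SETS)}"
        ) from None


def zscore_within_participant(values, participant_ids) -> np.ndarray:
    """Standardise to mean 0, SD 1 (ddof=1) within each participant.

    A participant with zero variance gets missing values with a warning.
    """
    values = np.asarray(values, dtype=float)
    participant_ids = np.asarray(participant_ids)
    out = np.full(len(values), np.nan)
    for pid in np.unique(participant_ids):
        m = participant_ids == pid
        if m.sum() < 2:
            raise ValueError(f"participant {pid}: needs >= 2 trials to z-score")
        v = values[m]
        sd = v.std(ddof=1)
        if sd == 0.0 or not np.isfinite(sd):
            warnings.warn(f"participant {pid}: zero variance; values set missing",
                          stacklevel=2)
            continue
        out[m] = (v - v.mean()) / sd
    return out


def standardize_trialwise(data: pd.DataFrame, columns, group_col="participant_id"):
    """Return a copy with the given continuous columns z-scored within
    participant."""
    out = data.copy()
    for c in columns:
        out[c] = zscore_within_participant(out[c], out[group_col])
    return out


@dataclass
class ModelSpec:
    """Specification of one trial-wise mixed model."""

    outcome: str
    predictor_of_interest: str
    nuisance_terms: list = field(default_factory=list)
    family: str = "linear"  # or "logistic"
    trial_filter: str = "all_studied"
    random_slope: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.trial_filter not in TRIAL_FILTERS:
            raise ValueError(f"unknown trial filter {self.trial_filter!r}")
        if self.predictor_of_interest in self.nuisance_terms:
            raise ValueError("predictor and nuisance sets must be disjoint")

    @property
    def fixed_terms(self) -> list[str]:
        return [self.predictor_of_interest, *self.nuisance_terms]


def _encode_columns(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Numeric design columns for the given terms; two-level categorical
    columns become 0/1 indicators."""
    cols = {}
    for t in terms:
        col = data[t]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(pd.unique(col.dropna()))
            if len(levels) > 2:
                raise ValueError(f"categorical term {t!r} has >2 levels")
            cols[t] = (col == levels[-1]).astype(float)
        else:
            cols[t] = col.astype(float)
    return pd.DataFrame(cols, index=data.index)


def _column_scales(design: pd.DataFrame) -> np.ndarray:
    """Per-column SDs used to fit on unit-variance regressors (constant or
    zero-variance columns keep scale 1)."""
    s = design.std(ddof=0).to_numpy(dtype=float)
    return np.where((s == 0) | ~np.isfinite(s), 1.0, s)


def apply_trial_filter(data: pd.DataFrame, trial_filter: str) -> pd.DataFrame:
    if trial_filter == "all_studied":
        return data
    if trial_filter == "associative_hits_only":
        return data.loc[data["condition"] == "associative_hit"]
    return data.loc[data["condition"] != "item_miss"]


class TrialwiseModel:
    """Mixed-effects model of a trial-level outcome.

    Built from a trial-level DataFrame (one row per artifact-free studied
    retrieval trial) and a :class:`ModelSpec`; ``fit()`` returns a
    :class:`MixedModelResult`.  Linear models are fitted by maximum
    likelihood through statsmodels MixedLM with a variance-components
    random slope (uncorrelated from the intercept); logistic models use
    the in-package Laplace-ML fitter.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec, group_col="participant_id"):
        self.spec = spec
        self.group_col = group_col
        data = apply_trial_filter(data, spec.trial_filter)
        needed = [spec.outcome, *spec.fixed_terms, group_col]
        data = data.dropna(subset=[c for c in needed if c in data.columns])
        if data.empty:
            raise ValueError("no rows left after filtering")
        self.data = data.reset_index(drop=True)

    def fit(self) -> MixedModelResult:
        spec = self.spec
        design = _encode_columns(self.data, spec.fixed_terms)
        y = self.data[spec.outcome].astype(float).to_numpy()
        groups = self.data[self.group_col].to_numpy()
        X = np.column_stack([np.ones(len(y)), design.to_numpy()])
        names = ["Intercept", *spec.fixed_terms]
        if spec.family == "linear":
            return self._fit_linear(y, design, groups, names)
        return self._fit_logistic(y, X, design, groups, names)

    # -- linear family (statsmodels MixedLM, ML) ------------------------
    def _fit_linear(self, y, design, groups, names) -> MixedModelResult:
        # fit on unit-variance columns so results are invariant to affine
        # rescaling of the inputs, then map estimates back
        scales = _column_scales(design)
        df = design / scales
        df.columns = [f"x{i}" for i in range(design.shape[1])]
        df["_y"] = y
        df["_g"] = groups
        fixed = " + ".join(df.columns[: design.shape[1]]) or "1"
        pred_col = "x0"  # predictor of interest is the first term
        vc = {"slope": f"0 + {pred_col}"} if self.spec.random_slope else None
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(
                f"_y ~ {fixed}", data=df, groups=df["_g"],
                re_formula="1", vc_formula=vc,
            )
            try:
                res = md.fit(reml=False)
                converged = bool(res.converged)
            except Exception:
                res = None
                converged = False
            if res is None or not converged:
                # singular/failed fit: drop the random slope, keep the flag
                md = smf.mixedlm(f"_y ~ {fixed}", data=df, groups=df["_g"],
                                 re_formula="1")
                res = md.fit(reml=False)
                vc = None
        params = res.fe_params
        ses = res.bse_fe
        coefs = {}
        all_scales = np.concatenate([[1.0], scales])
        cols = ["Intercept"] + list(df.columns[: design.shape[1]])
        for name, col, s in zip(names, cols, all_scales):
            est, se = float(params[col]) / s, float(ses[col]) / s
            z = est / se if se > 0 else np.nan
            coefs[name] = (est, se, z, 2 * stats.norm.sf(abs(z)))
        slope_var = float(res.vcomp[0]) / scales[0] ** 2 if vc else 0.0
        return MixedModelResult(
            coefficients=coefs,
            loglik=float(res.llf),
            random_intercept_var=float(res.cov_re.iloc[0, 0]),
            random_slope_var=slope_var,
            n_obs=len(y),
            converged=converged,
            family="linear",
            formula=f"{self.spec.outcome} ~ {' + '.join(names[1:])}",
        )

    # -- logistic family (in-package Laplace ML) ------------------------
    def _fit_logistic(self, y, X, design, groups, names) -> MixedModelResult:
        scales = _column_scales(design)
        Xs = X / np.concatenate([[1.0], scales])
        pred = design.iloc[:, 0].to_numpy() / scales[0]
        Z = np.column_stack([np.ones(len(y)), pred]) if self.spec.random_slope else \
            np.ones((len(y), 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start = sm.Logit(y, Xs).fit(disp=0, maxiter=100).params
        model = LogisticGLMM(y, Xs, Z, groups)
        fit = model.fit(start_beta=start)
        coefs = {}
        all_scales = np.concatenate([[1.0], scales])
        for i, name in enumerate(names):
            est = float(fit.beta[i]) / all_scales[i]
            se = float(fit.beta_se[i]) / all_scales[i]
            z = est / se if se > 0 else np.nan
            coefs[name] = (est, se, z, 2 * stats.norm.sf(abs(z)))
        slope_var = (float(fit.sigmas[1] ** 2) / scales[0] ** 2
                     if len(fit.sigmas) > 1 else 0.0)
        return MixedModelResult(
            coefficients=coefs,
            loglik=fit.loglik,
            random_intercept_var=float(fit.sigmas[0] ** 2),
            random_slope_var=slope_var,
            n_obs=fit.n_obs,
            converged=fit.converged,
            family="logistic",
            formula=f"{self.spec.outcome} ~ {' + '.join(names[1:])}",
        )


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec, **kw) -> MixedModelResult:
    """Convenience wrapper: build a :class:`TrialwiseModel` and fit it."""
    return TrialwiseModel(data, spec, **kw).fit()


def lrt(full: MixedModelResult, reduced: MixedModelResult) -> LRTResult:
    """Log-likelihood ratio test of nested fits: chi2 = 2 * delta-loglik,
    floored at zero (optimizer noise can make it marginally negative)."""
    full_terms = set(full.coefficients)
    red_terms = set(reduced.coefficients)
    if not red_terms <= full_terms or full.family != reduced.family:
        raise ValueError("models are not nested")
    df = max(len(full_terms) - len(red_terms), 1)
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < 0:
        warnings.warn(f"negative LRT statistic ({chi2:.3g}) floored at 0",
                      stacklevel=2)
        chi2 = 0.0
    return LRTResult(chi2=float(chi2), df=df, p=float(stats.chi2.sf(chi2, df)))


def fixed_effect_lrt(data: pd.DataFrame, spec: ModelSpec, **kw) -> tuple:
    """Fit the model with and without the predictor of interest (keeping
    its random slope in both) and return (full fit, reduced fit, LRT)."""
    full = fit_mixed_model(data, spec, **kw)
    reduced_spec = ModelSpec(
        outcome=spec.outcome,
        predictor_of_interest=spec.predictor_of_interest,
        nuisance_terms=spec.nuisance_terms,
        family=spec.family,
        trial_filter=spec.trial_filter,
        random_slope=spec.random_slope,
    )
    # reduced model: same random structure, predictor dropped from the
    # fixed part.  Implemented by fitting with the predictor replaced by a
    # zero column cannot work for the slope; instead refit with nuisances
    # only as fixed terms but the predictor still defining the slope.
    red = _fit_reduced(data, reduced_spec, **kw)
    return full, red, lrt(full, red)


def _fit_reduced(data: pd.DataFrame, spec: ModelSpec, group_col="participant_id"):
    """Fit the nested model without the predictor's fixed term but with its
    random slope retained."""
    model = TrialwiseModel(data, spec, group_col=group_col)
    d = model.data
    design = _encode_columns(d, spec.fixed_terms)
    y = d[spec.outcome].astype(float).to_numpy()
    groups = d[group_col].to_numpy()
    scales = _column_scales(design)
    pred = design.iloc[:, 0].to_numpy() / scales[0]
    nuis = design.iloc[:, 1:] / scales[1:]
    nuis_scales = scales[1:]
    names = ["Intercept", *spec.nuisance_terms]
    if spec.family == "linear":
        df = nuis.copy()
        df.columns = [f"x{i}" for i in range(nuis.shape[1])]
        df["_y"] = y
        df["_g"] = groups
        df["_pred"] = pred
        fixed = " + ".join(df.columns[: nuis.shape[1]]) or "1"
        vc = {"slope": "0 + _pred"} if spec.random_slope else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(f"_y ~ {fixed}", data=df, groups=df["_g"],
                             re_formula="1", vc_formula=vc)
            res = md.fit(reml=False)
        coefs = {}
        cols = ["Intercept"] + list(df.columns[: nuis.shape[1]])
        all_scales = np.concatenate([[1.0], nuis_scales])
        for name, col, s in zip(names, cols, all_scales):
            est, se = float(res.fe_params[col]) / s, float(res.bse_fe[col]) / s
            z = est / se if se > 0 else np.nan
            coefs[name] = (est, se, z, 2 * stats.norm.sf(abs(z)))
        return MixedModelResult(
            coefficients=coefs, loglik=float(res.llf),
            random_intercept_var=float(res.cov_re.iloc[0, 0]),
            random_slope_var=float(res.vcomp[0]) / scales[0] ** 2 if vc else 0.0,
            n_obs=len(y), converged=bool(res.converged), family="linear",
        )
    X = np.column_stack([np.ones(len(y)), nuis.to_numpy()])
    Z = np.column_stack([np.ones(len(y)), pred]) if spec.random_slope else \
        np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start = sm.Logit(y, X).fit(disp=0, maxiter=100).params
    fit = LogisticGLMM(y, X, Z, groups).fit(start_beta=start)
    coefs = {}
    all_scales = np.concatenate([[1.0], nuis_scales])
    for i, name in enumerate(names):
        est = float(fit.beta[i]) / all_scales[i]
        se = float(fit.beta_se[i]) / all_scales[i]
        z = est / se if se > 0 else np.nan
        coefs[name] = (est, se, z, 2 * stats.norm.sf(abs(z)))
    return MixedModelResult(
        coefficients=coefs, loglik=fit.loglik,
        random_intercept_var=float(fit.sigmas[0] ** 2),
        random_slope_var=(float(fit.sigmas[1] ** 2) / scales[0] ** 2
                          if len(fit.sigmas) > 1 else 0.0),
        n_obs=fit.n_obs, converged=fit.converged, family="logistic",
    )


def moderation_by_age(
    data: pd.DataFrame, spec: ModelSpec, age_col: str = "age", **kw
) -> LRTResult:
    """LRT for the age x predictor interaction.

    ``age_col`` must be a participant-level variable z-scored across
    participants; a zero-variance age column is an error.
    """
    age = data[age_col].astype(float)
    if float(age.std()) == 0.0:
        raise ValueError("age has zero variance; interaction is undefined")
    d = data.copy()
    inter = f"{age_col}_x_{spec.predictor_of_interest}"
    d[inter] = age * d[spec.predictor_of_interest].astype(float)
    nuis = list(spec.nuisance_terms)
    if age_col not in nuis:
        nuis.append(age_col)
    full_spec = ModelSpec(
        outcome=spec.outcome,
        predictor_of_interest=spec.predictor_of_interest,
        nuisance_terms=nuis + [inter],
        family=spec.family,
        trial_filter=spec.trial_filter,
        random_slope=spec.random_slope,
    )
    red_spec = ModelSpec(
        outcome=spec.outcome,
        predictor_of_interest=spec.predictor_of_interest,
        nuisance_terms=nuis,
        family=spec.family,
        trial_filter=spec.trial_filter,
        random_slope=spec.random_slope,
    )
    full = fit_mixed_model(d, full_spec, **kw)
    red = fit_mixed_model(d, red_spec, **kw)
    return lrt(full, red)


# ---------------------------------------------------------------------
# Mediation
# ---------------------------------------------------------------------

def _logit_newton(X, y, start=None, max_iter=50, tol=1e-9):
    """Newton-Raphson logistic MLE; warm-startable for bootstrap loops."""
    n, p = X.shape
    beta = np.zeros(p) if start is None else np.asarray(start, float).copy()
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol * n:
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (X * w[:, None]).T @ X
        try:
            beta = beta + np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise RuntimeError("singular design in logistic path model")
    if not np.all(np.isfinite(beta)):
        raise RuntimeError("logistic path model diverged")
    return beta

def _path_coefs(data, treatment, mediator, outcome, nuis_med, nuis_out,
                outcome_family, engine, group_col):
    """a- and b-path coefficients for one dataset."""
    if engine == "pooled":
        Xm = np.column_stack(
            [np.ones(len(data)), _encode_columns(data, [treatment, *nuis_med]).to_numpy()]
        )
        a = float(np.linalg.lstsq(Xm, data[mediator].astype(float), rcond=None)[0][1])
        Xo = np.column_stack(
            [np.ones(len(data)),
             _encode_columns(data, [mediator, treatment, *nuis_out]).to_numpy()]
        )
        yo = data[outcome].astype(float).to_numpy()
        if outcome_family == "logistic":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                b = float(sm.Logit(yo, Xo).fit(disp=0, maxiter=100).params[1])
        else:
            b = float(np.linalg.lstsq(Xo, yo, rcond=None)[0][1])
        return a, b
    med_spec = ModelSpec(outcome=mediator, predictor_of_interest=treatment,
                         nuisance_terms=list(nuis_med), family="linear")
    out_spec = ModelSpec(outcome=outcome, predictor_of_interest=mediator,
                         nuisance_terms=[treatment, *nuis_out],
                         family=outcome_family)
    a = fit_mixed_model(data, med_spec, group_col=group_col).estimate(treatment)
    b = fit_mixed_model(data, out_spec, group_col=group_col).estimate(mediator)
    return a, b


class MediationModel:
    """Indirect-effect (a*b) model with cluster bootstrap inference.

    The a-path is the treatment coefficient in a model of the mediator;
    the b-path is the mediator coefficient in a model of the outcome
    controlling the treatment.  The bootstrap resamples participants
    (whole clusters) with replacement, preserving within-participant
    dependence; a trial-level resampling mode exists behind
    ``cluster=False``.  The default engine fits the two path models as
    pooled regressions (linear mediator model, logistic outcome model for
    a binary outcome) so the bootstrapped estimator is the reported
    estimator; ``engine="mixed"`` uses the full mixed models.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        treatment: str = "hippocampal_activity",
        mediator: str = "reinstatement_logit",
        outcome: str = "associative_hit",
        nuisance_mediator=None,
        nuisance_outcome=None,
        outcome_family: str = "logistic",
        engine: str = "pooled",
        group_col: str = "participant_id",
        cluster: bool = True,
    ):
        self.treatment, self.mediator, self.outcome = treatment, mediator, outcome
        self.nuis_med = list(nuisance_mediator or [])
        self.nuis_out = list(nuisance_outcome or [])
        used = [group_col, treatment, mediator, outcome,
                *self.nuis_med, *self.nuis_out]
        n_before = len(data)
        data = data.dropna(subset=[c for c in dict.fromkeys(used)
                                   if c in data.columns])
        if len(data) < n_before:
            log.info("mediation: %d incomplete row(s) dropped listwise",
                     n_before - len(data))
        self.data = data.reset_index(drop=True)
        self.outcome_family = outcome_family
        self.engine = engine
        self.group_col = group_col
        self.cluster = cluster

    def _paths(self, data) -> tuple:
        return _path_coefs(
            data, self.treatment, self.mediator, self.outcome,
            self.nuis_med, self.nuis_out, self.outcome_family,
            self.engine, self.group_col,
        )

    def _pooled_arrays(self) -> dict:
        """Precomputed design matrices for the fast pooled bootstrap."""
        d = self.data
        ones = np.ones(len(d))
        Xm = np.column_stack(
            [ones, _encode_columns(d, [self.treatment, *self.nuis_med]).to_numpy()]
        )
        Xo = np.column_stack(
            [ones,
             _encode_columns(d, [self.mediator, self.treatment,
                                 *self.nuis_out]).to_numpy()]
        )
        return {
            "Xm": Xm,
            "ym": d[self.mediator].astype(float).to_numpy(),
            "Xo": Xo,
            "yo": d[self.outcome].astype(float).to_numpy(),
        }

    def _pooled_paths_rows(self, arrs, rows, warm=None) -> tuple:
        Xm, ym = arrs["Xm"][rows], arrs["ym"][rows]
        Xo, yo = arrs["Xo"][rows], arrs["yo"][rows]
        a = float(np.linalg.lstsq(Xm, ym, rcond=None)[0][1])
        if self.outcome_family == "logistic":
            b = float(_logit_newton(Xo, yo, start=warm)[1])
        else:
            b = float(np.linalg.lstsq(Xo, yo, rcond=None)[0][1])
        return a, b

    def fit(self, n_boot: int = 5000, seed=0) -> MediationResult:
        rng = rng_from_seed(seed)
        n = len(self.data)
        groups = self.data[self.group_col].to_numpy()
        uniq = np.unique(groups)
        idx_of = {g: np.where(groups == g)[0] for g in uniq}
        all_rows = np.arange(n)
        warm = None
        if self.engine == "pooled":
            arrs = self._pooled_arrays()
            if self.outcome_family == "logistic":
                warm = _logit_newton(arrs["Xo"], arrs["yo"])
            a, b = self._pooled_paths_rows(arrs, all_rows, warm=warm)
        else:
            a, b = self._paths(self.data)
        boots = np.empty(n_boot)
        failures = 0
        for i in range(n_boot):
            if self.cluster:
                take = rng.choice(uniq, size=len(uniq), replace=True)
                rows = np.concatenate([idx_of[g] for g in take])
            else:
                rows = rng.integers(0, n, size=n)
            try:
                if self.engine == "pooled":
                    ab, bb = self._pooled_paths_rows(arrs, rows, warm=warm)
                else:
                    ab, bb = self._paths(self.data.iloc[rows])
                boots[i] = ab * bb
            except Exception:
                failures += 1
                boots[i] = np.nan
        if failures > 0.05 * n_boot:
            warnings.warn(
                f"{failures}/{n_boot} bootstrap resamples failed to converge",
                stacklevel=2,
            )
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        return MediationResult(
            a_path=float(a), b_path=float(b), indirect=float(a * b),
            ci_low=float(lo), ci_high=float(hi), n_boot=n_boot,
        )


def mediate(
    data: pd.DataFrame,
    treatment: str = "hippocampal_activity",
    mediator: str = "reinstatement_logit",
    outcome: str = "associative_hit",
    n_boot: int = 5000,
    seed=0,
    **kw,
) -> MediationResult:
    """Bootstrap mediation of ``treatment -> mediator -> outcome``; the
    indirect effect a*b is significant iff zero falls outside the 95%
    percentile interval of its bootstrap distribution."""
    return MediationModel(
        data, treatment=treatment, mediator=mediator, outcome=outcome, **kw
    ).fit(n_boot=n_boot, seed=seed)
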