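"""Core domain types for the pattern-completion analysis pipeline.

Tabular data (trials, covariates, participant summaries) travel as pandas
DataFrames with documented column schemas; the small dataclasses here carry
the non-tabular objects (voxel pattern matrices, QC series) and the results
of model fits.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


class Phase(str, enum.Enum):
    ENCODING = "encoding"
    RETRIEVAL = "retrieval"


class Category(str, enum.Enum):
    FACE = "face"
    PLACE = "place"
    NONE = "none"


class Response(str, enum.Enum):
    FACE = "Face"
    PLACE = "Place"
    OLD = "Old"
    NEW = "New"
    NONE = "none"


class Condition(str, enum.Enum):
    """Memory-outcome taxonomy for retrieval trials.

    Studied words: a correct category response is an associative hit, the
    wrong category an associative miss, "Old" an item hit and "New" an item
    miss.  Novel (foil) words: "New" is a correct rejection, "Old" an item
    false alarm, and a category response an associative false alarm.
    """

    ASSOCIATIVE_HIT = "associative_hit"
    ASSOCIATIVE_MISS = "associative_miss"
    ITEM_HIT = "item_hit"
    ITEM_MISS = "item_miss"
    ITEM_FALSE_ALARM = "item_false_alarm"
    ASSOCIATIVE_FALSE_ALARM = "associative_false_alarm"
    CORRECT_REJECTION = "correct_rejection"
    UNCLASSIFIED = "unclassified"


#: Mandatory columns of a trial table.  ``rt``, ``condition``, ``artifact``
#: and ``posttest_correct`` are retrieval-only and may be missing on
#: encoding rows.
TRIAL_COLUMNS = (
    "participant_id",
    "run",
    "trial_index",
    "phase",
    "word",
    "category",
    "is_foil",
    "response",
)

OPTIONAL_TRIAL_COLUMNS = ("rt", "condition", "artifact", "posttest_correct")


@dataclass
class PatternMatrix:
    """Trials-by-voxels activity matrix for one ROI and phase.

    Rows are aligned with (a subset of) the trial table: ``trial_ids[i]``
    names the trial whose pattern is ``values[i]`` and ``run_labels[i]`` its
    run.  After within-run scaling all entries are finite.
    """

    roi: str
    phase: Phase
    values: np.ndarray
    run_labels: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.run_labels = np.asarray(self.run_labels)
        self.trial_ids = np.asarray(self.trial_ids, dtype=object)
        if isinstance(self.phase, str):
            self.phase = Phase(self.phase)
        n = self.values.shape[0]
        if not (len(self.run_labels) == len(self.trial_ids) == n):
            raise ValueError(
                "run_labels/trial_ids length must equal the number of "
                f"pattern rows ({n})"
            )

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def subset(self, mask: np.ndarray) -> "PatternMatrix":
        """Row-subset by boolean mask or integer index, preserving order."""
        return PatternMatrix(
            roi=self.roi,
            phase=self.phase,
            values=self.values[mask],
            run_labels=self.run_labels[mask],
            trial_ids=self.trial_ids[mask],
        )


@dataclass
class QCSeries:
    """Per-volume quality-control series for one run."""

    run: int
    framewise_displacement: np.ndarray
    global_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.framewise_displacement = np.asarray(
            self.framewise_displacement, dtype=float
        )
        self.global_intensity = np.asarray(self.global_intensity, dtype=float)
        if len(self.framewise_displacement) != len(self.global_intensity):
            raise ValueError("FD and intensity series must have equal length")
        if np.any(self.framewise_displacement < 0):
            raise ValueError("framewise displacement must be non-negative")

    @property
    def n_volumes(self) -> int:
        return len(self.framewise_displacement)


@dataclass
class LRTResult:
    """Log-likelihood-ratio test between two nested model fits."""

    chi2: float
    df: int
    p: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"chi2({self.df}) = {self.chi2:.2f}, p = {self.p:.3g}"


@dataclass
class MixedModelResult:
    """Fit of a linear or logistic mixed-effects model.

    ``coefficients`` maps each fixed-effect term to
    ``(estimate, se, wald_z, p)``.  The random structure is a participant
    intercept plus an uncorrelated random slope of the predictor of
    interest; their variances are reported on the natural scale.
    """

    coefficients: Mapping[str, tuple]
    loglik: float
    random_intercept_var: float
    random_slope_var: float
    n_obs: int
    converged: bool
    family: str = "linear"
    formula: str = ""

    def estimate(self, term: str) -> float:
        return self.coefficients[term][0]

    def se(self, term: str) -> float:
        return self.coefficients[term][1]

    def wald_z(self, term: str) -> float:
        return self.coefficients[term][2]

    def pvalue(self, term: str) -> float:
        return self.coefficients[term][3]

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            [(k, *v) for k, v in self.coefficients.items()],
            columns=["term", "estimate", "se", "wald_z", "p"],
        ).set_index("term")
        tab.attrs["loglik"] = self.loglik
        tab.attrs["random_intercept_var"] = self.random_intercept_var
        tab.attrs["random_slope_var"] = self.random_slope_var
        tab.attrs["n_obs"] = self.n_obs
        tab.attrs["family"] = self.family
        return tab

    def to_dict(self) -> dict:
        return {
            "coefficients": {k: list(map(float, v)) for k, v in self.coefficients.items()},
            "loglik": float(self.loglik),
            "random_intercept_var": float(self.random_intercept_var),
            "random_slope_var": float(self.random_slope_var),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "family": self.family,
            "formula": self.formula,
        }


@dataclass
class MediationResult:
    """Indirect (a*b) effect with a bootstrap percentile interval."""

    a_path: float
    b_path: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int

    @property
    def significant(self) -> bool:
        """True iff zero lies outside the 95% bootstrap interval."""
        return not (self.ci_low <= 0.0 <= self.ci_high)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "a_path": [self.a_path],
                "b_path": [self.b_path],
                "indirect": [self.indirect],
                "ci_low": [self.ci_low],
                "ci_high": [self.ci_high],
                "n_boot": [self.n_boot],
                "significant": [self.significant],
            }
        )

    def to_dict(self) -> dict:
        return {
            "a_path": float(self.a_path),
            "b_path": float(self.b_path),
            "indirect": float(self.indirect),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "n_boot": int(self.n_boot),
            "significant": bool(self.significant),
        }


@dataclass
class RegressionResult:
    """OLS fit on across-participant z-scored variables.

    ``coefficients`` maps each term to ``(standardized beta, se, p)``.
    """

    coefficients: Mapping[str, tuple]
    r2: float
    adjusted_r2: float
    n: int

    def beta(self, term: str) -> float:
        return self.coefficients[term][0]

    def pvalue(self, term: str) -> float:
        return self.coefficients[term][2]

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            [(k, *v) for k, v in self.coefficients.items()],
            columns=["term", "beta", "se", "p"],
        ).set_index("term")
        tab.attrs["r2"] = self.r2
        tab.attrs["adjusted_r2"] = self.adjusted_r2
        tab.attrs["n"] = self.n
        return tab

    def to_dict(self) -> dict:
        return {
            "coefficients": {k: list(map(float, v)) for k, v in self.coefficients.items()},
            "r2": float(self.r2),
            "adjusted_r2": float(self.adjusted_r2),
            "n": int(self.n),
        }


@dataclass
class ClassifierSpec:
    """Hyper-parameters of the category classifier pipeline.

    Defaults follow the standard configuration for this paradigm: an
    L2-penalised logistic regression with C = 1, 10 balanced subsampling
    iterations, the top 250 voxels per category selected at encoding, and a
    1000-iteration permutation null.
    """

    inverse_regularization: float = 1.0
    n_subsamples: int = 10
    n_features_per_category: int = 250
    n_permutations: int = 1000
    clip_eps: float = 1e-6
    select_within_folds: bool = True
    refit_selection_in_permutation: bool = True

    def __post_init__(self) -> None:
        for name in (
            "inverse_regularization",
            "n_subsamples",
            "n_features_per_category",
            "n_permutations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
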