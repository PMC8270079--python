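"""External validation and updating of logistic NTCP models.

Given a new cohort with the model's predictors and observed binary
six-month toxicity outcomes, this module measures discrimination (AUC) and
calibration (intercept and slope of the linear predictor), and decides —
with a closed testing procedure over likelihood-ratio tests — whether the
original model should be kept, its intercept updated, its intercept and
slope recalibrated, or all coefficients revised on the new data.

The nested model sequence, with ``LP`` the original model's linear predictor:

====================  ==========================================  ==========
level                 model                                       free params
====================  ==========================================  ==========
original              logit p = LP                                0
intercept_update      logit p = a + LP          (LP as offset)    1
recalibration         logit p = a + b·LP                          2
revision              logit p = a + x'β        (full refit)       p + 1
====================  ==========================================  ==========

The closed test compares the revised model against each simpler level in
increasing order of complexity (revision vs original, vs intercept update,
vs recalibration), each by a likelihood-ratio chi-square at level ``alpha``,
stopping at the first non-rejection and selecting that simpler level; if
every test rejects, full revision is selected. This controls the overall
type-I error: on data truly generated by the original model, "original" is
kept with probability ``1 − alpha``.

Fits are maximum-likelihood logistic regressions via iteratively reweighted
least squares (statsmodels GLM backend), converged when the relative change
in log-likelihood falls below 1e-10 or after 100 iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .models import ModelSpec, NTCPModel

__all__ = [
    "UPDATE_LEVELS",
    "SeparationWarning",
    "LogisticFit",
    "CalibrationResult",
    "ClosedTestResult",
    "ValidationReport",
    "TRIPOD_LEVELS",
    "auc",
    "refit_logistic",
    "refit_model",
    "calibration",
    "closed_testing_update",
    "apply_update",
    "validate_model",
]

#: Update levels in increasing order of complexity.
UPDATE_LEVELS = ("original", "intercept_update", "recalibration", "revision")

#: Staged-evaluation labels a report may carry (user-declared, not computed).
TRIPOD_LEVELS = ("1a", "1b", "2a", "2b", "3", "4a", "4b")

#: |coefficient| beyond which a fit is flagged as (quasi-)separated.
SEPARATION_BOUND = 15.0

_CONVERGENCE_TOL = 1e-10
_MAX_ITER = 100


class SeparationWarning(UserWarning):
    """A logistic fit produced implausibly large coefficients."""


def auc(scores, outcomes) -> float:
    """Concordance (c) statistic: P(random event outscores random non-event).

    Ties count 1/2. Requires at least one event and one non-event.
    """
    outcomes = np.asarray(outcomes)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != outcomes.shape:
        raise ValueError("scores and outcomes must have the same length")
    if not np.isin(outcomes, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    n_events = int(outcomes.sum())
    if n_events == 0 or n_events == len(outcomes):
        raise ValueError("AUC undefined: need at least one event and one non-event")
    return float(roc_auc_score(outcomes, scores))


def _check_outcomes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("degenerate outcome vector: need both events and non-events")
    return y


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit: intercept-first coefficient series."""

    params: pd.Series
    loglik: float
    converged: bool
    separation_flag: bool
    bse: pd.Series
    n: int
    events: int

    @property
    def intercept(self) -> float:
        return float(self.params.iloc[0])


def refit_logistic(
    X: pd.DataFrame | None,
    y,
    offset: np.ndarray | None = None,
    add_intercept: bool = True,
) -> LogisticFit:
    """Fit a logistic regression of ``y`` on ``X`` (plus optional fixed offset).

    ``X=None`` fits an intercept-only model. Rank-deficient designs raise;
    coefficients beyond ``SEPARATION_BOUND`` emit :class:`SeparationWarning`
    and set ``separation_flag``.
    """
    y = _check_outcomes(y)
    n = len(y)
    if X is None:
        X = pd.DataFrame(index=pd.RangeIndex(n))
    else:
        X = pd.DataFrame(X).astype(float).reset_index(drop=True)
        if len(X) != n:
            raise ValueError("design and outcome lengths differ")
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    if design.shape[1] == 0:
        raise ValueError("empty design: nothing to fit")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient design: rank {rank} < {design.shape[1]} columns"
        )
    model = sm.GLM(y, design, family=sm.families.Binomial(), offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels chatters on near-separation
        res = model.fit(maxiter=_MAX_ITER, tol=_CONVERGENCE_TOL)
    params = pd.Series(res.params, index=design.columns)
    separated = bool((params.abs() > SEPARATION_BOUND).any())
    if separated:
        warnings.warn(
            "logistic fit has |coefficient| > "
            f"{SEPARATION_BOUND}; data may be (quasi-)separated",
            SeparationWarning,
            stacklevel=2,
        )
    return LogisticFit(
        params=params,
        loglik=float(res.llf),
        converged=bool(res.converged),
        separation_flag=separated,
        bse=pd.Series(res.bse, index=design.columns),
        n=n,
        events=int(y.sum()),
    )


def refit_model(
    cohort: pd.DataFrame,
    model: ModelSpec,
    outcome: str = "outcome",
    merge_equal_dose_terms: bool = False,
) -> tuple[ModelSpec, LogisticFit]:
    """Re-estimate every coefficient of ``model`` on a new cohort.

    With ``merge_equal_dose_terms`` the model's dose terms are summed into a
    single predictor before fitting (the remedy for collinear organ doses,
    e.g. oral cavity and superior constrictor); the fitted per-Gy
    coefficient is then applied to each merged organ.
    """
    X = NTCPModel(model).design_matrix(cohort)
    dose_cols = list(model.dose_coefficients)
    if merge_equal_dose_terms and len(dose_cols) > 1:
        merged = X[dose_cols].sum(axis=1)
        X = X.drop(columns=dose_cols)
        X.insert(0, "dose_sum", merged)
    fit = refit_logistic(X, cohort[outcome].to_numpy())
    params = fit.params
    if merge_equal_dose_terms and len(dose_cols) > 1:
        dose_coefficients = {oar: float(params["dose_sum"]) for oar in dose_cols}
    else:
        dose_coefficients = {oar: float(params[oar]) for oar in dose_cols}
    updated = model.replace(
        intercept=float(params["const"]),
        dose_coefficients=dose_coefficients,
        clinical_coefficients={
            key: float(params[key]) for key in model.clinical_coefficients
        },
    )
    return updated, fit


@dataclass
class CalibrationResult:
    """Calibration-in-the-large and calibration slope on a new cohort.

    ``intercept`` is fitted with the linear predictor as a fixed offset: a
    negative value means the model overpredicts on the new data. ``slope``
    is the coefficient of the linear predictor in a logistic refit; 1 means
    the spread of predictions is right, < 1 means overfitting.
    """

    intercept: float
    slope: float
    slope_se: float
    n: int
    events: int


def calibration(
    cohort: pd.DataFrame, model: ModelSpec, outcome: str = "outcome"
) -> CalibrationResult:
    lp = NTCPModel(model).linear_predictor(cohort)
    if np.ptp(lp) == 0:
        raise ValueError("constant linear predictor: calibration slope is not identifiable")
    y = cohort[outcome].to_numpy()
    slope_fit = refit_logistic(pd.DataFrame({"lp": lp}), y)
    intercept_fit = refit_logistic(None, y, offset=lp)
    return CalibrationResult(
        intercept=intercept_fit.intercept,
        slope=float(slope_fit.params["lp"]),
        slope_se=float(slope_fit.bse["lp"]),
        n=len(y),
        events=int(np.sum(y)),
    )


@dataclass
class LRTest:
    """One likelihood-ratio test in the closed-testing traversal."""

    comparison: str
    chi2: float
    df: int
    p_value: float
    rejected: bool


@dataclass
class ClosedTestResult:
    selected_update: str
    tests: list[LRTest]
    loglik: dict[str, float]
    updated_model: ModelSpec
    alpha: float
    fits: dict = field(default_factory=dict, repr=False)


def _bernoulli_loglik(y: np.ndarray, lp: np.ndarray) -> float:
    # log L = Σ y·lp − log(1 + e^lp), numerically via logaddexp
    return float(np.sum(y * lp - np.logaddexp(0.0, lp)))


def closed_testing_update(
    cohort: pd.DataFrame,
    original: ModelSpec,
    alpha: float = 0.05,
    outcome: str = "outcome",
) -> ClosedTestResult:
    """Closed-testing choice among original / intercept update / recalibration / revision.

    Likelihood-ratio chi-squares compare the fully revised model against
    each simpler level in increasing complexity; traversal stops at the
    first non-rejection and that level is selected.
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    evaluator = NTCPModel(original)
    lp = evaluator.linear_predictor(cohort)
    y = _check_outcomes(cohort[outcome].to_numpy())

    ll = {"original": _bernoulli_loglik(y, lp)}
    try:
        fit_intercept = refit_logistic(None, y, offset=lp)
        fit_recal = refit_logistic(pd.DataFrame({"lp": lp}), y)
        revised_model, fit_rev = refit_model(cohort, original, outcome=outcome)
    except ValueError as exc:
        raise ValueError(f"closed-testing refit failed: {exc}") from exc
    ll["intercept_update"] = fit_intercept.loglik
    ll["recalibration"] = fit_recal.loglik
    ll["revision"] = fit_rev.loglik

    n_free = {"original": 0, "intercept_update": 1, "recalibration": 2,
              "revision": len(original.predictor_names) + 1}
    tests: list[LRTest] = []
    selected = "revision"
    for level in ("original", "intercept_update", "recalibration"):
        df = n_free["revision"] - n_free[level]
        chi2 = max(0.0, 2.0 * (ll["revision"] - ll[level]))
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
        rejected = p < alpha
        tests.append(LRTest(f"revision_vs_{level}", chi2, df, p, rejected))
        if not rejected:
            selected = level
            break

    if selected == "original":
        updated = original
    elif selected == "intercept_update":
        updated = original.replace(intercept=original.intercept + fit_intercept.intercept)
    elif selected == "recalibration":
        a = float(fit_recal.params["const"])
        b = float(fit_recal.params["lp"])
        updated = original.replace(
            intercept=a + b * original.intercept,
            dose_coefficients={k: b * v for k, v in original.dose_coefficients.items()},
            clinical_coefficients={
                k: b * v for k, v in original.clinical_coefficients.items()
            },
        )
    else:
        updated = revised_model

    return ClosedTestResult(
        selected_update=selected,
        tests=tests,
        loglik=ll,
        updated_model=updated,
        alpha=alpha,
        fits={
            "intercept_update": fit_intercept,
            "recalibration": fit_recal,
            "revision": fit_rev,
        },
    )


def apply_update(result: ClosedTestResult) -> ModelSpec:
    """Coefficient set implied by the selected update level."""
    return result.updated_model


@dataclass
class ValidationReport:
    """External-validation summary for one model on one cohort."""

    model_name: str
    n: int
    events: int
    auc: float
    calibration_intercept: float
    calibration_slope: float
    tripod_level: str | None = None

    def __post_init__(self):
        if self.tripod_level is not None and self.tripod_level not in TRIPOD_LEVELS:
            raise ValueError(
                f"tripod_level must be one of {TRIPOD_LEVELS}, got {self.tripod_level!r}"
            )

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model": self.model_name,
            "n": self.n,
            "events": self.events,
            "auc": round(self.auc, 4),
            "calibration_intercept": round(self.calibration_intercept, 4),
            "calibration_slope": round(self.calibration_slope, 4),
            "tripod_level": self.tripod_level,
        }


def validate_model(
    cohort: pd.DataFrame,
    model: ModelSpec,
    outcome: str = "outcome",
    tripod_level: str | None = None,
) -> ValidationReport:
    """Discrimination + calibration of ``model`` on a cohort with outcomes.

    Operates on complete cases: rows missing any required predictor or the
    outcome must be dropped by the caller beforehand.
    """
    lp = NTCPModel(model).linear_predictor(cohort)
    y = cohort[outcome].to_numpy()
    cal = calibration(cohort, model, outcome=outcome)
    return ValidationReport(
        model_name=model.name,
        n=len(y),
        events=int(np.sum(y)),
        auc=auc(lp, y),
        calibration_intercept=cal.intercept,
        calibration_slope=cal.slope,
        tripod_level=tripod_level,
    )
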