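"""Normal tissue complication probability (NTCP) models for head-and-neck radiotherapy.

The Dutch national indication protocol for proton therapy in head-and-neck
cancer selects patients with three logistic NTCP models, one per toxicity
endpoint at six months after radiotherapy:

* moderate-to-severe patient-rated xerostomia (CTCAE grade 2),
* grade II-IV physician-rated dysphagia (CTCAE grade 2),
* tube feeding dependence (CTCAE grade 3).

Each model is a logistic regression over organ-at-risk mean doses (Gy) and
categorical clinical factors:

    NTCP = 1 / (1 + exp(-LP)),
    LP   = intercept + sum_j beta_j * D_mean,j + sum_k gamma_k * 1[level_k]

Coefficient sets are data, not code: they live in ``data/default_models.json``
and are loaded into :class:`ModelSpec` objects, so revised coefficient tables
can be swapped in without a code change.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "DOSE_COLUMNS",
    "ENUM_FACTORS",
    "BOOLEAN_FACTORS",
    "CLINICAL_COLUMNS",
    "MissingPredictorError",
    "ModelSpec",
    "EndpointResult",
    "NTCPModel",
    "logistic",
    "linear_predictor",
    "ntcp",
    "ntcp_profile",
    "default_models",
    "load_models",
    "dump_models",
]

#: Organ-at-risk mean-dose columns (Gy) known to the engine.
DOSE_COLUMNS: tuple[str, ...] = (
    "parotid_contralateral_mean",
    "oral_cavity_mean",
    "pcm_superior_mean",
    "pcm_inferior_mean",
    "cricopharyngeal_mean",
)

#: Categorical clinical factors and their admissible levels. The first level
#: of each factor is the reference level (implicit coefficient 0).
ENUM_FACTORS: dict[str, tuple[str, ...]] = {
    "xer_baseline": ("none", "minor", "moderate_severe"),
    "weight_loss": ("none", "moderate_1_10pct", "severe_gt10pct"),
    "treatment": (
        "conventional_rt_alone",
        "accelerated_rt",
        "chemoradiation",
        "rt_plus_cetuximab",
    ),
}

#: Binary clinical factors (0/1 indicators).
BOOLEAN_FACTORS: tuple[str, ...] = ("dysphagia_baseline_ge2", "advanced_t_stage")

CLINICAL_COLUMNS: tuple[str, ...] = tuple(ENUM_FACTORS) + BOOLEAN_FACTORS

#: Upper sanity bound on a mean dose in Gy (configurable at the I/O layer).
DEFAULT_DOSE_CAP = 80.0


class MissingPredictorError(KeyError):
    """A predictor required by a model is absent from the input record."""

    def __init__(self, model_name: str, predictor: str):
        super().__init__(predictor)
        self.model_name = model_name
        self.predictor = predictor

    def __str__(self) -> str:  # KeyError quotes its arg; give a real message
        return f"model {self.model_name!r} requires predictor {self.predictor!r}, which is missing"


def logistic(lp: float) -> float:
    """Logistic (inverse-logit) link: ``1 / (1 + exp(-lp))``.

    Raises ``ValueError`` on non-finite input.
    """
    lp = float(lp)
    if not math.isfinite(lp):
        raise ValueError(f"linear predictor must be finite, got {lp!r}")
    return float(expit(lp))


def _validate_clinical_key(key: str) -> None:
    if key in BOOLEAN_FACTORS:
        return
    factor, sep, level = key.partition("=")
    if sep and factor in ENUM_FACTORS:
        levels = ENUM_FACTORS[factor]
        if level == levels[0]:
            raise ValueError(
                f"clinical coefficient {key!r} targets the reference level; "
                "reference levels carry an implicit coefficient of 0"
            )
        if level in levels:
            return
    raise ValueError(f"unknown clinical coefficient key {key!r}")


@dataclass(frozen=True)
class ModelSpec:
    """A named logistic NTCP model: endpoint, CTCAE grade and coefficients.

    ``dose_coefficients`` maps organ-at-risk column names to per-Gy
    coefficients; ``clinical_coefficients`` maps indicator keys to
    coefficients. Indicator keys are either a boolean factor name
    (``"advanced_t_stage"``) or ``"factor=level"`` for one non-reference
    level of a categorical factor (``"xer_baseline=minor"``).
    """

    name: str
    endpoint: str
    grade: int
    intercept: float
    dose_coefficients: Mapping[str, float] = field(default_factory=dict)
    clinical_coefficients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.grade not in (2, 3, 4):
            raise ValueError(f"CTCAE grade must be 2, 3 or 4, got {self.grade}")
        for oar in self.dose_coefficients:
            if oar not in DOSE_COLUMNS:
                raise ValueError(f"unknown organ-at-risk dose column {oar!r}")
        for key in self.clinical_coefficients:
            _validate_clinical_key(key)
        object.__setattr__(self, "dose_coefficients", dict(self.dose_coefficients))
        object.__setattr__(
            self, "clinical_coefficients", dict(self.clinical_coefficients)
        )

    @property
    def required_clinical_factors(self) -> tuple[str, ...]:
        """Clinical factor columns this model reads."""
        factors = []
        for key in self.clinical_coefficients:
            factor = key.partition("=")[0]
            if factor not in factors:
                factors.append(factor)
        return tuple(factors)

    @property
    def predictor_names(self) -> tuple[str, ...]:
        """Design-matrix column order: dose terms then clinical indicators."""
        return tuple(self.dose_coefficients) + tuple(self.clinical_coefficients)

    @property
    def coefficients(self) -> dict[str, float]:
        return {**self.dose_coefficients, **self.clinical_coefficients}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "endpoint": self.endpoint,
            "grade": self.grade,
            "intercept": self.intercept,
            "dose_coefficients": dict(self.dose_coefficients),
            "clinical_coefficients": dict(self.clinical_coefficients),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            name=d["name"],
            endpoint=d["endpoint"],
            grade=int(d["grade"]),
            intercept=float(d["intercept"]),
            dose_coefficients={k: float(v) for k, v in d.get("dose_coefficients", {}).items()},
            clinical_coefficients={
                k: float(v) for k, v in d.get("clinical_coefficients", {}).items()
            },
        )

    def replace(self, **changes) -> "ModelSpec":
        d = self.to_dict()
        d.update(changes)
        return ModelSpec.from_dict(d)


def _indicator(key: str, clinical: Mapping, model_name: str) -> float:
    """Evaluate one clinical indicator on a record; error if the factor is missing."""
    factor, sep, level = key.partition("=")
    try:
        value = clinical[factor]
    except KeyError:
        raise MissingPredictorError(model_name, factor) from None
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingPredictorError(model_name, factor)
    if not sep:  # boolean factor
        if isinstance(value, str):
            raise ValueError(f"factor {factor!r} must be boolean, got {value!r}")
        return 1.0 if value else 0.0
    if value not in ENUM_FACTORS[factor]:
        raise ValueError(
            f"invalid level {value!r} for factor {factor!r}; "
            f"expected one of {ENUM_FACTORS[factor]}"
        )
    return 1.0 if value == level else 0.0


def linear_predictor(model: ModelSpec, doses: Mapping, clinical: Mapping) -> float:
    """Evaluate ``LP = intercept + Σ β·D_mean + Σ γ·indicator`` for one record.

    ``doses`` and ``clinical`` are mappings (dict, Series, dataclass asdict)
    keyed by the canonical column names. Only the predictors named by the
    model are required; a missing one raises :class:`MissingPredictorError`
    rather than silently defaulting.
    """
    lp = float(model.intercept)
    for oar, coef in model.dose_coefficients.items():
        try:
            dose = doses[oar]
        except KeyError:
            raise MissingPredictorError(model.name, oar) from None
        if dose is None or (isinstance(dose, float) and math.isnan(dose)):
            raise MissingPredictorError(model.name, oar)
        dose = float(dose)
        if dose < 0:
            raise ValueError(f"negative mean dose {dose} Gy for {oar!r}")
        lp += coef * dose
    for key, coef in model.clinical_coefficients.items():
        lp += coef * _indicator(key, clinical, model.name)
    return lp


def ntcp(model: ModelSpec, doses: Mapping, clinical: Mapping) -> float:
    """Complication probability for one patient/plan under one model."""
    return logistic(linear_predictor(model, doses, clinical))


@dataclass(frozen=True)
class EndpointResult:
    """NTCP evaluation of a single endpoint model."""

    endpoint: str
    grade: int
    linear_predictor: float
    ntcp: float


def ntcp_profile(
    doses: Mapping,
    clinical: Mapping,
    models: Sequence[ModelSpec] | None = None,
) -> dict[str, EndpointResult]:
    """Per-endpoint NTCP profile (default: the three national models)."""
    if models is None:
        models = default_models()
    profile = {}
    for model in models:
        lp = linear_predictor(model, doses, clinical)
        profile[model.name] = EndpointResult(
            endpoint=model.endpoint,
            grade=model.grade,
            linear_predictor=lp,
            ntcp=logistic(lp),
        )
    return profile


class NTCPModel:
    """Vectorised evaluator for a :class:`ModelSpec` over cohort DataFrames.

    Exposes an sklearn-flavoured surface (``linear_predictor`` /
    ``predict_proba``) but carries fixed, published coefficients — nothing is
    fitted here; refitting lives in :mod:`ntcp_select.validation`.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec

    def design_matrix(self, df: pd.DataFrame) -> pd.DataFrame:
        """Numeric design matrix (no intercept column) in coefficient order."""
        cols = {}
        for oar in self.spec.dose_coefficients:
            if oar not in df.columns:
                raise MissingPredictorError(self.spec.name, oar)
            dose = pd.to_numeric(df[oar])
            if dose.isna().any() or (dose < 0).any():
                bad = df.index[dose.isna() | (dose < 0)][0]
                raise ValueError(f"missing or negative dose in column {oar!r} at row {bad}")
            cols[oar] = dose.astype(float)
        for key in self.spec.clinical_coefficients:
            factor, sep, level = key.partition("=")
            if factor not in df.columns:
                raise MissingPredictorError(self.spec.name, factor)
            if sep:
                values = df[factor]
                unknown = ~values.isin(ENUM_FACTORS[factor])
                if unknown.any():
                    bad = values[unknown].iloc[0]
                    raise ValueError(f"invalid level {bad!r} for factor {factor!r}")
                cols[key] = (values == level).astype(float)
            else:
                cols[key] = df[factor].astype(float)
        return pd.DataFrame(cols, index=df.index)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X = self.design_matrix(df)
        beta = np.array([self.spec.coefficients[c] for c in X.columns])
        return self.spec.intercept + X.to_numpy() @ beta

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        """NTCP per row, as a fraction in (0, 1)."""
        return expit(self.linear_predictor(df))


def _transcription_guard(models: Iterable[ModelSpec]) -> None:
    # Guard against sign/transcription slips in shipped coefficient files:
    # in all published national models doses increase risk and no clinical
    # level is protective.
    for m in models:
        for oar, coef in m.dose_coefficients.items():
            if coef <= 0:
                raise ValueError(f"{m.name}: dose coefficient for {oar} must be positive")
        for key, coef in m.clinical_coefficients.items():
            if coef < 0:
                raise ValueError(f"{m.name}: clinical coefficient for {key} must be nonnegative")


def load_models(source) -> tuple[ModelSpec, ...]:
    """Load a coefficient file (JSON list of model objects) into ModelSpecs."""
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    if isinstance(payload, Mapping) and "models" in payload:
        payload = payload["models"]
    models = tuple(ModelSpec.from_dict(d) for d in payload)
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate model names in coefficient file: {names}")
    return models


def dump_models(models: Sequence[ModelSpec], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([m.to_dict() for m in models], fh, indent=2)
        fh.write("\n")


_DEFAULTS: tuple[ModelSpec, ...] | None = None


def default_models() -> tuple[ModelSpec, ...]:
    """The three national NTCP models (xerostomia, dysphagia, tube feeding)."""
    global _DEFAULTS
    if _DEFAULTS is None:
        ref = resources.files("ntcp_select.data").joinpath("default_models.json")
        with ref.open("r", encoding="utf-8") as fh:
            models = load_models(fh)
        _transcription_guard(models)
        _DEFAULTS = models
    return _DEFAULTS
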