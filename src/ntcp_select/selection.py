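"""The national model-based selection flowchart for proton therapy.

A patient traverses three stages:

1. **Eligibility gate** — primary tumour in the pharynx, larynx or oral
   cavity; no distant metastases; curative intent.
2. **ΔNTCP_max pre-screen** — with the photon plan in hand, the best-case
   toxicity reduction per endpoint is ``ΔNTCP_max = NTCP(photon doses) −
   NTCP(all model doses = 0)``, i.e. protons are assumed to clear every
   organ-at-risk in the model. A proton plan comparison is indicated only if
   the national thresholds could be reached at this bound.
3. **Qualification** — with a real proton plan, ``ΔNTCP = NTCP_photon −
   NTCP_proton`` per endpoint; the patient qualifies if a single endpoint
   meets its grade's threshold, or if two endpoints of the *same* CTCAE
   grade jointly meet the summed threshold. No summation across grades.

All ΔNTCP values are handled in percentage points; threshold comparisons are
inclusive (≥) and performed at full floating precision — rounding only
happens in reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .models import (
    MissingPredictorError,
    ModelSpec,
    default_models,
    linear_predictor,
    logistic,
    ntcp,
)

__all__ = [
    "TUMOR_SITES",
    "ThresholdPolicy",
    "DEFAULT_POLICY",
    "EligibilityGate",
    "TriggeredRule",
    "SelectionDecision",
    "delta_ntcp",
    "delta_ntcp_max",
    "triggered_rules",
    "plan_comparison_indicated",
    "qualifies",
    "select_patient",
    "screen_cohort",
]

TUMOR_SITES = ("pharynx", "larynx", "oral_cavity", "other")
_ELIGIBLE_SITES = frozenset({"pharynx", "larynx", "oral_cavity"})


@dataclass(frozen=True)
class ThresholdPolicy:
    """National ΔNTCP thresholds in percentage points, per CTCAE grade.

    ``single`` applies to one endpoint; ``summed`` to the sum of two
    endpoints of the same grade. Defaults are the thresholds fixed by the
    Dutch radiation-oncology society: 10/5/2 pp single and 15/7.5/3 pp
    summed for grades ≥II/≥III/≥IV.
    """

    single: Mapping[int, float] = field(
        default_factory=lambda: {2: 10.0, 3: 5.0, 4: 2.0}
    )
    summed: Mapping[int, float] = field(
        default_factory=lambda: {2: 15.0, 3: 7.5, 4: 3.0}
    )

    def __post_init__(self):
        object.__setattr__(self, "single", dict(self.single))
        object.__setattr__(self, "summed", dict(self.summed))
        for table in (self.single, self.summed):
            for g, t in table.items():
                if t <= 0:
                    raise ValueError(f"threshold for grade {g} must be positive, got {t}")
        if set(self.summed) != set(self.single):
            raise ValueError("single and summed threshold tables must cover the same grades")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThresholdPolicy":
        return cls(
            single={int(k): float(v) for k, v in d["single"].items()},
            summed={int(k): float(v) for k, v in d["summed"].items()},
        )

    def to_dict(self) -> dict:
        return {
            "single": {str(k): v for k, v in self.single.items()},
            "summed": {str(k): v for k, v in self.summed.items()},
        }


DEFAULT_POLICY = ThresholdPolicy()


@dataclass(frozen=True)
class EligibilityGate:
    """General eligibility criteria for proton-therapy consideration."""

    tumor_site: str
    distant_metastases: bool = False
    curative_intent: bool = True

    def __post_init__(self):
        if self.tumor_site not in TUMOR_SITES:
            raise ValueError(
                f"unknown tumor site {self.tumor_site!r}; expected one of {TUMOR_SITES}"
            )

    @property
    def passed(self) -> bool:
        return (
            self.tumor_site in _ELIGIBLE_SITES
            and not self.distant_metastases
            and self.curative_intent
        )


@dataclass(frozen=True)
class TriggeredRule:
    """Record of one threshold rule that fired."""

    rule: str  # "single" or "summed"
    grade: int
    endpoints: tuple[str, ...]
    value_pp: float
    threshold_pp: float


@dataclass
class SelectionDecision:
    """Full record of one flowchart traversal."""

    gate_passed: bool
    plan_comparison_indicated: bool = False
    qualifies: bool = False
    ntcp_photon: dict[str, float] = field(default_factory=dict)
    ntcp_proton: dict[str, float] = field(default_factory=dict)
    delta_max_pp: dict[str, float] = field(default_factory=dict)
    delta_pp: dict[str, float] = field(default_factory=dict)
    triggered_rules: list[TriggeredRule] = field(default_factory=list)
    patient_id: str | None = None

    def __post_init__(self):
        if self.qualifies and not self.plan_comparison_indicated:
            raise ValueError("qualifies implies plan_comparison_indicated")
        if self.plan_comparison_indicated and not self.gate_passed:
            raise ValueError("plan_comparison_indicated implies gate_passed")


def _zero_doses(model: ModelSpec) -> dict[str, float]:
    return {oar: 0.0 for oar in model.dose_coefficients}


def delta_ntcp(
    photon_doses: Mapping, proton_doses: Mapping, clinical: Mapping, model: ModelSpec
) -> float:
    """ΔNTCP = 100 × (NTCP_photon − NTCP_proton), in percentage points."""
    return 100.0 * (ntcp(model, photon_doses, clinical) - ntcp(model, proton_doses, clinical))


def delta_ntcp_max(photon_doses: Mapping, clinical: Mapping, model: ModelSpec) -> float:
    """Best-case ΔNTCP in pp, zeroing every dose term of the model.

    Clinical covariates are held fixed; only the organ-at-risk doses the
    model reads are set to 0 Gy.
    """
    lp_photon = linear_predictor(model, photon_doses, clinical)
    lp_zero = linear_predictor(model, _zero_doses(model), clinical)
    return 100.0 * (logistic(lp_photon) - logistic(lp_zero))


def triggered_rules(
    deltas_pp: Mapping[str, float],
    grades: Mapping[str, int],
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> list[TriggeredRule]:
    """Apply the single and same-grade-pair summed rules to a ΔNTCP profile.

    Comparisons are inclusive and use signed values: a negative ΔNTCP
    (proton worse on that endpoint) never fires a single rule and enters a
    pair sum with its sign.
    """
    rules: list[TriggeredRule] = []
    for name, delta in deltas_pp.items():
        grade = grades[name]
        threshold = policy.single.get(grade)
        if threshold is not None and delta >= threshold:
            rules.append(TriggeredRule("single", grade, (name,), delta, threshold))
    for a, b in itertools.combinations(sorted(deltas_pp), 2):
        if grades[a] != grades[b]:
            continue
        grade = grades[a]
        threshold = policy.summed.get(grade)
        total = deltas_pp[a] + deltas_pp[b]
        if threshold is not None and total >= threshold:
            rules.append(TriggeredRule("summed", grade, (a, b), total, threshold))
    return rules


def qualifies(
    deltas_pp: Mapping[str, float],
    grades: Mapping[str, int],
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> tuple[bool, list[TriggeredRule]]:
    """Threshold qualification for a ΔNTCP profile: (verdict, fired rules)."""
    rules = triggered_rules(deltas_pp, grades, policy)
    return bool(rules), rules


def plan_comparison_indicated(
    photon_doses: Mapping,
    clinical: Mapping,
    models: Sequence[ModelSpec] | None = None,
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> tuple[bool, dict[str, float]]:
    """Pre-screen: could the thresholds be reached at the ΔNTCP_max bound?

    Returns the verdict and the per-endpoint ΔNTCP_max values (pp). The
    summed rule is mirrored at this stage: a comparison is worthwhile if a
    same-grade pair could jointly reach the summed threshold.
    """
    if models is None:
        models = default_models()
    delta_max = {m.name: delta_ntcp_max(photon_doses, clinical, m) for m in models}
    grades = {m.name: m.grade for m in models}
    indicated, _ = qualifies(delta_max, grades, policy)
    return indicated, delta_max


def select_patient(
    gate: EligibilityGate,
    photon_doses: Mapping | None = None,
    proton_doses: Mapping | None = None,
    clinical: Mapping | None = None,
    models: Sequence[ModelSpec] | None = None,
    policy: ThresholdPolicy = DEFAULT_POLICY,
    patient_id: str | None = None,
) -> SelectionDecision:
    """Traverse the full selection flowchart for one patient.

    If ``proton_doses`` is None the traversal stops after the ΔNTCP_max
    pre-screen (the clinical situation before a proton plan is made). A
    failed gate short-circuits: no NTCP is computed.
    """
    if not gate.passed:
        return SelectionDecision(gate_passed=False, patient_id=patient_id)
    if photon_doses is None or clinical is None:
        raise ValueError("photon doses and clinical factors are required once the gate passes")
    if models is None:
        models = default_models()
    grades = {m.name: m.grade for m in models}

    indicated, delta_max = plan_comparison_indicated(photon_doses, clinical, models, policy)
    ntcp_photon = {m.name: ntcp(m, photon_doses, clinical) for m in models}
    decision = SelectionDecision(
        gate_passed=True,
        plan_comparison_indicated=indicated,
        ntcp_photon=ntcp_photon,
        delta_max_pp=delta_max,
        patient_id=patient_id,
    )
    if not indicated or proton_doses is None:
        return decision

    ntcp_proton = {m.name: ntcp(m, proton_doses, clinical) for m in models}
    deltas = {
        name: 100.0 * (ntcp_photon[name] - ntcp_proton[name]) for name in ntcp_photon
    }
    verdict, rules = qualifies(deltas, grades, policy)
    decision.ntcp_proton = ntcp_proton
    decision.delta_pp = deltas
    decision.qualifies = verdict
    decision.triggered_rules = rules
    return decision


_GATE_COLUMNS = ("tumor_site", "distant_metastases", "curative_intent")


def _gate_from_row(row: Mapping) -> EligibilityGate:
    return EligibilityGate(
        tumor_site=row.get("tumor_site", "other"),
        distant_metastases=bool(row.get("distant_metastases", False)),
        curative_intent=bool(row.get("curative_intent", True)),
    )


def screen_cohort(
    patients: pd.DataFrame,
    photon_plans: pd.DataFrame,
    proton_plans: pd.DataFrame | None = None,
    models: Sequence[ModelSpec] | None = None,
    policy: ThresholdPolicy = DEFAULT_POLICY,
    strict: bool = True,
) -> tuple[list[SelectionDecision], dict]:
    """Row-wise flowchart traversal over a cohort.

    ``patients`` carries ``patient_id``, the clinical factor columns and
    (optionally) the eligibility columns; plan tables carry ``patient_id``
    plus the five organ-at-risk dose columns. Returns the decision list and
    a summary with screened/compared/qualified counts. Row-level errors
    abort in strict mode; otherwise the row is skipped and reported.
    """
    if models is None:
        models = default_models()
    photon_by_id = photon_plans.set_index("patient_id")
    proton_by_id = proton_plans.set_index("patient_id") if proton_plans is not None else None

    decisions: list[SelectionDecision] = []
    errors: list[dict] = []
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        try:
            gate = _gate_from_row(row)
            photon = photon_by_id.loc[pid] if gate.passed else None
            proton = None
            if proton_by_id is not None and pid in proton_by_id.index:
                proton = proton_by_id.loc[pid]
            decisions.append(
                select_patient(
                    gate,
                    photon_doses=photon,
                    proton_doses=proton,
                    clinical=row,
                    models=models,
                    policy=policy,
                    patient_id=str(pid),
                )
            )
        except (KeyError, ValueError, MissingPredictorError) as exc:
            if strict:
                raise
            errors.append({"patient_id": str(pid), "error": str(exc)})
    summary = {
        "screened": len(decisions),
        "gate_passed": sum(d.gate_passed for d in decisions),
        "plan_comparison_indicated": sum(d.plan_comparison_indicated for d in decisions),
        "qualified": sum(d.qualifies for d in decisions),
        "errors": errors,
    }
    return decisions, summary
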