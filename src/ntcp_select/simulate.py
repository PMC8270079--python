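"""Synthetic referral cohorts for exercising the selection and validation tools.

No public dataset accompanies the national protocol, so testable inputs are
simulated with the statistical structure the protocol assumes:

* correlated organ-at-risk mean doses (Gy), truncated at 0 and capped at a
  sanity bound — with a deliberately high correlation between the oral
  cavity and superior pharyngeal constrictor doses, the collinearity that
  motivated merging those dose terms;
* categorical clinical factors drawn from configurable prevalences;
* proton plans as per-organ multiplicatively dose-reduced photon plans,
  emulating the across-the-board dose reductions reported for proton
  planning;
* binary six-month toxicity outcomes drawn as Bernoulli(true NTCP) under
  the published models, so parameter recovery and validation statistics
  have a known truth.

Everything is deterministic given ``(config, seed)``; the seed is split
into independent per-table streams so regenerating one table never
perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import DOSE_COLUMNS, ENUM_FACTORS, ModelSpec, NTCPModel, default_models
from .selection import DEFAULT_POLICY, ThresholdPolicy, screen_cohort

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "generate_cohort",
    "qualification_rate",
]

# Referral-cohort dose levels (Gy) for definitive head-and-neck radiotherapy:
# swallowing structures near the target sit around 30-45 Gy mean dose, the
# spared contralateral parotid lower. Chosen so the latent event fractions
# are of the same order as the published validation cohorts (roughly one
# half, one quarter and one tenth for xerostomia, dysphagia, tube feeding).
_DEFAULT_DOSE_MEANS = {
    "parotid_contralateral_mean": 25.0,
    "oral_cavity_mean": 38.0,
    "pcm_superior_mean": 45.0,
    "pcm_inferior_mean": 30.0,
    "cricopharyngeal_mean": 25.0,
}
_DEFAULT_DOSE_SDS = {
    "parotid_contralateral_mean": 10.0,
    "oral_cavity_mean": 12.0,
    "pcm_superior_mean": 12.0,
    "pcm_inferior_mean": 12.0,
    "cricopharyngeal_mean": 12.0,
}

#: Pairwise dose correlations: a common planning factor links all organs,
#: the oral cavity / superior constrictor pair is nearly collinear.
_BASE_CORR = 0.45
_OC_PCMS_CORR = 0.85

_DEFAULT_PREVALENCES = {
    "xer_baseline": {"none": 0.55, "minor": 0.30, "moderate_severe": 0.15},
    "weight_loss": {"none": 0.60, "moderate_1_10pct": 0.30, "severe_gt10pct": 0.10},
    "treatment": {
        "conventional_rt_alone": 0.30,
        "accelerated_rt": 0.20,
        "chemoradiation": 0.40,
        "rt_plus_cetuximab": 0.10,
    },
    "dysphagia_baseline_ge2": 0.15,
    "advanced_t_stage": 0.50,
}

_DEFAULT_SITES = {"pharynx": 0.45, "larynx": 0.35, "oral_cavity": 0.15, "other": 0.05}


def _default_correlation() -> np.ndarray:
    k = len(DOSE_COLUMNS)
    corr = np.full((k, k), _BASE_CORR)
    np.fill_diagonal(corr, 1.0)
    i = DOSE_COLUMNS.index("oral_cavity_mean")
    j = DOSE_COLUMNS.index("pcm_superior_mean")
    corr[i, j] = corr[j, i] = _OC_PCMS_CORR
    return corr


@dataclass
class SimulationConfig:
    """Study conditions for one simulated referral cohort.

    ``proton_reduction_mean`` is the expected proton/photon dose ratio per
    organ (0 = protons spare the organ completely, 1 = no benefit); each
    patient/organ draws its own ratio with SD ``proton_reduction_sd``,
    clipped to [0, 1].
    """

    n: int = 1000
    seed: int = 0
    dose_means: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DOSE_MEANS))
    dose_sds: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DOSE_SDS))
    dose_correlation: np.ndarray = field(default_factory=_default_correlation)
    clinical_prevalences: Mapping = field(default_factory=lambda: dict(_DEFAULT_PREVALENCES))
    site_prevalences: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SITES))
    proton_reduction_mean: float | Mapping[str, float] = 0.6
    proton_reduction_sd: float = 0.15
    dose_cap: float = 80.0
    true_models: Sequence[ModelSpec] | None = None

    def __post_init__(self):
        corr = np.asarray(self.dose_correlation, dtype=float)
        k = len(DOSE_COLUMNS)
        if corr.shape != (k, k) or not np.allclose(corr, corr.T):
            raise ValueError(f"dose_correlation must be a symmetric {k}x{k} matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("dose_correlation is not positive semi-definite")
        self.dose_correlation = corr
        reductions = self._reduction_means()
        if any(not 0.0 <= r <= 1.0 for r in reductions.values()):
            raise ValueError("proton reduction factors must lie in [0, 1]")
        for factor, prev in self.clinical_prevalences.items():
            if isinstance(prev, Mapping):
                total = sum(prev.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"prevalences for {factor!r} sum to {total}, not 1")

    def _reduction_means(self) -> dict[str, float]:
        if isinstance(self.proton_reduction_mean, Mapping):
            return {oar: float(self.proton_reduction_mean[oar]) for oar in DOSE_COLUMNS}
        return {oar: float(self.proton_reduction_mean) for oar in DOSE_COLUMNS}

    def with_(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass
class SimulatedCohort:
    """Patient, plan and outcome tables plus the latent truth."""

    patients: pd.DataFrame
    photon_plans: pd.DataFrame
    proton_plans: pd.DataFrame
    true_ntcp: pd.DataFrame  # latent photon-plan NTCP per endpoint
    outcomes: pd.DataFrame  # Bernoulli realisations of true_ntcp
    config: SimulationConfig

    def analysis_frame(self) -> pd.DataFrame:
        """Patients + photon-plan doses + outcomes, merged on patient_id.

        This is the shape the validation tools consume (one outcome column
        per endpoint, named ``outcome_<model>``).
        """
        df = self.patients.merge(self.photon_plans, on="patient_id")
        out = self.outcomes.rename(
            columns={c: f"outcome_{c}" for c in self.outcomes.columns if c != "patient_id"}
        )
        return df.merge(out, on="patient_id")


def _draw_categorical(rng, levels, probs, n):
    return rng.choice(levels, size=n, p=probs)


def generate_cohort(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """Draw one cohort under ``config`` (seed defaults to ``config.seed``)."""
    if config is None:
        config = SimulationConfig()
    if seed is not None:
        config = config.with_(seed=seed)
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_doses, rng_clin, rng_proton, rng_out = (np.random.default_rng(s) for s in streams)

    n = config.n
    patient_id = np.array([f"P{i:05d}" for i in range(n)])

    # --- correlated truncated-normal photon doses -------------------------
    means = np.array([config.dose_means[oar] for oar in DOSE_COLUMNS])
    sds = np.array([config.dose_sds[oar] for oar in DOSE_COLUMNS])
    cov = config.dose_correlation * np.outer(sds, sds)
    doses = rng_doses.multivariate_normal(means, cov, size=n, method="svd")
    doses = np.clip(doses, 0.0, config.dose_cap)
    photon = pd.DataFrame(doses, columns=list(DOSE_COLUMNS))
    photon.insert(0, "patient_id", patient_id)
    photon.insert(1, "plan_id", [f"{p}-photon" for p in patient_id])

    # --- clinical factors -------------------------------------------------
    prev = config.clinical_prevalences
    clin = {"patient_id": patient_id}
    for factor, levels in ENUM_FACTORS.items():
        p = [prev[factor][lvl] for lvl in levels]
        clin[factor] = _draw_categorical(rng_clin, list(levels), p, n)
    for factor in ("dysphagia_baseline_ge2", "advanced_t_stage"):
        clin[factor] = rng_clin.random(n) < prev[factor]
    sites = list(config.site_prevalences)
    clin["tumor_site"] = _draw_categorical(
        rng_clin, sites, [config.site_prevalences[s] for s in sites], n
    )
    clin["distant_metastases"] = np.zeros(n, dtype=bool)
    clin["curative_intent"] = np.ones(n, dtype=bool)
    patients = pd.DataFrame(clin)

    # --- proton plans: per-organ dose-reduced photon plans ----------------
    red_means = config._reduction_means()
    proton = photon.copy()
    proton["plan_id"] = [f"{p}-proton" for p in patient_id]
    for oar in DOSE_COLUMNS:
        factors = rng_proton.normal(red_means[oar], config.proton_reduction_sd, size=n)
        factors = np.clip(factors, 0.0, 1.0)
        proton[oar] = photon[oar].to_numpy() * factors

    # --- latent NTCP under the true models, realised outcomes -------------
    models = tuple(config.true_models) if config.true_models is not None else default_models()
    frame = patients.merge(photon, on="patient_id")
    ntcp_cols = {"patient_id": patient_id}
    out_cols = {"patient_id": patient_id}
    for model in models:
        p = NTCPModel(model).predict_proba(frame)
        ntcp_cols[model.name] = p
        out_cols[model.name] = (rng_out.random(n) < p).astype(int)
    return SimulatedCohort(
        patients=patients,
        photon_plans=photon,
        proton_plans=proton,
        true_ntcp=pd.DataFrame(ntcp_cols),
        outcomes=pd.DataFrame(out_cols),
        config=config,
    )


def qualification_rate(
    cohort: SimulatedCohort,
    models: Sequence[ModelSpec] | None = None,
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> dict[str, float]:
    """Screen the cohort and return the flowchart stage rates.

    Returns fractions of the screened cohort: ``gate_passed``,
    ``plan_comparison_indicated`` and ``qualified``.
    """
    _, summary = screen_cohort(
        cohort.patients, cohort.photon_plans, cohort.proton_plans, models=models, policy=policy
    )
    n = max(summary["screened"], 1)
    return {
        "gate_passed": summary["gate_passed"] / n,
        "plan_comparison_indicated": summary["plan_comparison_indicated"] / n,
        "qualified": summary["qualified"] / n,
    }
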