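"""Selection flowchart: eligibility gate, ΔNTCP_max pre-screen, threshold rules."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntcp_select import (
    DOSE_COLUMNS,
    DEFAULT_POLICY,
    EligibilityGate,
    SelectionDecision,
    ThresholdPolicy,
    delta_ntcp,
    delta_ntcp_max,
    qualifies,
    screen_cohort,
    select_patient,
)
from ntcp_select.selection import plan_comparison_indicated, triggered_rules

from conftest import expit_ref

GRADES_DEFAULT = {"xerostomia": 2, "dysphagia": 2, "tube_feeding": 3}


class TestThresholdPolicy:
    def test_default_tables(self):
        assert DEFAULT_POLICY.single == {2: 10.0, 3: 5.0, 4: 2.0}
        assert DEFAULT_POLICY.summed == {2: 15.0, 3: 7.5, 4: 3.0}

    def test_summed_is_one_and_a_half_times_single(self):
        for g in DEFAULT_POLICY.single:
            assert DEFAULT_POLICY.summed[g] == pytest.approx(1.5 * DEFAULT_POLICY.single[g])

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            ThresholdPolicy(single={2: 0.0, 3: 5, 4: 2}, summed={2: 15, 3: 7.5, 4: 3})


class TestEligibilityGate:
    @pytest.mark.parametrize("site", ["pharynx", "larynx", "oral_cavity"])
    def test_eligible_sites_pass(self, site):
        assert EligibilityGate(site).passed

    def test_other_site_fails(self):
        assert not EligibilityGate("other").passed

    def test_metastases_or_palliative_fail(self):
        assert not EligibilityGate("pharynx", distant_metastases=True).passed
        assert not EligibilityGate("pharynx", curative_intent=False).passed


class TestDeltaNTCPMax:
    def test_xerostomia_hand_value(self, models_by_name, zero_doses):
        # logistic(-1.507+1.3+0.525) - logistic(-1.507+0.525) = 30.6 pp
        doses = dict(zero_doses, parotid_contralateral_mean=25.0)
        clinical = {"xer_baseline": "minor"}
        dmax = delta_ntcp_max(doses, clinical, models_by_name["xerostomia"])
        expected = 100 * (expit_ref(-1.507 + 1.3 + 0.525) - expit_ref(-1.507 + 0.525))
        assert dmax == pytest.approx(expected, abs=1e-9)
        assert dmax == pytest.approx(30.6, abs=0.05)

    def test_dysphagia_hand_value(self, models_by_name, zero_doses, reference_clinical):
        doses = dict(zero_doses, oral_cavity_mean=40.0, pcm_superior_mean=50.0)
        dmax = delta_ntcp_max(doses, reference_clinical, models_by_name["dysphagia"])
        assert dmax == pytest.approx(100 * (expit_ref(-1.143) - expit_ref(-3.303)), abs=1e-9)
        assert dmax == pytest.approx(20.6, abs=0.05)

    def test_zero_photon_doses_give_zero_bound(self, models, zero_doses, reference_clinical):
        for model in models:
            assert delta_ntcp_max(zero_doses, reference_clinical, model) == pytest.approx(0.0)

    def test_clinical_factors_held_fixed(self, models_by_name, zero_doses):
        # the bound zeroes doses only; baseline xerostomia stays in both terms
        doses = dict(zero_doses, parotid_contralateral_mean=30.0)
        model = models_by_name["xerostomia"]
        for level in ("none", "minor", "moderate_severe"):
            clinical = {"xer_baseline": level}
            got = delta_ntcp_max(doses, clinical, model)
            shift = {"none": 0.0, "minor": 0.525, "moderate_severe": 1.482}[level]
            expected = 100 * (
                expit_ref(-1.507 + 0.052 * 30 + shift) - expit_ref(-1.507 + shift)
            )
            assert got == pytest.approx(expected, abs=1e-9)


class TestThresholdRules:
    def test_single_grade2_boundary_inclusive(self):
        ok, rules = qualifies({"a": 10.0, "b": 0.0, "c": 0.0}, {"a": 2, "b": 2, "c": 3})
        assert ok and rules[0].rule == "single" and rules[0].endpoints == ("a",)
        ok, _ = qualifies({"a": 9.999, "b": 0.0, "c": 0.0}, {"a": 2, "b": 2, "c": 3})
        assert not ok

    def test_single_grade3_boundary(self):
        ok, _ = qualifies({"c": 5.0}, {"c": 3})
        assert ok
        ok, _ = qualifies({"c": 4.999}, {"c": 3})
        assert not ok

    def test_summed_grade2_pair(self):
        ok, rules = qualifies({"a": 8.0, "b": 7.5}, {"a": 2, "b": 2})
        assert ok and rules[0].rule == "summed" and rules[0].value_pp == pytest.approx(15.5)
        ok, _ = qualifies({"a": 7.5, "b": 7.5}, {"a": 2, "b": 2})
        assert ok  # exactly 15 is inclusive
        ok, _ = qualifies({"a": 7.5, "b": 7.499}, {"a": 2, "b": 2})
        assert not ok

    def test_pair_just_below_does_not_qualify(self):
        ok, _ = qualifies({"a": 9.9, "b": 4.9, "c": 4.9}, {"a": 2, "b": 2, "c": 3})
        assert not ok  # 9.9<10, 14.8<15, 4.9<5

    def test_no_summation_across_grades(self):
        # 7+7 grade-2 gives 14 < 15; grade-3 endpoint at 4 < 5 cannot join them
        ok, _ = qualifies({"a": 7.0, "b": 7.0, "c": 4.0}, {"a": 2, "b": 2, "c": 3})
        assert not ok

    def test_negative_delta_never_triggers_and_sums_signed(self):
        ok, _ = qualifies({"a": -20.0}, {"a": 2})
        assert not ok
        # signed sum: 16 + (-2) = 14 < 15 even though 16 alone would... (16 >= 10 single)
        ok, rules = qualifies({"a": 16.0, "b": -2.0}, {"a": 2, "b": 2})
        assert ok and all(r.rule == "single" for r in rules)

    def test_all_zero_not_qualified(self):
        ok, _ = qualifies({"a": 0.0, "b": 0.0, "c": 0.0}, {"a": 2, "b": 2, "c": 3})
        assert not ok


def _brute_force_rules(deltas, grades, policy):
    """Independent enumerator of every single and same-grade-pair rule."""
    fired = []
    for name, d in deltas.items():
        t = policy.single.get(grades[name])
        if t is not None and d >= t:
            fired.append(("single", (name,)))
    for a, b in itertools.combinations(sorted(deltas), 2):
        if grades[a] == grades[b]:
            t = policy.summed.get(grades[a])
            if t is not None and deltas[a] + deltas[b] >= t:
                fired.append(("summed", (a, b)))
    return sorted(fired)


def test_rule_engine_matches_brute_force_enumerator():
    rng = np.random.default_rng(42)
    endpoints = ["e1", "e2", "e3", "e4"]
    for _ in range(2000):
        k = rng.integers(1, 5)
        names = endpoints[:k]
        deltas = {n: float(rng.uniform(-10, 20)) for n in names}
        grades = {n: int(rng.choice([2, 3, 4])) for n in names}
        got = sorted((r.rule, r.endpoints) for r in triggered_rules(deltas, grades))
        assert got == _brute_force_rules(deltas, grades, DEFAULT_POLICY)


@settings(max_examples=300, deadline=None)
@given(
    deltas=st.lists(st.floats(-30, 40), min_size=1, max_size=4),
    grades=st.lists(st.sampled_from([2, 3, 4]), min_size=4, max_size=4),
    scale=st.floats(1.0, 3.0),
)
def test_raising_thresholds_never_adds_qualifiers(deltas, grades, scale):
    named = {f"e{i}": d for i, d in enumerate(deltas)}
    g = {f"e{i}": grades[i] for i in range(len(deltas))}
    stricter = ThresholdPolicy(
        single={k: v * scale for k, v in DEFAULT_POLICY.single.items()},
        summed={k: v * scale for k, v in DEFAULT_POLICY.summed.items()},
    )
    before, _ = qualifies(named, g, DEFAULT_POLICY)
    after, _ = qualifies(named, g, stricter)
    assert not (after and not before)


class TestSelectPatient:
    def test_gate_failure_short_circuits(self):
        decision = select_patient(EligibilityGate("other"))
        assert decision.gate_passed is False
        assert decision.qualifies is False
        assert decision.ntcp_photon == {}

    def test_screen_false_blocks_qualification(self, zero_doses, reference_clinical):
        # zero photon doses: ΔNTCP_max = 0 everywhere, below every threshold
        decision = select_patient(
            EligibilityGate("larynx"),
            photon_doses=zero_doses,
            proton_doses=zero_doses,
            clinical=reference_clinical,
        )
        assert decision.gate_passed
        assert not decision.plan_comparison_indicated
        assert not decision.qualifies

    def test_worked_pair_matches_spreadsheet_oracle(self, models, reference_clinical):
        photon = {
            "parotid_contralateral_mean": 35.0,
            "oral_cavity_mean": 45.0,
            "pcm_superior_mean": 55.0,
            "pcm_inferior_mean": 30.0,
            "cricopharyngeal_mean": 25.0,
        }
        proton = {
            "parotid_contralateral_mean": 20.0,
            "oral_cavity_mean": 25.0,
            "pcm_superior_mean": 35.0,
            "pcm_inferior_mean": 20.0,
            "cricopharyngeal_mean": 15.0,
        }
        clinical = dict(reference_clinical, treatment="chemoradiation")
        decision = select_patient(
            EligibilityGate("pharynx"),
            photon_doses=photon,
            proton_doses=proton,
            clinical=clinical,
        )
        # independent spreadsheet-style arithmetic
        lp_xer_ph = -1.507 + 0.052 * 35
        lp_xer_pr = -1.507 + 0.052 * 20
        lp_dys_ph = -3.303 + 0.024 * 45 + 0.024 * 55
        lp_dys_pr = -3.303 + 0.024 * 25 + 0.024 * 35
        lp_tf_ph = -6.849 + 1.101 + 0.030 * 55 + 0.013 * 30 + 0.022 * 35 + 0.008 * 25
        lp_tf_pr = -6.849 + 1.101 + 0.030 * 35 + 0.013 * 20 + 0.022 * 20 + 0.008 * 15
        exp_delta = {
            "xerostomia": 100 * (expit_ref(lp_xer_ph) - expit_ref(lp_xer_pr)),
            "dysphagia": 100 * (expit_ref(lp_dys_ph) - expit_ref(lp_dys_pr)),
            "tube_feeding": 100 * (expit_ref(lp_tf_ph) - expit_ref(lp_tf_pr)),
        }
        assert decision.plan_comparison_indicated
        assert decision.delta_pp == pytest.approx(exp_delta, abs=1e-9)
        # rule check by hand: xerostomia Δ ≈ 18.9 pp ≥ 10 → qualifies
        single_fired = {n for n, d in exp_delta.items() if d >= DEFAULT_POLICY.single[GRADES_DEFAULT[n]]}
        assert decision.qualifies == bool(single_fired or
            exp_delta["xerostomia"] + exp_delta["dysphagia"] >= 15.0)
        assert decision.qualifies

    def test_photon_plan_compared_with_itself(self, reference_clinical):
        photon = {oar: 40.0 for oar in DOSE_COLUMNS}
        decision = select_patient(
            EligibilityGate("pharynx"),
            photon_doses=photon,
            proton_doses=photon,
            clinical=dict(reference_clinical, xer_baseline="minor"),
        )
        assert decision.plan_comparison_indicated  # 40 Gy everywhere is screen-worthy
        assert decision.delta_pp == pytest.approx({k: 0.0 for k in decision.delta_pp})
        assert not decision.qualifies

    def test_implication_chain_enforced(self):
        with pytest.raises(ValueError):
            SelectionDecision(gate_passed=False, plan_comparison_indicated=True)
        with pytest.raises(ValueError):
            SelectionDecision(gate_passed=True, plan_comparison_indicated=False, qualifies=True)


def _random_pair(rng):
    photon = {oar: float(rng.uniform(0, 70)) for oar in DOSE_COLUMNS}
    proton = {oar: photon[oar] * float(rng.uniform(0, 1)) for oar in DOSE_COLUMNS}
    clinical = {
        "xer_baseline": str(rng.choice(["none", "minor", "moderate_severe"])),
        "dysphagia_baseline_ge2": bool(rng.integers(2)),
        "advanced_t_stage": bool(rng.integers(2)),
        "weight_loss": str(rng.choice(["none", "moderate_1_10pct", "severe_gt10pct"])),
        "treatment": str(
            rng.choice(
                ["conventional_rt_alone", "accelerated_rt", "chemoradiation", "rt_plus_cetuximab"]
            )
        ),
    }
    return photon, proton, clinical


def test_delta_ntcp_max_dominates_any_proton_plan(models):
    rng = np.random.default_rng(3)
    for _ in range(500):
        photon, proton, clinical = _random_pair(rng)
        for model in models:
            d = delta_ntcp(photon, proton, clinical, model)
            dmax = delta_ntcp_max(photon, clinical, model)
            assert d <= dmax + 1e-9


class TestScreenCohort:
    def _cohort_frames(self, n, seed=0, reduction=0.5, spread=0.15):
        from ntcp_select.simulate import SimulationConfig, generate_cohort

        cohort = generate_cohort(
            SimulationConfig(
                n=n, seed=seed,
                proton_reduction_mean=reduction, proton_reduction_sd=spread,
            )
        )
        return cohort.patients, cohort.photon_plans, cohort.proton_plans

    def test_empty_cohort(self):
        patients, photon, proton = self._cohort_frames(1)
        decisions, summary = screen_cohort(patients.iloc[:0], photon.iloc[:0], proton.iloc[:0])
        assert decisions == []
        assert summary["screened"] == 0 and summary["qualified"] == 0

    def test_identical_proton_plans_qualify_nobody(self):
        patients, photon, _ = self._cohort_frames(60, seed=5)
        decisions, summary = screen_cohort(patients, photon, photon.copy())
        assert summary["qualified"] == 0

    def test_zero_dose_protons_qualify_all_screened(self):
        # reduction 0: ΔNTCP equals ΔNTCP_max, so qualification = pre-screen
        patients, photon, proton = self._cohort_frames(80, seed=6, reduction=0.0, spread=0.0)
        assert (proton[list(DOSE_COLUMNS)].to_numpy() == 0).all()
        _, summary = screen_cohort(patients, photon, proton)
        assert summary["qualified"] == summary["plan_comparison_indicated"]

    def test_decision_implication_chain_on_cohort(self):
        patients, photon, proton = self._cohort_frames(150, seed=7)
        decisions, _ = screen_cohort(patients, photon, proton)
        for d in decisions:
            assert (not d.qualifies) or d.plan_comparison_indicated
            assert (not d.plan_comparison_indicated) or d.gate_passed

    def test_strict_mode_raises_on_missing_plan(self):
        patients, photon, proton = self._cohort_frames(5)
        with pytest.raises(KeyError):
            screen_cohort(patients, photon.iloc[:2], proton)
        _, summary = screen_cohort(patients, photon.iloc[:2], proton, strict=False)
        assert len(summary["errors"]) > 0
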