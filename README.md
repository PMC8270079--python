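# ntcp-select

Model-based selection of head-and-neck cancer patients for proton therapy.

In the Netherlands, patients with pharyngeal, laryngeal or oral-cavity tumours
qualify for proton therapy when the *predicted* reduction in late
radiation-induced toxicity — comparing their best photon plan with a proton
plan — exceeds nationally agreed thresholds. The prediction uses normal
tissue complication probability (NTCP) models: logistic regressions on
organ-at-risk mean doses and clinical factors,

```
NTCP = 1 / (1 + exp(-LP)),    LP = β₀ + Σⱼ βⱼ · D_mean,j + Σₖ γₖ · 1[levelₖ]
```

for three endpoints at 6 months after radiotherapy: moderate-to-severe
xerostomia (CTCAE grade 2), grade II–IV dysphagia (grade 2) and tube feeding
dependence (grade 3). The expected benefit per endpoint is
`ΔNTCP = NTCP_photon − NTCP_proton`; the flowchart first checks the
best-case bound `ΔNTCP_max` (all model doses reduced to 0 Gy by protons),
and a patient qualifies when a single endpoint's ΔNTCP reaches 10/5/2
percentage points (grade ≥II/≥III/≥IV) or two endpoints of the same grade
jointly reach 15/7.5/3 points.

This package provides, for clinical physicists, radiation oncologists and
prediction-model researchers:

- **`ntcp_select.models`** — the three published coefficient sets as
  versioned data (`data/default_models.json`), with scalar and vectorised
  evaluation and strict missing-predictor handling;
- **`ntcp_select.selection`** — the eligibility gate, ΔNTCP_max pre-screen
  and threshold rule engine, per patient or per cohort;
- **`ntcp_select.validation`** — external validation (AUC, calibration
  intercept/slope) and the closed-testing update procedure that chooses
  among keeping a model, updating its intercept, recalibrating, or fully
  revising it on new data;
- **`ntcp_select.simulate`** — synthetic referral cohorts with correlated
  organ doses, clinical covariates, proton plans as dose-reduced photon
  plans, and outcomes drawn from the models, so everything is testable
  without patient data.

## Worked example

```python
from ntcp_select import EligibilityGate, select_patient

photon = {"parotid_contralateral_mean": 35.0, "oral_cavity_mean": 45.0,
          "pcm_superior_mean": 55.0, "pcm_inferior_mean": 30.0,
          "cricopharyngeal_mean": 25.0}
proton = {"parotid_contralateral_mean": 20.0, "oral_cavity_mean": 25.0,
          "pcm_superior_mean": 35.0, "pcm_inferior_mean": 20.0,
          "cricopharyngeal_mean": 15.0}
clinical = {"xer_baseline": "none", "dysphagia_baseline_ge2": False,
            "advanced_t_stage": False, "weight_loss": "none",
            "treatment": "chemoradiation"}

decision = select_patient(EligibilityGate("pharynx"),
                          photon_doses=photon, proton_doses=proton,
                          clinical=clinical)
```

This prints (via the decision object):

```
xerostomia   NTCP_photon=0.578 NTCP_proton=0.385 dmax= 39.6 delta= 19.2
dysphagia    NTCP_photon=0.288 NTCP_proton=0.134 dmax= 25.3 delta= 15.4
tube_feeding NTCP_photon=0.061 NTCP_proton=0.020 dmax=  5.8 delta=  4.0
indicated: True qualifies: True
```

Read: under photons this patient has a 57.8% predicted xerostomia risk and
28.8% dysphagia risk; the proton plan cuts them by 19.2 and 15.4 percentage
points. Both grade-2 endpoints individually clear the 10-point single
threshold (and jointly the 15-point summed threshold), so the patient
qualifies for proton therapy; `decision.triggered_rules` lists all three
fired rules.

The same machinery runs from the shell over CSV cohorts:

```
ntcp-select simulate --n 200 --seed 7 --out-dir cohort/
ntcp-select select --patients cohort/patients.csv \
    --photon-plans cohort/photon_plans.csv \
    --proton-plans cohort/proton_plans.csv \
    --out decisions.csv --summary summary.json
```

`ntcp-select --version` prints the hash of the active coefficient set so a
clinical decision is auditable against the exact model version used.

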