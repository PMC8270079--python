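[
  {
    "name": "xerostomia",
    "endpoint": "patient-rated moderate-to-severe xerostomia at 6 months",
    "grade": 2,
    "intercept": -1.507,
    "dose_coefficients": {
      "parotid_contralateral_mean": 0.052
    },
    "clinical_coefficients": {
      "xer_baseline=minor": 0.525,
      "xer_baseline=moderate_severe": 1.482
    }
  },
  {
    "name": "dysphagia",
    "endpoint": "physician-rated grade II-IV dysphagia at 6 months",
    "grade": 2,
    "intercept": -3.303,
    "dose_coefficients": {
      "oral_cavity_mean": 0.024,
      "pcm_superior_mean": 0.024
    },
    "clinical_coefficients": {
      "dysphagia_baseline_ge2": 0.967
    }
  },
  {
    "name": "tube_feeding",
    "endpoint": "tube feeding dependence at 6 months",
    "grade": 3,
    "intercept": -6.849,
    "dose_coefficients": {
      "pcm_superior_mean": 0.03,
      "pcm_inferior_mean": 0.013,
      "parotid_contralateral_mean": 0.022,
      "cricopharyngeal_mean": 0.008
    },
    "clinical_coefficients": {
      "advanced_t_stage": 0.68,
      "weight_loss=moderate_1_10pct": 0.317,
      "weight_loss=severe_gt10pct": 1.178,
      "treatment=accelerated_rt": 0.198,
      "treatment=chemoradiation": 1.101,
      "treatment=rt_plus_cetuximab": 1.716
    }
  }
]
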