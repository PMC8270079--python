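import math

import pytest

from ntcp_select import DOSE_COLUMNS, default_models


def expit_ref(lp: float) -> float:
    """Independent logistic reference used as the arithmetic oracle in tests."""
    return 1.0 / (1.0 + math.exp(-lp))


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def models_by_name(models):
    return {m.name: m for m in models}


@pytest.fixture
def zero_doses():
    return {oar: 0.0 for oar in DOSE_COLUMNS}


@pytest.fixture
def reference_clinical():
    """All clinical factors at their reference level."""
    return {
        "xer_baseline": "none",
        "dysphagia_baseline_ge2": False,
        "advanced_t_stage": False,
        "weight_loss": "none",
        "treatment": "conventional_rt_alone",
    }
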