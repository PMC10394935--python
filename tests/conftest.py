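import pytest

from ltxcdss import ConfusionMatrix, builtin_referral_pack

# Per-user PSSUQ subscale scores as printed in the published usability table
PSSUQ_PRINTED = {
    "system_usefulness": [7, 5.83, 5.33, 6.67, 5.5, 6.67],
    "information_quality": [7, 6, 5.5, 7, 5.33, 7],
    "interface_quality": [7, 6, 5.25, 6.5, 5.5, 7],
    "overall": [7, 6, 4.83, 6.5, 6.25, 6.67],
}

# COPD worked example: every referral criterion satisfied, NYHA III symptoms
COPD_FACTS = {
    "age": 50,
    "esld": True,
    "survival_lt_50pct": True,
    "advanced_despite_treatment": True,
    "diagnosis_confirmed": True,
    "disease_permitted": True,
    "fev1_pct": 45.0,
    "dyspnea_history": True,
    "recurrent_hospitalization": True,
    "nyha_symptoms": "daily-activity-only",
}


@pytest.fixture(scope="session")
def referral_pack():
    return builtin_referral_pack()


@pytest.fixture
def copd_facts():
    return dict(COPD_FACTS)


@pytest.fixture(scope="session")
def published_cm():
    """The 59-patient evaluation confusion matrix: TP=28, FN=9, FP=0, TN=22."""
    return ConfusionMatrix(tp=28, fn=9, fp=0, tn=22)
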