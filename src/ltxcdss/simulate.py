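"""Synthetic study data: referral cohorts with gold eligibility labels,
expert content-validity surveys, and Likert matrices with tunable
reliability.

The cohort generator emulates a 59-patient referral clinic population: the
default status and blood-group composition matches the published cohort
(waiting list 74.6%, O+ 32.2%, ...), eligibility prevalence defaults to the
observed 37/59, and a configurable fraction of eligibility-relevant facts
can be blanked to unknown *after* labelling, so gold labels stay
well-defined and the inference engine is graded on abstention rather than
forced guesses.

The gold-label oracle is a deliberate second implementation: straight-line
evaluation of the COPD referral conjunction with no condition trees and no
engine involvement, so engine-versus-oracle agreement is a genuine
two-implementation test.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .patient import BloodGroup, PatientRecord, PatientStatus, parse_blood_group
from .survey import SurveyMatrix

__all__ = [
    "TABLE5_STATUS_MIX",
    "TABLE5_BLOOD_MIX",
    "CohortSpec",
    "referral_oracle",
    "generate_cohort",
    "generate_survey",
    "expected_retention",
    "generate_likert",
]

# Published 59-patient cohort composition (counts / 59).
TABLE5_STATUS_MIX: dict[str, float] = {
    "referred": 3 / 59,
    "preassessment": 3 / 59,
    "referred_to_committee": 2 / 59,
    "waiting_list": 44 / 59,
    "transplanted": 7 / 59,
}
TABLE5_BLOOD_MIX: dict[str, float] = {
    "O+": 19 / 59, "O-": 5 / 59, "A+": 5 / 59, "A-": 2 / 59,
    "B+": 10 / 59, "B-": 3 / 59, "AB+": 10 / 59, "AB-": 5 / 59,
}

#: Facts the eligibility label depends on; missingness is injected here.
ELIGIBILITY_FACTS = ("fev1_pct", "dyspnea_history", "recurrent_hospitalization", "nyha_symptoms")

_NYHA_34_SYMPTOMS = ("daily-activity-only", "at-rest")
_NYHA_12_SYMPTOMS = ("none", "normal-activity")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic referral cohort."""

    n: int = 59
    seed: int = 0
    status_mix: Mapping[str, float] = field(default_factory=lambda: dict(TABLE5_STATUS_MIX))
    blood_mix: Mapping[str, float] = field(default_factory=lambda: dict(TABLE5_BLOOD_MIX))
    prevalence: float = 37 / 59  # eligible fraction, as observed
    missing_rate: float = 0.0
    disease_mix: Mapping[str, float] = field(default_factory=lambda: {"COPD": 1.0})
    fev1_threshold: float = 35.0

    def __post_init__(self):
        for name, mix in (("status_mix", self.status_mix), ("blood_mix", self.blood_mix),
                          ("disease_mix", self.disease_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} must be a proper probability vector (sums to {total})")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")


def referral_oracle(facts: Mapping, fev1_threshold: float = 35.0) -> bool | None:
    """Straight-line gold-label oracle for the COPD referral conjunction.

    Returns True/False, or None when a needed fact is absent.  Kept free of
    the Condition/engine machinery on purpose.
    """
    fev1 = facts.get("fev1_pct")
    dysp = facts.get("dyspnea_history")
    hosp = facts.get("recurrent_hospitalization")
    symptoms = facts.get("nyha_symptoms")
    if fev1 is None or dysp is None or hosp is None or symptoms is None:
        return None
    nyha_3_or_4 = symptoms in _NYHA_34_SYMPTOMS
    return bool(fev1 > fev1_threshold) and bool(dysp) and bool(hosp) and nyha_3_or_4


def _sample_mix(rng: np.random.Generator, mix: Mapping[str, float], size: int) -> list[str]:
    keys = list(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return [keys[i] for i in idx]


def generate_cohort(spec: CohortSpec) -> tuple[list[PatientRecord], dict[str, bool]]:
    """Generate a cohort and its gold eligibility labels.

    Deterministic given ``spec.seed``.  Labels are computed from the complete
    fact set by :func:`referral_oracle`; only afterwards is a fraction
    ``missing_rate`` of the eligibility-relevant facts blanked to unknown.
    """
    rng = np.random.default_rng(spec.seed)
    statuses = _sample_mix(rng, dict(spec.status_mix), spec.n)
    bloods = _sample_mix(rng, dict(spec.blood_mix), spec.n)
    diseases = _sample_mix(rng, dict(spec.disease_mix), spec.n)
    eligible_draw = rng.random(spec.n) < spec.prevalence

    records: list[PatientRecord] = []
    gold: dict[str, bool] = {}
    thr = spec.fev1_threshold
    for i in range(spec.n):
        pid = f"P{i + 1:05d}"
        eligible = bool(eligible_draw[i])
        facts: dict = {
            "esld": bool(rng.random() < 0.9),
            "survival_lt_50pct": bool(rng.random() < 0.8),
            "advanced_despite_treatment": bool(rng.random() < 0.85),
            "diagnosis_confirmed": True,
            "disease_permitted": True,
            "waiting_days": int(rng.integers(0, 1500)),
        }
        if eligible:
            facts["fev1_pct"] = float(np.round(rng.uniform(thr + 1.0, 80.0), 1))
            facts["dyspnea_history"] = True
            facts["recurrent_hospitalization"] = True
            facts["nyha_symptoms"] = str(rng.choice(_NYHA_34_SYMPTOMS))
        else:
            # break a random non-empty subset of the four criteria
            broken = rng.random(4) < 0.5
            if not broken.any():
                broken[rng.integers(0, 4)] = True
            facts["fev1_pct"] = float(np.round(
                rng.uniform(10.0, thr - 1.0) if broken[0] else rng.uniform(thr + 1.0, 80.0), 1))
            facts["dyspnea_history"] = not broken[1]
            facts["recurrent_hospitalization"] = not broken[2]
            facts["nyha_symptoms"] = str(rng.choice(_NYHA_12_SYMPTOMS if broken[3] else _NYHA_34_SYMPTOMS))

        label = referral_oracle(facts, thr)
        assert label is not None
        gold[pid] = label

        if spec.missing_rate > 0:
            for name in ELIGIBILITY_FACTS:
                if rng.random() < spec.missing_rate:
                    del facts[name]

        records.append(PatientRecord(
            patient_id=pid,
            age=float(rng.integers(16, 76)),
            sex="female" if rng.random() < 31 / 59 else "male",
            diagnosis=diseases[i],
            blood_group=parse_blood_group(bloods[i]),
            status=PatientStatus(statuses[i]),
            facts=facts,
        ))
    return records, gold


def generate_survey(
    n_experts: int,
    essential_probs: Sequence[float],
    seed: int = 0,
    item_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Expert response table: rows = experts, columns = items, cells 1/0.

    Each expert independently rates item *j* essential with probability
    ``essential_probs[j]``, so per-item essential counts are
    Binomial(n_experts, p_j).  Deterministic given the seed.
    """
    probs = np.asarray(essential_probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("essential probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    grid = (rng.random((n_experts, probs.size)) < probs[None, :]).astype(int)
    if item_labels is None:
        item_labels = [f"item_{j + 1:02d}" for j in range(probs.size)]
    return pd.DataFrame(grid, columns=list(item_labels),
                        index=[f"expert_{i + 1}" for i in range(n_experts)])


def expected_retention(
    essential_probs: Sequence[float], n_experts: int, critical_cvr: float
) -> tuple[float, float]:
    """Expected retained-item count and its SD under binomial sampling.

    An item passes when its CVR reaches the critical value, i.e. when
    n_e >= N(critical + 1)/2; the pass probability is the binomial upper
    tail at that count.
    """
    need = int(np.ceil(n_experts * (critical_cvr + 1.0) / 2.0))
    probs = np.asarray(essential_probs, dtype=float)
    pass_p = binom.sf(need - 1, n_experts, probs)
    return float(pass_p.sum()), float(np.sqrt((pass_p * (1 - pass_p)).sum()))


def generate_likert(
    n_resp: int,
    n_items: int,
    target_alpha: float,
    scale: tuple[float, float] = (1, 7),
    seed: int = 0,
) -> SurveyMatrix:
    """Likert matrix from a one-factor model with reliability near a target.

    Item scores are ``loading * latent + noise`` with a common loading
    solved from the Spearman-Brown relation: for k parallel items with
    inter-item correlation r, alpha = k r / (1 + (k-1) r), so
    r = alpha / (k - (k-1) alpha) and loading = sqrt(r / (1-r)) at unit
    noise variance.  Continuous scores are rescaled to the scale midpoint
    with spread (max-min)/4, clipped, and rounded to integer steps —
    discretisation attenuates the realised alpha slightly below target.
    """
    if not 0.0 <= target_alpha < 1.0:
        raise ValueError(f"target alpha must be in [0, 1), got {target_alpha}")
    if n_items < 2 or n_resp < 2:
        raise ValueError("need at least 2 items and 2 respondents")
    r = target_alpha / (n_items - (n_items - 1) * target_alpha)
    if r >= 0.995:
        raise ValueError(
            f"target alpha {target_alpha} is infeasible at {n_items} items "
            "(required inter-item correlation ~1)"
        )
    loading = float(np.sqrt(r / (1.0 - r)))
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n_resp)
    noise = rng.standard_normal((n_resp, n_items))
    x = loading * latent[:, None] + noise
    x /= np.sqrt(loading**2 + 1.0)
    lo, hi = float(scale[0]), float(scale[1])
    mid, spread = (lo + hi) / 2.0, (hi - lo) / 4.0
    scores = np.clip(np.rint(mid + spread * x), lo, hi)
    frame = pd.DataFrame(scores, columns=[f"item_{j + 1:02d}" for j in range(n_items)])
    return SurveyMatrix(frame, scale_min=lo, scale_max=hi)
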