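# ltxcdss

A desk-scale, fully testable rule engine for **lung-transplant (LTx)
candidate management**, modelled on the clinical decision support systems
used at transplant referral centres. Candidate eligibility knowledge is kept
as *data* — declarative IF–THEN–ELSE rules in YAML/JSON "knowledge packs" —
and a forward-chaining inference engine evaluates a patient's facts against
the pack, producing derived facts, recommendations, alerts, requests for
missing data, and a complete explanation trace for every conclusion.

It is aimed at health-informatics researchers and developers who want to
prototype, audit, or evaluate eligibility rule sets without a hospital
deployment: the whole pipeline — from referral screening through committee
review, waiting-list management, and ABO/Rh donor matching — runs from the
command line or three lines of Python, and the package ships the evaluation
mathematics used to assess such systems (exact binomial confidence
intervals, Lawshe's content-validity ratio, Cronbach's α, PSSUQ usability
scoring).

## The model

**Rules.** A rule is `IF condition THEN actions [ELSE actions]`, where the
condition is a tree of `all`/`any`/`not` nodes over atoms `fact ⟨op⟩ value`.
Conditions are evaluated in strong Kleene three-valued logic: a fact absent
from the record is *unknown*, and unknown propagates
(`U ∧ F = F`, `U ∧ T = U`, `U ∨ T = T`, `¬U = U`). A rule with a true
antecedent fires its THEN actions, a definitely false one its ELSE actions,
and an unknown one is deferred — its blocking facts become data requests
("order this test"), never silent rejections.

**Inference.** Forward chaining to fixpoint with a single-firing policy:
each pass evaluates all unresolved rules in priority order (priority
defaults to the rule's decision level; ties by file order); iteration stops
when a pass resolves nothing. Facts only accrue — a conflicting
re-assertion raises an error naming both sources — so Kleene monotonicity
guarantees termination in at most `#rules + 1` passes and makes the result
independent of rule order.

**Bundled knowledge.** The `imamltx-referral` pack encodes a published
referral rule set across four decision levels: general criteria (age band
14–65; end-stage lung disease with < 50% survival probability and
progression despite optimal treatment), the four mutually exclusive NYHA
functional-class rules, diagnosis confirmation, and the COPD-specific
criterion

```
FEV1-flag ∧ dyspnea history ∧ recurrent hospitalization ∧ NYHA ∈ {III, IV}
    ⟹  patient has the criteria of referral
```

**Workflow.** A six-point decision model over five statuses
(referred → preassessment → referred-to-committee → waiting-list →
transplanted), with a follow-up self-loop on the waiting list, audit-logged
transitions, and cohort frequency reports. Donor-day selection filters the
waiting list by the standard ABO matrix (O→all, A→{A,AB}, B→{B,AB},
AB→{AB}) with optional Rh enforcement.

**Evaluation mathematics.** For x successes in n trials the exact
(Clopper–Pearson) 95% interval is `Beta⁻¹(.025; x, n−x+1)` to
`Beta⁻¹(.975; x+1, n−x)`; CVR = (nₑ − N/2)/(N/2);
α = k/(k−1)·(1 − Σsᵢ²/s_T²).

## Worked example

```python
from ltxcdss import builtin_referral_pack, infer, explain

pack = builtin_referral_pack()
facts = {
    "age": 50, "esld": True, "survival_lt_50pct": True,
    "advanced_despite_treatment": True, "diagnosis_confirmed": True,
    "disease_permitted": True, "fev1_pct": 45.0, "dyspnea_history": True,
    "recurrent_hospitalization": True, "nyha_symptoms": "daily-activity-only",
}
result = infer(facts, pack)
print(result.final_conclusions)
print(explain(result, "referral_criteria_met").render())
```

prints

```
['referral_criteria_met']
referral_criteria_met = True  [rule referral.copd.criteria]
  fev1_flag = True  [rule referral.copd.fev1]
    fev1_pct = 45.0  [input]
  dyspnea_history = True  [input]
  recurrent_hospitalization = True  [input]
  nyha_class_3_or_4 = True  [rule referral.copd.nyha_flag]
    nyha_class = 'III'  [rule referral.nyha.class3]
      nyha_symptoms = 'daily-activity-only'  [input]
```

— the NYHA class III is *derived* from the symptom description ("symptoms
during daily activity, asymptomatic at rest"), feeds the class-III/IV flag,
and together with the other three criteria completes the referral
conclusion; every leaf of the tree is an input fact.

On the evaluation side, a predictions file reproducing a 59-patient test
(TP=28, FN=9, FP=0, TN=22) gives

```
$ ltxcdss evaluate --predictions preds.csv
confusion matrix: TP=28 FN=9 FP=0 TN=22 (n=59)
accuracy: 84.75% (73.01-92.78%; 95% CI)
sensitivity: 75.68% (58.80-88.23%; 95% CI)
specificity: 100.00% (84.56-100.00%; 95% CI)
```

i.e. the system's call agreed with the physician reference in 50/59 cases,
and it never called an ineligible patient eligible (specificity 1.0, exact
lower bound 0.8456 = 0.025^(1/22)).

Other subcommands: `assess`, `advance`, `match-donor`, `report`,
`validate-kb`, `survey {cvr,alpha,pssuq}`, `simulate {cohort,survey,likert}`.

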