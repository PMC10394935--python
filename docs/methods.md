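# Methods

## Scope and design stance

The package treats clinical eligibility knowledge as a declarative artifact:
rules are YAML/JSON data validated against a small schema, and the engine is
a generic forward-chaining interpreter. This replaces ontology tooling
(OWL/SWRL) that production systems of this kind sometimes use; a
self-contained pack format keeps the artifact dependency-light, diffable,
and unit-testable, at the cost of ontology interoperability, which is out of
scope here.

## Three-valued semantics

A fact not present in a record is *unknown* — never false. Conditions are
evaluated in strong Kleene logic, the standard choice when absence of
evidence must not become evidence of absence: `unknown AND false = false`,
`unknown AND true = unknown`, `unknown OR true = true`, `NOT unknown =
unknown`. Clinically this means a patient with one definitively failed
criterion is definitively ineligible even if other facts are missing, while
a patient who fails nothing but lacks data gets a *data request*, not a
rejection. Kleene logic is monotone in the information order: filling in an
unknown can never flip an already-definite answer. That property carries the
engine's two guarantees: (1) evaluating a definite antecedent early is
sound, and (2) with missing data the engine can abstain but can never make
a definite call that contradicts the full-information answer.

Ordering comparators (`lt`/`le`/`gt`/`ge`) on a present but non-numeric
value raise a `TypeError`: a wrongly typed present value is a data error,
not missing data, and silently coercing it would hide it.

## Engine policy

The inference engine is deliberately simple and loud:

- **Single firing.** Each rule resolves at most once (then- or else-branch).
  With accruing facts this bounds passes by `#rules + 1` and rules out
  non-termination by construction.
- **Priority.** Default priority equals the rule's decision level, ties by
  file order. Because facts never change once set, permuting rules never
  changes the derived facts, only the trace order; priority exists for trace
  readability, not correctness.
- **Conflicts are hard errors.** Two rules asserting different values for
  one fact, or a rule contradicting an input fact, raise an error naming
  both sources. In a clinical setting an arbitrary tie-break would be a
  silent wrong answer.
- **Else-branches run only on definite falsity**, never on unknown.
- **Conclusions** are pack-declared fact names (`conclusions:` list); the
  result reports those derived true. The explanation tree for a conclusion
  expands each derived fact through the rule that asserted it, down to
  input-fact leaves.

## The bundled referral pack

The pack encodes the printed referral rule set of a lung-transplant centre.
Two printed rules needed interpretation, both kept configurable:

- The **age rule** is printed as `age >= 65 AND age >= 14`, which cannot
  describe an eligibility band. It is implemented as `14 <= age <= 65`, the
  only clinically coherent reading, with both thresholds exposed as
  parameters of `builtin_referral_pack`.
- The **FEV1 rule** is printed as `FEV1 > 35%`, opposite in direction to
  common COPD referral practice (severe obstruction, i.e. *low* FEV1,
  motivates referral). It is encoded exactly as printed; the comparator and
  threshold are pack parameters, because the engine must be agnostic about
  the knowledge it executes — the pack is data.

The final COPD conclusion is the printed four-way conjunction (FEV1 flag,
dyspnea history, recurrent hospitalization, NYHA III/IV). Level 1–3 rules
(age band, ESLD criteria, NYHA class assignment, diagnosis confirmation)
derive their intermediate facts and emit alerts, but are not added as extra
conjuncts to the conclusion, since the printed rule does not include them.

Rule categories beyond referral (initial assessment, committee, waiting-list
placement, donor-day confirmation) ship with minimal single-rule defaults so
the six-point workflow is executable end-to-end; these are package defaults,
not published knowledge. The follow-up category is an intentionally empty
extension point (its conclusion fact is `follow_up_ok` once rules are
added); with no rules, the follow-up stage passes vacuously as a self-loop.

## Workflow

Six decision points over five statuses. Committee review (point 3) records
approval without moving the patient; waiting-list placement (point 4)
executes the shared `referred_to_committee → waiting_list` edge. The
transition graph is validated to be a forward DAG apart from the follow-up
self-loop, with `transplanted` terminal. A stage outcome is `passed` /
`failed` / `needs_data`; only `passed` can change status, every status
change must be a configured edge, and each change appends an audit entry
carrying the fired-rule trace. Point names and the stage→category binding
are configuration, since this mapping differs between centres.

## Donor matching

Standard ABO matrix; Rh handling and exact-vs-compatible matching are a
policy object because practice varies. The default is the conservative
`identical_only` + Rh-strict. Ranking: identical group before merely
compatible, then longer waiting time (optional numeric fact
`waiting_days`), then patient id. No HLA, size, or allocation-score
modelling.

## Evaluation statistics

All reported metrics are binomial proportions; intervals are Clopper–Pearson
exact (beta quantiles), chosen because exact intervals reproduce the
published bounds of the reference evaluation to the printed precision and
are conservative (coverage ≥ nominal), which suits small clinical samples
(n = 59). Closed forms at the boundary: lower bound `(α/2)^(1/n)` at x = n,
upper `1 − (α/2)^(1/n)` at x = 0. Degenerate denominators (no actual
positives for sensitivity, etc.) raise an explicit undefined-metric error.
Percentages print at 2 d.p., proportions at 4 d.p.

## Survey psychometrics

- **CVR** = (nₑ − N/2)/(N/2). The critical-value table (panel size →
  minimum CVR) is editable CSV config, not code; the bundled values are the
  conventional one-tailed 5% table, interpolated downward to the
  next-smaller tabulated panel size.
- **Retention** combines the CVR bar with an optional mean-score rule that
  has *two* thresholds (keep ≥ 3.6, drop < 3.5 by default). Protocols that
  state thresholds this way leave a [3.5, 3.6) gap; items falling in it are
  flagged *borderline* rather than silently classified, because guessing the
  protocol's intent would be invisible data-dependent behaviour.
- **Cronbach's α** uses the variance decomposition with sample (ddof = 1)
  variances and listwise deletion of incomplete respondents; zero
  total-score variance is an explicit degenerate-input error. The
  implementation is cross-checked against an independent library in the
  test suite.
- **PSSUQ** defaults to the 16-item Version-3 subscale layout (items 1–6
  usefulness, 7–12 information quality, 13–15 interface quality, 1–16
  overall), fully overridable, since deployed questionnaires vary. Pooled
  SD is the sample SD across respondents and is reported as absent for a
  single respondent.

## Synthetic data: what it emulates and what it does not

`generate_cohort` emulates a referral-clinic cohort: status and blood-group
mixes default to a published 59-patient composition (waiting list 74.6%,
O+ 32.2%, …), eligibility prevalence defaults to the observed 37/59, and
the four eligibility-relevant facts (FEV1 percent, dyspnea history,
recurrent hospitalization, NYHA symptom state) are sampled to satisfy or
break the referral conjunction. Ineligible patients break a uniformly
chosen non-empty subset of the four criteria. Missingness is injected
*after* gold labelling, so labels stay well-defined and the engine is graded
on abstention, not forced guesses.

The gold-label oracle is a second, deliberately independent implementation:
straight-line evaluation of the referral conjunction with no condition trees
and no engine code, making engine-versus-oracle agreement a genuine
two-implementation test rather than a tautology.

What the generator does **not** model: realistic lab value distributions,
spirometry curves, correlated comorbidities, longitudinal follow-up, or
inter-physician disagreement. Passing the agreement tests therefore shows
the engine executes the encoded rules exactly; it says nothing about whether
the rules themselves are clinically complete.

`generate_survey` draws expert×item essential ratings independently as
Bernoulli(p_item); `generate_likert` uses a one-factor model with a common
loading solved from the Spearman–Brown relation
r = α/(k − (k−1)α), loading = √(r/(1−r)), then centres scores at the scale
midpoint with spread (max−min)/4, clips, and rounds to integer steps.
Discretisation attenuates realised α slightly below target (≈ 0.005 at
α = 0.936, k = 16 on a 7-point scale); targets requiring inter-item
correlation ≳ 0.995 are rejected as infeasible. All generators take one
explicit seed and are bit-reproducible; no global random state is touched.

## Problem sizes and numerical choices

The repository's heavier checks run at: 10⁴ patients (four prevalence
levels × 2 500) for engine-versus-oracle agreement plus 2 000 at 10%
missingness; 1 000 random conditions with ≤ 6 atoms enumerated over all
3^k assignments for the Kleene-logic oracle; 10⁴ replicates per (p, n)
cell for interval coverage; 100 replicates of 500×16 matrices for
reliability recovery. These sizes make the binomial error of every
stochastic check several times smaller than its acceptance margin while the
whole suite stays interactive (seconds, one core).

Lint's contradiction check over-approximates satisfiability by treating
distinct atoms as independent, except that eq-atoms on the same fact with
different constants are marked mutually exclusive; pairs with more than 12
distinct atoms are conservatively assumed to overlap. It is a reviewer aid,
not a verifier.

## Known limitations

- Only the printed referral rules ship; the production-scale rule base
  (hundreds of rules) is not public, so the pack format's extensibility is
  the deliverable, not coverage.
- The eight data-item domain names of the minimum data set are not public;
  the schema ships documented placeholders (`domain_1` … `domain_8`).
- The committee/waiting-list stage rules are single-fact plumbing defaults.
- No persistence, scheduling, messaging, or EMR integration.
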