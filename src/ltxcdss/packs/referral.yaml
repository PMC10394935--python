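# Bundled lung-transplant candidate-management pack.
#
# Referral-category rules encode the published referral criteria for the
# four decision levels (general criteria, NYHA classification, diagnosis
# confirmation, COPD-specific criteria).  The FEV1 rule is encoded with the
# published comparator (fev1_pct > 35); see builtin_referral_pack() for the
# configurable threshold parameters.  Rules in the other workflow categories
# are minimal defaults so the six-point workflow is executable end-to-end;
# the follow_up category is an intentionally empty extension point.
name: imamltx-referral
version: "1.0"
facts:
  age: number
  esld: boolean
  survival_lt_50pct: boolean
  advanced_despite_treatment: boolean
  diagnosis_confirmed: boolean
  disease_permitted: boolean
  fev1_pct: number
  fev1_flag: boolean
  dyspnea_history: boolean
  recurrent_hospitalization: boolean
  nyha_symptoms: string
  nyha_class: string
  nyha_class_3_or_4: boolean
  age_criterion: boolean
  esld_confirmed: boolean
  dx_confirmed: boolean
  referral_criteria_met: boolean
  assessment_complete: boolean
  contraindication_found: boolean
  initial_assessment_passed: boolean
  committee_approved: boolean
  waitlist_approved: boolean
  waitlisted: boolean
  donor_confirmed: boolean
  transplant_confirmed: boolean
conclusions:
  - referral_criteria_met
  - initial_assessment_passed
  - waitlist_approved
  - waitlisted
  - transplant_confirmed
metadata:
  disease_coverage: [COPD]
  input_facts:
    - age
    - esld
    - survival_lt_50pct
    - advanced_despite_treatment
    - diagnosis_confirmed
    - disease_permitted
    - fev1_pct
    - fev1_flag
    - dyspnea_history
    - recurrent_hospitalization
    - nyha_symptoms
    - nyha_class
    - assessment_complete
    - contraindication_found
    - committee_approved
    - donor_confirmed
rules:
  # ---- Level 1: general criteria for patient referral -------------------
  - id: referral.age
    level: 1
    category: referral_criteria
    if:
      all:
        - {fact: age, op: ge, value: 14}
        - {fact: age, op: le, value: 65}
    then:
      - assert: {age_criterion: true}
    else:
      - assert: {age_criterion: false}
      - alert: "Patient age is outside the 14-65 eligibility band"
  - id: referral.esld
    level: 1
    category: referral_criteria
    if:
      all:
        - {fact: esld, op: eq, value: true}
        - {fact: survival_lt_50pct, op: eq, value: true}
        - {fact: advanced_despite_treatment, op: eq, value: true}
    then:
      - assert: {esld_confirmed: true}
    else:
      - assert: {esld_confirmed: false}
      - recommend: "End-stage lung disease criteria not (yet) met; reassess disease course"
  # ---- Level 2: NYHA functional classification --------------------------
  - id: referral.nyha.class1
    level: 2
    category: referral_criteria
    if: {fact: nyha_symptoms, op: eq, value: none}
    then:
      - assert: {nyha_class: I}
  - id: referral.nyha.class2
    level: 2
    category: referral_criteria
    if: {fact: nyha_symptoms, op: eq, value: normal-activity}
    then:
      - assert: {nyha_class: II}
  - id: referral.nyha.class3
    level: 2
    category: referral_criteria
    if: {fact: nyha_symptoms, op: eq, value: daily-activity-only}
    then:
      - assert: {nyha_class: III}
  - id: referral.nyha.class4
    level: 2
    category: referral_criteria
    if: {fact: nyha_symptoms, op: eq, value: at-rest}
    then:
      - assert: {nyha_class: IV}
  # ---- Level 3: diagnosis confirmation -----------------------------------
  - id: referral.dx
    level: 3
    category: referral_criteria
    if:
      all:
        - {fact: diagnosis_confirmed, op: eq, value: true}
        - {fact: disease_permitted, op: eq, value: true}
    then:
      - assert: {dx_confirmed: true}
    else:
      - assert: {dx_confirmed: false}
      - alert: "Diagnosis unconfirmed or disease not in the centre's permitted list"
  # ---- Level 4: disease-specific criteria (COPD) -------------------------
  - id: referral.copd.fev1
    level: 4
    category: referral_criteria
    if: {fact: fev1_pct, op: gt, value: 35}
    then:
      - assert: {fev1_flag: true}
    else:
      - assert: {fev1_flag: false}
  - id: referral.copd.nyha_flag
    level: 4
    category: referral_criteria
    if: {fact: nyha_class, op: in, value: [III, IV]}
    then:
      - assert: {nyha_class_3_or_4: true}
    else:
      - assert: {nyha_class_3_or_4: false}
  - id: referral.copd.criteria
    level: 4
    category: referral_criteria
    if:
      all:
        - {fact: fev1_flag, op: eq, value: true}
        - {fact: dyspnea_history, op: eq, value: true}
        - {fact: recurrent_hospitalization, op: eq, value: true}
        - {fact: nyha_class_3_or_4, op: eq, value: true}
    then:
      - assert: {referral_criteria_met: true}
      - recommend: "Patient has the criteria of referral to the lung transplant centre"
    else:
      - assert: {referral_criteria_met: false}
      - alert: "Patient does not meet the COPD referral criteria"
  # ---- Initial assessment (workflow defaults) ----------------------------
  - id: assessment.complete
    level: 1
    category: initial_assessment
    if:
      all:
        - {fact: assessment_complete, op: eq, value: true}
        - {fact: contraindication_found, op: eq, value: false}
    then:
      - assert: {initial_assessment_passed: true}
    else:
      - assert: {initial_assessment_passed: false}
  - id: assessment.contraindication
    level: 1
    category: initial_assessment
    if: {fact: contraindication_found, op: eq, value: true}
    then:
      - alert: "Contraindication found during initial assessment"
  # ---- Committee review and waiting-list placement -----------------------
  - id: committee.approval
    level: 1
    category: committee
    if: {fact: committee_approved, op: eq, value: true}
    then:
      - assert: {waitlist_approved: true}
      - recommend: "Approved by the lung-transplant committee"
    else:
      - assert: {waitlist_approved: false}
      - alert: "Not approved by the lung-transplant committee"
  - id: waitlist.place
    level: 1
    category: waiting_list_placement
    if: {fact: committee_approved, op: eq, value: true}
    then:
      - assert: {waitlisted: true}
      - set_status: waiting_list
  # ---- Donor-day candidate confirmation ----------------------------------
  - id: donor.confirm
    level: 1
    category: donor_selection
    if: {fact: donor_confirmed, op: eq, value: true}
    then:
      - assert: {transplant_confirmed: true}
      - set_status: transplanted
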