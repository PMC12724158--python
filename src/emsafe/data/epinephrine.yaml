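schema_version: "1"
name: epinephrine-ase
version: "1.0"
nodes:
  patient_age:
    kind: input
    value_type: {type: number}
    description: Patient age in years.
    extraction_hint: the patient's age in years
  patient_weight:
    kind: input
    value_type: {type: quantity, unit: kg}
    description: Patient body weight in kilograms.
    extraction_hint: the patient's body weight in kilograms
  administered_dose:
    kind: input
    value_type: {type: quantity, unit: mg}
    description: Dose of one epinephrine administration, in milligrams.
    extraction_hint: an administered epinephrine dose with its unit
  ems_arrival_time:
    kind: input
    value_type: {type: timestamp}
    description: Time the EMS unit arrived on scene.
    extraction_hint: the EMS unit scene-arrival time
  arrest_onset_time:
    kind: input
    value_type: {type: timestamp}
    description: Time cardiac arrest began.
    extraction_hint: the time cardiac arrest began
  first_epi_time:
    kind: input
    value_type: {type: timestamp}
    description: Time of the first epinephrine administration.
    extraction_hint: the time of the first epinephrine dose
  recommended_dose:
    kind: derived
    value_type: {type: quantity, unit: mg}
    description: >-
      Weight-based recommended epinephrine dose for pediatric cardiac arrest,
      0.01 mg per kg of body weight (PALS).
    rule_ref: recommended_dose_v1
    depends_on: [patient_weight]
  dose_ratio:
    kind: derived
    value_type: {type: number}
    description: Administered dose divided by the recommended dose (dimensionless).
    rule_ref: dose_ratio_v1
    depends_on: [administered_dose, recommended_dose]
  delay_from_arrival:
    kind: derived
    value_type: {type: quantity, unit: min}
    description: Minutes elapsed from EMS scene arrival to the first epinephrine dose.
    rule_ref: delay_from_arrival_v1
    depends_on: [first_epi_time, ems_arrival_time]
  delay_from_arrest:
    kind: derived
    value_type: {type: quantity, unit: min}
    description: Minutes elapsed from arrest onset to the first epinephrine dose.
    rule_ref: delay_from_arrest_v1
    depends_on: [first_epi_time, arrest_onset_time]
  overdose_ase:
    kind: output
    value_type: {type: categorical, levels: [none, mild, severe]}
    description: >-
      Epinephrine overdose determination: mild if the administered dose is at
      least 2 times the recommended dose, severe if at least 10 times.
    rule_ref: classify_overdose_v1
    depends_on: [dose_ratio]
  underdose_ase:
    kind: output
    value_type: {type: categorical, levels: [none, mild, severe]}
    description: >-
      Epinephrine underdose determination: mild if the administered dose is at
      most 80% of the recommended dose, severe if at most 50%.
    rule_ref: classify_underdose_v1
    depends_on: [dose_ratio]
  delay_ase:
    kind: output
    value_type: {type: categorical, levels: [none, mild, severe]}
    description: >-
      Delay-in-administration determination: the first epinephrine dose is
      delayed if it follows BOTH EMS arrival and arrest onset by at least
      5 minutes (mild) or 10 minutes (severe).
    rule_ref: classify_delay_v1
    depends_on: [delay_from_arrival, delay_from_arrest]
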