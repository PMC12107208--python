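# Default prompt bank: 10 editorial templates, one per line, each with a
# single {disease} placeholder. Replace freely; downstream stages depend only
# on the bank shape (10 templates x 20 diseases), not the wording.
Generate a complete electronic health record for a patient diagnosed with {disease}, including demographics, presenting complaint, and past medical history.
Write a synthetic EHR entry for a patient with {disease}; include the patient's sex, race, age, and relevant clinical findings.
Produce a detailed admission note for a hospitalized patient suffering from {disease}, with full demographic information and medication list.
Create a realistic outpatient clinic record for a case of {disease}, covering patient demographics, symptoms, and examination findings.
Draft an electronic health record describing a newly diagnosed case of {disease}, including demographic details, laboratory results, and treatment plan.
Generate a discharge summary for a patient treated for {disease}, stating the patient's demographics, hospital course, and follow-up plan.
Write a case record for a patient presenting with {disease}, documenting sex, race, social history, and family history.
Compose a synthetic medical record of a patient managing chronic {disease}, with demographics, comorbidities, and current medications.
Produce an emergency department note for a patient with acute manifestations of {disease}, including demographic information and triage assessment.
Create a longitudinal care record for a patient followed for {disease}, with demographics, progression notes, and specialist referrals.
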