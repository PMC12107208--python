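name,category
COVID-19,epidemics
Bacterial pneumonia,epidemics
Hepatitis B,epidemics
Tuberculosis,epidemics
Hypertension,chronic conditions
Colon cancer,chronic conditions
Rheumatoid arthritis,chronic conditions
Multiple myeloma,chronic conditions
Prostate cancer,chronic conditions
Multiple sclerosis,chronic conditions
Major depressive disorder,mental health disorders
Lupus,rare diseases
Huntington disease,rare diseases
Amyotrophic lateral sclerosis,rare diseases
Takotsubo cardiomyopathy,rare diseases
Tricuspid endocarditis,rare diseases
Sarcoidosis,rare diseases
HIV,geographic/socioeconomic
Syphilis,geographic/socioeconomic
Preeclampsia,geographic/socioeconomic
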