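disease,attribute,category,proportion,source
Lupus,gender,female,0.893,printed_prevalence_table
Lupus,gender,male,0.107,printed_prevalence_table
Takotsubo cardiomyopathy,gender,female,0.869,printed_prevalence_table
Takotsubo cardiomyopathy,gender,male,0.131,printed_prevalence_table
Multiple sclerosis,gender,female,0.758,printed_prevalence_table
Multiple sclerosis,gender,male,0.242,printed_prevalence_table
Rheumatoid arthritis,gender,female,0.741,printed_prevalence_table
Rheumatoid arthritis,gender,male,0.259,printed_prevalence_table
Major depressive disorder,gender,female,0.633,printed_prevalence_table
Major depressive disorder,gender,male,0.367,printed_prevalence_table
Huntington disease,gender,female,0.5,printed_prevalence_table
Huntington disease,gender,male,0.5,printed_prevalence_table
Bacterial pneumonia,gender,female,0.49,printed_prevalence_table
Bacterial pneumonia,gender,male,0.51,printed_prevalence_table
Hypertension,gender,female,0.478,printed_prevalence_table
Hypertension,gender,male,0.522,printed_prevalence_table
Amyotrophic lateral sclerosis,gender,female,0.462,printed_prevalence_table
Amyotrophic lateral sclerosis,gender,male,0.538,printed_prevalence_table
COVID-19,gender,female,0.452,printed_prevalence_table
COVID-19,gender,male,0.548,printed_prevalence_table
Multiple myeloma,gender,female,0.445,printed_prevalence_table
Multiple myeloma,gender,male,0.555,printed_prevalence_table
Colon cancer,gender,female,0.429,printed_prevalence_table
Colon cancer,gender,male,0.571,printed_prevalence_table
Tricuspid endocarditis,gender,female,0.42,printed_prevalence_table
Tricuspid endocarditis,gender,male,0.58,printed_prevalence_table
Hepatitis B,gender,female,0.402,printed_prevalence_table
Hepatitis B,gender,male,0.598,printed_prevalence_table
Tuberculosis,gender,female,0.388,printed_prevalence_table
Tuberculosis,gender,male,0.612,printed_prevalence_table
Syphilis,gender,female,0.203,printed_prevalence_table
Syphilis,gender,male,0.797,printed_prevalence_table
HIV,gender,female,0.189,printed_prevalence_table
HIV,gender,male,0.811,printed_prevalence_table
Amyotrophic lateral sclerosis,race,Black,0.065,reconstructed_ratio_minus_spd
Amyotrophic lateral sclerosis,race,White,0.667,reconstructed_ratio_minus_spd
Amyotrophic lateral sclerosis,race,Hispanic,0.202899,reconstructed_census_split
Amyotrophic lateral sclerosis,race,Asian,0.065101,reconstructed_census_split
Bacterial pneumonia,race,Black,0.25,reconstructed_ratio_minus_spd
Bacterial pneumonia,race,White,0.61,reconstructed_ratio_minus_spd
Bacterial pneumonia,race,Hispanic,0.105992,reconstructed_census_split
Bacterial pneumonia,race,Asian,0.034008,reconstructed_census_split
Colon cancer,race,Black,0.156,reconstructed_ratio_minus_spd
Colon cancer,race,White,0.626,reconstructed_ratio_minus_spd
Colon cancer,race,Hispanic,0.165045,reconstructed_census_split
Colon cancer,race,Asian,0.052955,reconstructed_census_split
COVID-19,race,Black,0.137,reconstructed_ratio_minus_spd
COVID-19,race,White,0.67,reconstructed_ratio_minus_spd
COVID-19,race,Hispanic,0.146117,reconstructed_census_split
COVID-19,race,Asian,0.046883,reconstructed_census_split
Hepatitis B,race,Black,0.304,reconstructed_ratio_minus_spd
Hepatitis B,race,White,0.282,reconstructed_ratio_minus_spd
Hepatitis B,race,Hispanic,0.313433,reconstructed_census_split
Hepatitis B,race,Asian,0.100567,reconstructed_census_split
HIV,race,Black,0.417,reconstructed_ratio_minus_spd
HIV,race,White,0.245,reconstructed_ratio_minus_spd
HIV,race,Hispanic,0.255895,reconstructed_census_split
HIV,race,Asian,0.082105,reconstructed_census_split
Huntington disease,race,Black,0.14,reconstructed_ratio_minus_spd
Huntington disease,race,White,0.701,reconstructed_ratio_minus_spd
Huntington disease,race,Hispanic,0.120377,reconstructed_census_split
Huntington disease,race,Asian,0.038623,reconstructed_census_split
Hypertension,race,Black,0.147,reconstructed_ratio_minus_spd
Hypertension,race,White,0.536,reconstructed_ratio_minus_spd
Hypertension,race,Hispanic,0.239996,reconstructed_census_split
Hypertension,race,Asian,0.077004,reconstructed_census_split
Lupus,race,Black,0.284,reconstructed_ratio_minus_spd
Lupus,race,White,0.481,reconstructed_ratio_minus_spd
Lupus,race,Hispanic,0.177915,reconstructed_census_split
Lupus,race,Asian,0.057085,reconstructed_census_split
Major depressive disorder,race,Black,0.105,reconstructed_ratio_minus_spd
Major depressive disorder,race,White,0.667,reconstructed_ratio_minus_spd
Major depressive disorder,race,Hispanic,0.172615,reconstructed_census_split
Major depressive disorder,race,Asian,0.055385,reconstructed_census_split
Multiple myeloma,race,Black,0.212,reconstructed_ratio_minus_spd
Multiple myeloma,race,White,0.655,reconstructed_ratio_minus_spd
Multiple myeloma,race,Hispanic,0.100692,reconstructed_census_split
Multiple myeloma,race,Asian,0.032308,reconstructed_census_split
Multiple sclerosis,race,Black,0.108,reconstructed_ratio_minus_spd
Multiple sclerosis,race,White,0.776,reconstructed_ratio_minus_spd
Multiple sclerosis,race,Hispanic,0.087822,reconstructed_census_split
Multiple sclerosis,race,Asian,0.028178,reconstructed_census_split
Preeclampsia,race,Black,0.18,reconstructed_ratio_minus_spd
Preeclampsia,race,White,0.532,reconstructed_ratio_minus_spd
Preeclampsia,race,Hispanic,0.21804,reconstructed_census_split
Preeclampsia,race,Asian,0.06996,reconstructed_census_split
Prostate cancer,race,Black,0.146,reconstructed_ratio_minus_spd
Prostate cancer,race,White,0.744,reconstructed_ratio_minus_spd
Prostate cancer,race,Hispanic,0.083279,reconstructed_census_split
Prostate cancer,race,Asian,0.026721,reconstructed_census_split
Rheumatoid arthritis,race,Black,0.113,reconstructed_ratio_minus_spd
Rheumatoid arthritis,race,White,0.537,reconstructed_ratio_minus_spd
Rheumatoid arthritis,race,Hispanic,0.26498,reconstructed_census_split
Rheumatoid arthritis,race,Asian,0.08502,reconstructed_census_split
Sarcoidosis,race,Black,0.332,reconstructed_ratio_minus_spd
Sarcoidosis,race,White,0.579,reconstructed_ratio_minus_spd
Sarcoidosis,race,Hispanic,0.067381,reconstructed_census_split
Sarcoidosis,race,Asian,0.021619,reconstructed_census_split
Syphilis,race,Black,0.38,reconstructed_ratio_minus_spd
Syphilis,race,White,0.387,reconstructed_ratio_minus_spd
Syphilis,race,Hispanic,0.176401,reconstructed_census_split
Syphilis,race,Asian,0.056599,reconstructed_census_split
Takotsubo cardiomyopathy,race,Black,0.073,reconstructed_ratio_minus_spd
Takotsubo cardiomyopathy,race,White,0.815,reconstructed_ratio_minus_spd
Takotsubo cardiomyopathy,race,Hispanic,0.084794,reconstructed_census_split
Takotsubo cardiomyopathy,race,Asian,0.027206,reconstructed_census_split
Tricuspid endocarditis,race,Black,0.157,reconstructed_ratio_minus_spd
Tricuspid endocarditis,race,White,0.813,reconstructed_ratio_minus_spd
Tricuspid endocarditis,race,Hispanic,0.022713,reconstructed_census_split
Tricuspid endocarditis,race,Asian,0.007287,reconstructed_census_split
Tuberculosis,race,Black,0.194,reconstructed_ratio_minus_spd
Tuberculosis,race,White,0.113,reconstructed_ratio_minus_spd
Tuberculosis,race,Hispanic,0.52466,reconstructed_census_split
Tuberculosis,race,Asian,0.16834,reconstructed_census_split
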