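attribute,category,synonym
gender,female,female
gender,female,woman
gender,female,women
gender,male,male
gender,male,man
gender,male,men
race,White,White
race,White,Caucasian
race,White,European American
race,Black,Black
race,Black,African American
race,Black,African-American
race,Hispanic,Hispanic
race,Hispanic,Latino
race,Hispanic,Latina
race,Hispanic,Latinx
race,Asian,Asian
race,Asian,Asian American
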