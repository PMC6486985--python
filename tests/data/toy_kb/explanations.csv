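explanation_id,label,kind,code_system,code,regions,age_groups,sex
E001,Malaria,DISEASE,ICD10,B54,Africa;SouthAmerica,,ANY
E002,Influenza,DISEASE,ICD10,J11,,,ANY
E003,Drug fever,MEDICATION,RXNORM,12345,,,ANY
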