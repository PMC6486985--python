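finding_id,label,vocabulary,code
F001,Fever,SNOMED,386661006
F002,Headache,SNOMED,25064002
F003,Rash,SNOMED,271807003
F004,Cough,SNOMED,49727002
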