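explanation_id,finding_id,weight
E001,F001,1.0
E001,F002,0.75
E001,F003,-1
E002,F001,0.5
E002,F002,0.25
E002,F004,0.9
E003,F001,0.3
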