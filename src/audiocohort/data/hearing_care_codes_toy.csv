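code,code_system,fitting_flag
92557,CPT,0
92591,CPT,0
92593,CPT,0
92626,CPT,0
V5011,HCPCS,1
V5241,HCPCS,1
V5014,HCPCS,0
V5266,HCPCS,0
389.10,ICD9,0
389.15,ICD9,0
389.18,ICD9,0
388.30,ICD9,0
H90.3,ICD10,0
H93.13,ICD10,0
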