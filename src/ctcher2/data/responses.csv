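patient_id,best_response
R01,PR
R02,PR
R03,PR
R04,PR
R05,PR
R06,PR
R07,PR
R08,PR
R09,PR
R10,PR
R11,PR
R12,SD
R13,SD
R14,SD
R15,SD
R16,SD
R17,SD
R18,SD
R19,SD
R20,SD
R21,PD
R22,PD
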