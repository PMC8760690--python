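donor_id,donor_age,blood_type,hla_a1,hla_a2,hla_b1,hla_b2,hla_dr1,hla_dr2,allocation_date
D001,62.3,O,A4,A9,B4,B4,DR7,DR8,2018-01-27
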