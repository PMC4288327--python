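life_stage,body_weight,hepatic_fraction_of_adult,gut_fraction_of_adult,mrp2_fraction_of_adult
PND3,0.009,0.0428997,0.05,0.30
PND10,0.020,0.0664820,0.10,0.45
PND21,0.050,0.1671850,0.50,0.75
adult,0.25,1.0,1.0,1.0
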