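life_stage,body_weight,hepatic_fraction_of_adult,gut_fraction_of_adult,mrp2_fraction_of_adult
PND5,0.5,0.4016700,0.80,1.0
PND35,0.8,0.3952800,0.90,1.0
PND70,1.1,0.3662400,0.95,1.0
adult,5.0,1.0,1.0,1.0
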