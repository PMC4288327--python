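# Newborn-human physiology used when extrapolating the newborn (PND5)
# monkey model to newborn humans.  Reference values for a 3.5 kg neonate;
# flow fractions follow the adult human set, cardiac output scaled by
# (BW/70)^0.75.
physiology:
  body_weight: 3.5
  cardiac_output: 33.0
  tissue_volumes:
    venous_blood: 0.18
    arterial_blood: 0.0965
    liver: 0.091
    fat: 0.749
    richly_perfused: 0.175
    slowly_perfused: 1.75
    enterocyte: 0.0125
    gut_lumen: 0.05
  tissue_flows:
    liver_arterial: 2.145
    gut_portal: 4.95
    fat: 1.65
    richly_perfused: 14.355
    slowly_perfused: 9.9
  bile_flow: 0.002
  glomerular_filtration: 0.4
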