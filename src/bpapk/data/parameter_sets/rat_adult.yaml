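schema_version: 1
species: rat
life_stage: adult
physiology:
  body_weight: 0.25
  cardiac_output: 4.95
  tissue_volumes:
    venous_blood: 0.011
    arterial_blood: 0.0075
    liver: 0.00925
    fat: 0.0175
    richly_perfused: 0.0125
    slowly_perfused: 0.1625
    enterocyte: 0.001
    gut_lumen: 0.005
  tissue_flows:
    liver_arterial: 0.099
    gut_portal: 0.6435
    fat: 0.594
    richly_perfused: 2.1285
    slowly_perfused: 1.485
  bile_flow: 0.0023
  glomerular_filtration: 0.02
chemical:
  molecular_weight_parent: 234.33
  molecular_weight_conjugate: 410.41
  partition_coefficients:
    liver: 3.0
    fat: 5.0
    richly_perfused: 4.0
    slowly_perfused: 3.0
  log_kow: 3.3
metabolism:
  hepatic_mode: michaelis_menten
  vmax_hepatic: 540000.0
  km_hepatic: 45200.0
  k_gut_composite: 50.0
  k_enterocyte_passthrough: 10.0
  fraction_hepatic_conjugate_to_bile: 0.995
absorption:
  k_gastric_emptying: 5.0
  k_lumen_uptake: 2.0
ehr:
  vmax_biliary: 2500.0
  km_biliary: 50000.0
  n_transit: 3
  k_transit: 6.0
  k_deconjugation: 0.8
  fraction_reconjugated: 0.90
  fraction_reabsorbed_parent: 0.02
  k_fecal: 0.0576
conjugate:
  n_compartments: 3
  volumes: [0.05, 0.025, 0.025]
  inter_compartment_rates: [0.002, 0.0005]
  urinary_clearance: 0.000658
  fecal_clearance: 0.0
provenance:
  physiology: assumed (standard reference physiology, 0.25 kg rat)
  chemical.molecular_weight_parent: literature-reported (d6-BPA)
  chemical.partition_coefficients.fat: literature-reported (fat:serum 5.0)
  chemical.partition_coefficients.liver: assumed
  chemical.partition_coefficients.richly_perfused: assumed
  chemical.partition_coefficients.slowly_perfused: assumed
  metabolism.vmax_hepatic: calibrated (IVIVE-scaled in vitro Vmax)
  metabolism.km_hepatic: assumed (in vitro Km, hepatic microsomes)
  metabolism.k_gut_composite: calibrated (composite gut conjugation + portal transfer)
  metabolism.k_enterocyte_passthrough: calibrated
  metabolism.fraction_hepatic_conjugate_to_bile: literature-reported (<1% systemic bypass)
  absorption: calibrated (oral profile shape)
  ehr.vmax_biliary: calibrated
  ehr.km_biliary: assumed (MRP2 affinity scale)
  ehr.k_transit: calibrated (bile-to-terminal-ileum delay)
  ehr.k_deconjugation: calibrated
  ehr.fraction_reconjugated: literature-reported (90% re-conjugated)
  ehr.fraction_reabsorbed_parent: calibrated (urine/feces windows)
  ehr.k_fecal: calibrated (urine/feces windows)
  conjugate: calibrated (conjugate terminal phase; urine 6-8% window)
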