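schema_version: 1
species: human
life_stage: adult
physiology:
  body_weight: 70.0
  cardiac_output: 312.0
  tissue_volumes:
    venous_blood: 3.6
    arterial_blood: 1.93
    liver: 1.82
    fat: 15.0
    richly_perfused: 3.5
    slowly_perfused: 35.0
    enterocyte: 0.25
    gut_lumen: 1.0
  tissue_flows:
    liver_arterial: 20.28
    gut_portal: 46.8
    fat: 15.6
    richly_perfused: 135.72
    slowly_perfused: 93.6
  bile_flow: 0.03
  glomerular_filtration: 7.5
chemical:
  molecular_weight_parent: 234.33
  molecular_weight_conjugate: 410.41
  partition_coefficients:
    liver: 1.5
    fat: 3.3
    richly_perfused: 1.5
    slowly_perfused: 0.8
  log_kow: 3.3
metabolism:
  hepatic_mode: first_order
  k_hepatic: 162.46
  k_gut_metabolism: 31.0
  k_enterocyte_conjugate_efflux: 1.03
  k_enterocyte_passthrough: 5.16
absorption:
  k_gastric_emptying: 3.0
  k_lumen_uptake: 1.5
conjugate:
  n_compartments: 1
  volumes: [4.2]
  inter_compartment_rates: []
  urinary_clearance: 3.618
  fecal_clearance: 0.0
provenance:
  physiology: assumed (standard reference physiology, 70 kg adult)
  chemical.molecular_weight_parent: literature-reported (d6-BPA)
  chemical.partition_coefficients.fat: literature-reported (vial equilibration, 3.3)
  chemical.partition_coefficients.liver: assumed
  chemical.partition_coefficients.richly_perfused: assumed
  chemical.partition_coefficients.slowly_perfused: assumed
  metabolism: extrapolated (monkey first-order constants, body-weight scaled)
  absorption: assumed (aqueous oral dosing)
  conjugate.urinary_clearance: extrapolated (monkey value, body-weight scaled)
  conjugate.renal_reabsorption: removed for human (no direct support for renal recycling)
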