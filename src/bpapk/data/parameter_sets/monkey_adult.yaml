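schema_version: 1
species: monkey
life_stage: adult
physiology:
  body_weight: 5.0
  cardiac_output: 53.5
  tissue_volumes:
    venous_blood: 0.21
    arterial_blood: 0.14
    liver: 0.15
    fat: 0.25
    richly_perfused: 0.25
    slowly_perfused: 3.0
    enterocyte: 0.02
    gut_lumen: 0.1
  tissue_flows:
    liver_arterial: 2.14
    gut_portal: 8.025
    fat: 2.675
    richly_perfused: 24.61
    slowly_perfused: 16.05
  bile_flow: 0.01
  glomerular_filtration: 0.6
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
  k_hepatic: 314.61
  k_gut_metabolism: 60.0
  k_enterocyte_conjugate_efflux: 2.0
  k_enterocyte_passthrough: 10.0
absorption:
  k_gastric_emptying: 3.0
  k_lumen_uptake: 1.5
conjugate:
  n_compartments: 1
  volumes: [0.3]
  inter_compartment_rates: []
  urinary_clearance: 0.5
  renal_reabsorption:
    vmax: 711.0
    km: 50.0
  fecal_clearance: 0.0004
provenance:
  physiology: assumed (standard reference physiology, 5 kg monkey)
  chemical.molecular_weight_parent: literature-reported (d6-BPA)
  chemical.partition_coefficients.fat: assumed (human vial-equilibration value)
  chemical.partition_coefficients.liver: assumed
  chemical.partition_coefficients.richly_perfused: assumed
  chemical.partition_coefficients.slowly_perfused: assumed
  metabolism.k_hepatic: calibrated (i.v. serum profile; first-order hepatic conjugation)
  metabolism.k_gut_metabolism: calibrated (oral serum profile)
  metabolism.k_enterocyte_conjugate_efflux: calibrated (early conjugate peak)
  metabolism.k_enterocyte_passthrough: calibrated
  absorption: calibrated (oral profile shape)
  conjugate.urinary_clearance: calibrated (urinary recovery window)
  conjugate.renal_reabsorption: calibrated (slowed conjugate clearance; MRP2 affinity scale)
  conjugate.fecal_clearance: calibrated (<3% fecal recovery)
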