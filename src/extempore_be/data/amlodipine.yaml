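# Amlodipine (dosed as besylate; 5 mg free-base-equivalent per dose).
# Physicochemical / biopharmaceutic / PK inputs from the published
# amlodipine-valsartan 5/80 suspension study parameter set.
name: amlodipine
molecular_weight_g_mol: 567.051      # besylate salt
log_d: 2.66
log_d_ref_ph: 7.4
pka_values:
  - {value: 8.7, species: base}
ref_solubility_mg_ml: 0.774
ref_solubility_ph: 7.4
peff_cm_s: 7.43e-6                   # 0.0743e-4 cm/s, caco-2 assay
peff_assay: caco2
dose_mg: 5.0
dose_volume_ml: 250.0
mean_precipitation_time_s: 900.0
diffusion_coefficient_cm2_s: 4.2e-8
particle_density_g_ml: 1.2
particle_radius_um: 25.0
blood_plasma_ratio: 1.0
fraction_unbound_pct: 2.0
clearance_l_h: 28.0
vc_l_kg: 17.0
half_life_h: 27.03                   # inconsistent with CL/Vc; CL/Vc primary
body_weight_kg: 70.0
simulation_time_h: 144.0
# Drug-level absorption scale, fixed during tablet-model verification by
# anchoring the simulated fraction absorbed to the literature value for
# amlodipine (Fa ~ 0.90, well-absorbed BCS class 1).  See docs/methods.md.
absorption_scale: 16.5
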