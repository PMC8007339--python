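# Valsartan, 80 mg per dose.  Physicochemical / biopharmaceutic / PK inputs
# from the published amlodipine-valsartan 5/80 suspension study parameter
# set.  The printed clearance entry is a typographic artifact; clearance is
# derived from Vc and the elimination half-life (ln2 * 16.1 L / 5.58 h =
# 2.00 L/h) by the disposition module, so it is omitted here.
name: valsartan
molecular_weight_g_mol: 435.53
log_d: -0.34
log_d_ref_ph: 7.0
pka_values:
  - {value: 3.9, species: acid}
  - {value: 4.73, species: acid}
ref_solubility_mg_ml: 16.8
ref_solubility_ph: 8.0
peff_cm_s: 2.62e-5                   # 0.262e-4 cm/s, rat assay
peff_assay: rat
dose_mg: 80.0
dose_volume_ml: 250.0
mean_precipitation_time_s: 900.0
diffusion_coefficient_cm2_s: 1.1e-8
particle_density_g_ml: 1.2
particle_radius_um: 25.0
blood_plasma_ratio: 1.0
fraction_unbound_pct: 5.0
clearance_l_h: null
vc_l_kg: 0.23
half_life_h: 5.58
body_weight_kg: 70.0
simulation_time_h: 72.0
# Drug-level absorption scale, fixed during tablet-model verification by
# anchoring the simulated fraction absorbed to the literature oral
# availability of valsartan (Fa ~ 0.23).  See docs/methods.md.
absorption_scale: 0.56
# Valsartan is fully ionized at intestinal pH and is absorbed from the
# upper gastrointestinal tract only; no caecal/colonic absorption.
colonic_absorption: false
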