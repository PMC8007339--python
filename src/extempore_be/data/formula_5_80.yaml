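# Batch composition of the compounded AML/VAL 5/80 suspension
# (20 bottles x 50 mL; 5 mL dose = 1 tablet equivalent).
components:
  - {name: "Valzadepine crushed tablets 80/5", function: "active ingredients", amount_g_per_batch: 40.00}
  - {name: "Aspartame", function: "sweetening agent", amount_g_per_batch: 2.00}
  - {name: "Mannitol", function: "flavoring agent", amount_g_per_batch: 272.00}
  - {name: "Trisodium citrate", function: "pH modifier/buffering agent", amount_g_per_batch: 3.20}
  - {name: "Sodium hydroxide", function: "pH modifier/buffering agent", amount_g_per_batch: 0.20}
  - {name: "Guar gum", function: "suspending agent", amount_g_per_batch: 3.00}
n_bottles: 20
bottle_volume_ml: 50.0
dose_volume_ml: 5.0
tablets_per_dose: 1
strength_label: "AML 5 mg / VAL 80 mg per 5 mL"
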