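# Observed in-vivo PK of the source tablet and the published model
# predictions (tablet and suspension records) for both actives.
# cmax in ng/mL, auc_0_inf in ng*h/mL.
amlodipine:
  observed: {cmax: 3.200, auc_0_inf: 160.65}
  reported_tablet: {cmax: 3.030, auc_0_inf: 169.81}
  reported_suspension: {cmax: 3.027, auc_0_inf: 169.78}
valsartan:
  observed: {cmax: 747.30, auc_0_inf: 8949.70}
  reported_tablet: {cmax: 704.55, auc_0_inf: 8517.70}
  reported_suspension: {cmax: 707.22, auc_0_inf: 8517.60}
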