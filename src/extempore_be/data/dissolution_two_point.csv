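product,medium_ph,time_min,pct_dissolved,sd
amlodipine_tablet,1.2,15,84.4,2.14
amlodipine_tablet,1.2,30,90.3,1.81
amlodipine_tablet,4.5,15,95.6,1.67
amlodipine_tablet,4.5,30,98.7,1.73
amlodipine_tablet,6.8,15,87.8,1.97
amlodipine_tablet,6.8,30,94.3,0.78
amlodipine_suspension,1.2,15,85.6,1.32
amlodipine_suspension,1.2,30,93.3,1.59
amlodipine_suspension,4.5,15,90.4,1.68
amlodipine_suspension,4.5,30,100.1,1.97
amlodipine_suspension,6.8,15,87.1,0.87
amlodipine_suspension,6.8,30,89.9,1.05
valsartan_tablet,1.2,15,17.7,2.07
valsartan_tablet,1.2,30,25.8,1.91
valsartan_tablet,4.5,15,49.6,2.18
valsartan_tablet,4.5,30,68.1,1.89
valsartan_tablet,6.8,15,104.4,1.83
valsartan_tablet,6.8,30,103.4,1.22
valsartan_suspension,1.2,15,16.1,1.96
valsartan_suspension,1.2,30,23.5,1.45
valsartan_suspension,4.5,15,44.4,1.84
valsartan_suspension,4.5,30,67.9,2.76
valsartan_suspension,6.8,15,99.8,0.56
valsartan_suspension,6.8,30,100.7,1.74
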