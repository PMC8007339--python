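week,drug,pct_remaining
Initial,amlodipine,102.1
Week 1,amlodipine,101.8
Week 2,amlodipine,99.1
Week 3,amlodipine,98.3
Week 4,amlodipine,97.3
Initial,valsartan,106.2
Week 1,valsartan,105.3
Week 2,valsartan,102.2
Week 3,valsartan,101.9
Week 4,valsartan,101.1
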