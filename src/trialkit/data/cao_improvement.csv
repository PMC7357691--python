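arm,improved_days_1_7,improved_days_8_14,improved_days_15_28,no_improvement
lopinavir-ritonavir,6,39,33,22
standard care,2,28,40,30
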