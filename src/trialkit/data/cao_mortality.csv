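arm,deaths_earlier_stage,deaths_later_stage,survivors
lopinavir-ritonavir,8,11,80
standard care,13,12,75
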