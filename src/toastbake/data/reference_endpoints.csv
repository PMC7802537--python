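formulation,T_oven_C,crust_T_C,weight_loss_pct
control,190,128.5,35.11
control,200,143.17,40.25
control,210,163.5,48.47
control,220,176.21,54.05
control,230,190.2,58.31
guar,190,120.18,20.37
guar,200,132.15,26.41
guar,210,143.5,29.57
guar,220,155.0,34.27
guar,230,164.8,37.25
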