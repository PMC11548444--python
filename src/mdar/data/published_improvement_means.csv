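method,mae_improvement_mean_pct,mape_improvement_mean_pct
DeepPhys,49.4,46.6
EfficientPhys,36.8,36.9
PhysFormer,43.5,47.4
PhysNet,31.5,35.7
TS-CAN,30.6,30.2
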