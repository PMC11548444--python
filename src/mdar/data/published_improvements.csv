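method,train_set,test_set,mae_improvement_pct,mape_improvement_pct
DeepPhys,PURE,UBFC-rPPG,78.1,68.9
DeepPhys,PURE,MMPD,26.1,26.2
DeepPhys,UBFC-rPPG,PURE,61.7,59.7
DeepPhys,UBFC-rPPG,MMPD,31.7,31.6
EfficientPhys,PURE,UBFC-rPPG,65.7,58.6
EfficientPhys,PURE,MMPD,11.4,16.6
EfficientPhys,UBFC-rPPG,PURE,56.7,57.3
EfficientPhys,UBFC-rPPG,MMPD,13.4,15.1
PhysFormer,PURE,UBFC-rPPG,55.4,50.1
PhysFormer,PURE,MMPD,31.9,35.1
PhysFormer,UBFC-rPPG,PURE,74.1,85.4
PhysFormer,UBFC-rPPG,MMPD,12.4,18.9
PhysNet,PURE,UBFC-rPPG,56.1,48.7
PhysNet,PURE,MMPD,6.9,8.5
PhysNet,UBFC-rPPG,PURE,78.9,88.8
PhysNet,UBFC-rPPG,MMPD,-15.9,-3.1
TS-CAN,PURE,UBFC-rPPG,42.3,39.2
TS-CAN,PURE,MMPD,10.3,11.4
TS-CAN,UBFC-rPPG,PURE,53.3,53.2
TS-CAN,UBFC-rPPG,MMPD,16.4,16.8
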