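method,train_set,test_set,mae,mape
DeepPhys,PURE,UBFC-rPPG,3.8,3.19
DeepPhys,PURE,MMPD,17.41,19.05
DeepPhys,UBFC-rPPG,PURE,5.94,5.52
DeepPhys,UBFC-rPPG,MMPD,19.06,21.08
EfficientPhys,PURE,UBFC-rPPG,2.42,2.39
EfficientPhys,PURE,MMPD,14.52,16.84
EfficientPhys,UBFC-rPPG,PURE,5.25,5.20
EfficientPhys,UBFC-rPPG,MMPD,15.03,16.97
PhysFormer,PURE,UBFC-rPPG,1.86,1.99
PhysFormer,PURE,MMPD,18.90,21.66
PhysFormer,UBFC-rPPG,PURE,8.75,15.17
PhysFormer,UBFC-rPPG,MMPD,14.86,17.79
PhysNet,PURE,UBFC-rPPG,1.89,1.93
PhysNet,PURE,MMPD,13.82,15.35
PhysNet,UBFC-rPPG,PURE,10.77,19.78
PhysNet,UBFC-rPPG,MMPD,11.61,13.98
TS-CAN,PURE,UBFC-rPPG,1.44,1.63
TS-CAN,PURE,MMPD,14.34,15.86
TS-CAN,UBFC-rPPG,PURE,4.87,4.74
TS-CAN,UBFC-rPPG,MMPD,15.57,17.34
MDAR,PURE,UBFC-rPPG,0.83,0.99
MDAR,PURE,MMPD,12.86,14.05
MDAR,UBFC-rPPG,PURE,2.27,2.22
MDAR,UBFC-rPPG,MMPD,13.01,14.42
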