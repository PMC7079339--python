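# Same as table1 except the effector death rate d = 2e-2, the value used
# for the killing-efficacy bifurcation diagram. Not reconciled on purpose.
model: base
a: 0.514
b: 1.02e-9
k: 1.0e-4
sigma: 10.0
d: 2.0e-2
m: -1.0e-6
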