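# NON-CANONICAL defaults for the saturation model: chosen in the
# exhaustion-dominated regime (b_e < d_e + d) where bistability is common.
model: saturation
a: 0.514
b: 1.02e-9
k: 1.0e-3
sigma: 10.0
d: 1.0e-2
b_e: 0.1
kappa_e: 1.0e4
d_e: 2.0
kappa_d: 1.0e4
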