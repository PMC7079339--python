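# NON-CANONICAL defaults for the NK+CTL model, exhaustion-dominated regime.
model: nkctl
a: 0.514
b: 1.02e-9
c: 1.0e-3
k: 1.0e-3
sigma: 10.0
mu: 1.0e-2
b_n: 0.1
kappa_bn: 1.0e4
d_n: 2.0
kappa_dn: 1.0e4
d: 1.0e-2
b_e: 0.1
kappa_be: 1.0e4
d_e: 2.0
kappa_de: 1.0e4
omega: 1.0e-7
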