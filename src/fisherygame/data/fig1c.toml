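# High/low control (alpha) x high/low risk tolerance (b) sweep scenario.
name = "fig1c"
P = 23.0
q = 0.023
c_prime = 2e-5
f_star = 18.0
alpha1 = 1.0
alpha2 = 1.0
b1 = 0.7
b2 = 0.7
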