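# Invasion experiment: low control, low risk tolerance, B'=0.3, r=1.0,
# 10% cooperative invaders.
name = "fig3b"
P = 23.0
q = 0.023
c_prime = 2e-5
f_star = 18.0
alpha1 = 0.8
alpha2 = 0.8
b1 = 0.7
b2 = 0.7
r_grid = [1.0]
B_grid = [0.3]
x0 = 0.1
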