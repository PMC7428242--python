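# Invasion experiment: high control, high risk tolerance, B'=0.3, r=1.0,
# 10% cooperative invaders.
name = "fig3a"
P = 23.0
q = 0.023
c_prime = 2e-5
f_star = 18.0
alpha1 = 1.0
alpha2 = 1.0
b1 = 0.3
b2 = 0.3
r_grid = [1.0]
B_grid = [0.3]
x0 = 0.1
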