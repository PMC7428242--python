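# Laguna shrimp fyke-net fishery defaults: regulated effort of 18 nets,
# symmetric high control perception and high risk tolerance.
name = "default"
P = 23.0
q = 0.023
c_prime = 2e-5
f_star = 18.0
alpha1 = 1.0
alpha2 = 1.0
b1 = 0.3
b2 = 0.3
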