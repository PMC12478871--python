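# q-SPC/Fw flexible water model parameters.
# Convention: V = (k/2) x^2 for stretch and bend terms.
# k_oh in kcal/mol/A^2, l_eq in A, k_a in kcal/mol/rad^2, theta in degrees,
# charges in e, epsilon in kcal/mol, sigma in A.
k_oh          1059.162
l_eq          1.0
k_a           75.90
theta_eq_deg  112.0
q_o           -0.84
q_h           0.42
epsilon       0.1554253
sigma         3.165492
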