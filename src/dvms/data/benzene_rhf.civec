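# dvms CI vector. benzene RHF/6-31G(d) single determinant
norb 6
n_alpha 21
n_beta 21
core 0 1 2 3 4 5 6 7 8 9 10 11 12 13 14 15 17 18
active 16 19 20 21 22 24
n_terms 1
n_determinants_full 1
total_norm_squared 1.000000000000
stored_norm_squared 1.000000000000
terms
111000 111000  1.000000000000e+00
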