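# Nucleotide-fraction scan of the two-enantiomer model across the
# symmetry-breaking transition: phi_D, phi_L, phi_M versus k_lig at the
# study conditions (C_tot = 10, k_pol = k_hyd = k_int = 1, l_max = 6).
# Expected outcome: mixed oligomers dominate at low k_lig; above the
# transition near k_lig = 4.6 one enantiomer takes over.
[model]
variant = "chirality"
l_max = 6

[run]
engine = "kinetics"
protocol = "biased"
output_dir = "out/chirality_scan"

[scan]
mode = "scan"
parameter = "k_lig"
grid = [0.0, 1.0, 2.0, 3.0, 4.0, 4.5, 5.0, 6.0, 8.0, 10.0]
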