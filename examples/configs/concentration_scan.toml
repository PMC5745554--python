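# Fractions versus total monomer concentration at fixed k_lig = 10.
# Expected outcome: symmetric at low C_tot, chirally biased at high C_tot;
# the critical concentration is roughly inversely proportional to k_lig.
[model]
variant = "chirality"
k_lig = 10.0

[run]
engine = "kinetics"
output_dir = "out/concentration_scan"

[scan]
mode = "scan"
parameter = "C_tot"
grid = [1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0]
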