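# Monomer-selection model with a 10% templating advantage to R
# (k_ligX = 0.9 k_ligR): smallest k_ligR at which the X-dominant branch
# survives the two-phase pure-start protocol.
# Expected outcome: branch limit close to 6.
[model]
variant = "monomer_selection"
k_lig = { R = 1.0, X = 0.9 }   # ratios; the bisection scales both

[run]
output_dir = "out/monomer_selection_branches"

[scan]
mode = "branch_limit"
branch = "X"
bracket = [2.0, 12.0]
tol = 0.1
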