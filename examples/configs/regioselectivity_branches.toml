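# Backbone regioselectivity with a 10% advantage to 3'-5' bonds
# (k_lig2 = 0.9 k_lig3): two-phase scan of both bond-dominant branches.
# Expected outcome: the 3'-5' branch exists everywhere, the 2'-5' branch
# only at high ligation rates.
[model]
variant = "regioselectivity"
k_lig = { 3 = 1.0, 2 = 0.9 }

[run]
output_dir = "out/regioselectivity_branches"

[scan]
mode = "branch_limit"
branch = "2"
bracket = [2.0, 14.0]
tol = 0.25
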