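# Bisection for the critical ligation rate of the chirality model.
# Expected outcome: critical k_lig close to 4.6.
[model]
variant = "chirality"

[run]
output_dir = "out/chirality_critical"

[scan]
mode = "critical"
parameter = "k_lig"
bracket = [1.0, 10.0]
tol = 0.05
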