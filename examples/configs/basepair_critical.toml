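# Base-explicit variant (A,U,G,C in D and L forms; AU/GC-complementary
# templating): bisection for the critical ligation rate.
# Expected outcome: critical k_lig close to 40 -- an order of magnitude
# above the base-agnostic model, because complementarity shrinks the
# template pool for any given product.
[model]
variant = "chirality_basepair"

[run]
output_dir = "out/basepair_critical"

[scan]
mode = "critical"
parameter = "k_lig"
bracket = [25.0, 60.0]
tol = 0.5
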