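# Cross-validation of the two engines on one point of the chirality model:
# stochastic time averages against the deterministic steady state.
# Expected outcome: phi values agree within a few standard errors.
[model]
variant = "chirality"
k_lig = 2.0

[montecarlo]
N_tot = 2000
V = 200.0
total_time = 120.0
burn_in = 30.0
seed = 1

[run]
engine = "both"
output_dir = "out/mc_vs_kinetics"
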