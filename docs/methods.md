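# Methods

## The model

All four variants share one reaction scheme over a well-mixed pool with a
fixed total nucleotide concentration `C_tot` (deterministic engine) or a
fixed integer nucleotide count `N_tot` in volume `V` (stochastic engine):

* **Spontaneous polymerisation.** Any ordered pair of strands (*i*, *j*)
  joins into the concatenation *ij* at rate `k_pol · C_i · C_j`. In the
  regioselectivity variant the join can form either backbone bond type;
  each occurs at `w_b · k_pol · C_i · C_j` with weights defaulting to ½, so
  the total join rate is unchanged and the equilibrium length distribution
  matches the other variants.
* **Hydrolysis.** Every bond of every strand severs at rate `k_hyd`,
  regenerating the two exact fragments.
* **Template-directed ligation.** The pair (*i*, *j*) is additionally
  joined at rate `k_lig · C_i · C_j · C_temp(ij)` when both partners are
  uniform and of a common type. `C_temp(ij)` aggregates all qualifying
  template material; a species is never excluded from its own template pool
  (concentrations are continuum quantities, so "the same molecule" has
  measure zero). Templating is a single effective trimolecular step: no
  duplex intermediates, and the product leaves the template immediately.
* **Monomer interconversion.** Free monomers switch type at rates
  `k_int(a→b)`; nucleotides inside strands cannot switch. This conserves
  total nucleotide number while letting the type composition drift — the
  ingredient that makes symmetry breaking possible. The regioselectivity
  variant has no analogue: bond-type numbers change only through hydrolysis
  and re-joining.

Template qualification per variant (always a *contiguous* requirement —
the worked rule is that a qualifying template carries an unbroken uniform
stretch at least as long as the product):

* *chirality / monomer selection*: a run of the product's monomer type of
  length ≥ the product length;
* *base-explicit*: a uniform-chirality window of the product's chirality
  whose base sequence pairs with the product under AU/GC complementarity
  (conventions below);
* *regioselectivity*: a run of the product's bond type at least as long as
  the product's bond sequence. Bare monomers carry no bonds and are
  compatible with either bond type.

## Template-counting conventions in the base-explicit variant

Whether the complementary window is read parallel or antiparallel to the
product is immaterial for the dynamics studied here: whole-strand reversal
commutes with every reaction and maps one convention's qualification rule
onto the other's, so from reversal-symmetric initial states (any monomer
start) the two give identical trajectories. This equivalence is asserted in
the test suite.

Two genuinely distinct choices remain, both exposed on `ModelSpec`:

* `complement_orientation`: accept one oriented alignment
  (`"antiparallel"` / `"parallel"`) or both (`"either"`). Model strands
  carry no 5′/3′ orientation, so `"either"` is the natural reading — an
  unoriented template can present a window in both alignments.
* `template_counting`: aggregate `C_temp` per qualifying strand
  (`"per_strand"`) or per matching window (`"per_site"`), i.e. treat each
  complementary alignment site as an independent binding opportunity.

Measured critical rates at the study conditions: single oriented
convention, per-strand ≈ 85; `either`, per-strand = 53.0; `either`,
per-site = 40.2. The base-explicit preset defaults to `either` + per-site —
each matching window is a distinct site at which the two substrates can be
brought together, and this convention also reproduces the transition value
reported for this model family. The simple variants default to per-strand
counting (their templates are runs, where "the strand qualifies" is the
natural unit and yields the reference transition at k_lig ≈ 4.64); per-site
counting is available for them as well.

## Deterministic engine

The full species set up to `l_max` is enumerated (canonical order: length,
then alphabet-lexicographic) and all reaction terms are flattened into
index arrays; one time derivative costs a sparse mat-vec for the template
sums plus a few vectorised gathers/scatters. Mass conservation is
structural: every term moves whole fragments, so Σ nᵢCᵢ drifts only by
floating-point rounding (< 1e-9 relative over full runs, asserted in
tests).

**Symmetry lumping.** The base-explicit system at `l_max = 6` has 299,592
sequences. Its dynamics commute with the 8-element group of base
permutations preserving AU/GC pairing, extended by strand reversal (16
elements). From group-symmetric initial states the concentration vector is
constant on orbits, so the engine integrates 19,699 orbit representatives
with orbit sizes as weights — an exact reduction, validated against the
unlumped system at `l_max = 3` to machine precision. Initial-condition
helpers always split each chirality's monomer mass equally over the four
bases, which keeps states inside the symmetric manifold the reduction
requires.

**Integration.** Forward Euler with two safeguards: a stability cap
`dt ≤ 0.8 / max λᵢ` (λᵢ = total per-concentration loss coefficient of class
*i*) and a per-step change limit (`rtol_step = 0.05` relative, absolute
floor `atol_step · C_tot = 1e-6`), both capped by `dt_max = 0.05`. The
loose relative limit is deliberate: fixed points of the Euler map are exact
steady states at *any* step size, so converged observables are independent
of the step policy (asserted by a dt-halving test); a tight limit would
only slow the transient. Steady state is declared when the maximum
per-unit-time concentration change falls below `ss_tol · C_tot`
(`ss_tol = 1e-10`) for 100 consecutive steps. Any concentration driven
below −1e-12·C_tot aborts with a step-size diagnostic; values in
(−1e-12·C_tot, 0) are clipped to zero.

## Stochastic engine

Fixed-timestep Monte Carlo over an explicit strand multiset. Per step,
iterating over a snapshot taken at step start: each strand hydrolyses with
probability `(n−1)·k_hyd·dt` at a uniform bond; each strand joins a
uniformly chosen partner with probability `(N_strands−1)/V·k_pol·dt`; for
each strand a partner and one candidate template are drawn and, if the
candidate qualifies, ligation is accepted with probability
`(N_strands−1)(N_strands−2)/V²·k_lig·dt` (multiplied by the site count
under per-site counting); each free monomer switches type with probability
`k_int·dt` per destination. The sub-channels run in the fixed order
hydrolysis → polymerisation → ligation → interconversion; strands consumed
earlier in a step are skipped by later channels and strands created within
a step react only from the next step. These snapshot semantics make the
expected per-step rates equal the mass-action rates at step start; the
residual within-step ordering bias is first order in the step probabilities
and therefore bounded by the adaptive-dt target.

`dt` starts at 5·10⁻⁵ and is re-targeted every 20 steps so that
max(p_pol, p_lig) ≈ 5% (configurable), never growing by more than ×2 per
adjustment; any probability reaching 1 halves `dt` and retries the step.
Because the scheme is first order in `dt`, time averages carry a systematic
O(target) bias (≈2% of a fraction at the 5% default); tests comparing
against closed forms or the deterministic engine therefore run at targets
of 1–2%, where the bias sits below three standard errors of the block
averages. All randomness flows from one seeded generator; identical
configuration and seed reproduce trajectories bitwise. The integer
nucleotide count is asserted at every sample.

Time averages discard a configurable burn-in and report block-averaged
standard errors (10 blocks by default); in symmetric variants the dominant
type can be relabelled first, the convention used when runs may have broken
symmetry in either direction.

## Locating transitions

`find_critical` bisects a control parameter (`k_lig` or `C_tot`). Each
point is classified from a cold biased monomer start (0.505/0.495 by
default; cold starts keep hysteresis out of the estimate): *broken* if the
steady-state oligomer excess |ee| exceeds 0.01, *symmetric* otherwise. The
classifier exploits that deterministic trajectories are smooth: it stops
early once |ee| crosses 0.05 (broken), falls below 5% of the initial bias
(symmetric), or shows a sustained exponential trend over 15-time-unit
windows after a 60-unit burn-in; at t = 400, far past all fast transients,
the raw sign of the trend decides. This matches the plain steady-state
threshold criterion except within a negligibly thin parameter sliver around
the bifurcation (the asymptotic excess rises steeply from zero), and the
agreement is cross-checked against the full steady-state criterion at
coarse tolerance in the tests. Monte Carlo classification instead
thresholds the time-averaged |ee| (default 0.25) against the
fluctuation background.

`find_branch_limit` brackets the smallest control value at which a
minority-type branch survives the two-phase protocol: phase 1 relaxes a
pure-type monomer pool with interconversion off (regioselectivity: with
spontaneous polymerisation restricted to one bond type, since no
interconversion exists to switch off); phase 2 restores the full dynamics
and the branch "persists" if the starting type still holds the largest
uniform fraction at steady state. The phase-2 run exits early once
dominance is lost, as the collapse onto the competing branch is
irreversible.

Grid scans warm-start each point from the previous endpoint for
continuation through bistable regions; under the biased protocol the free
monomer pool is re-biased at each point so continuation cannot pin the run
to the unstable symmetric manifold.

## Closed-form equilibrium (the k_lig = 0 oracle)

Without templating every reaction is reversible and the equilibrium
factorises: `C(s) = Π_bonds (w_b·k_pol/k_hyd) · Π_monomers m_a`, with
monomer activities fixed by the interconversion detailed-balance ratios
`m_b/m_a = k_int(a→b)/k_int(b→a)` and one mass-balance polynomial
`Σ n·rⁿ⁻¹·Mⁿ = C_tot` (geometric closed form for unbounded length). The
total strand concentration per length, `rⁿ⁻¹Mⁿ`, is variant-independent —
the ½-rate rule for the two bond types is what preserves this in the
regioselectivity variant. Both engines are tested against this form; it is
computed by `templig.closedform`, independent of either engine.

## Problem sizes and study conditions

Shipped defaults are the study conditions: `C_tot = 10`,
`k_pol = k_hyd = k_int = 1`, `l_max = 6`, and for the stochastic engine
`N_tot = 10⁵`, `V = 10⁴`, initial `dt = 5·10⁻⁵`, 5% step-probability
target. The test suite and examples run the same models at reduced
stochastic population sizes (N_tot of 400–5000) and coarser bisection
tolerances where a check needs only ordering or a band rather than a
precise location; each test states its sizes explicitly. Reduced
populations have larger fluctuations and finite-size rounding near the
transition, which is why stochastic checks are phrased in block-averaged
standard errors rather than point equality.

## What the simulations do and do not show

The models demonstrate the *mechanism* — templating by uniform strands
plus cross-inhibition through mixed polymerisation yields sharp symmetry
breaking under exact symmetry and gradual selection with branch limits
under approximate symmetry. They abstract away duplex
formation/melting, sequence-dependent rates beyond the uniformity rules,
monomer precursors and spatial structure; passing tests say nothing about
those. Quantitative transition locations are specific to the conventions
above (notably the base-explicit template-counting convention, where the
per-strand alternatives shift the critical rate upward by 30–110%) and to
`l_max`, whose enlargement shifts transitions upward (asserted only as an
ordering, 6 < 10 < unbounded).

## Known limitations

* Forward Euler needs many steps near criticality (critical slowing down);
  the trend classifier mitigates this for transition location but full
  steady-state convergence close to a critical point is slow.
* The stochastic engine is first-order accurate in `dt`; its bias is
  controlled, not eliminated, by the step-probability target.
* Monte Carlo transition estimates at small `N_tot` are rounded by finite
  size and classified against a fluctuation background; they are reliable
  for orderings and coarse locations, not for sharp critical values.
* The interconversion matrix must satisfy detailed balance for the
  closed-form oracle (one-way cycles are rejected there, though the
  engines themselves accept any non-negative rates).
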