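# Methods

## Scope and model structure

`varflux` connects three levels of description. At the molecular level the
inputs are binding free-energy differences ΔΔG = ΔG_WT − ΔG_mut between a
wild-type and a variant enzyme for a given ligand (computed elsewhere, by
MM-PBSA-style methods, or measured); a negative value means the wild type
binds more strongly. At the intermediate level these are converted to
Michaelis-constant and flux-capacity ratios. At the systems level the
ratios perturb either a constraint-based network (flux bounds) or a
mass-action kinetic network (rate constants), and phenotypes are read off:
exchange-flux biomarker categories, flux-distribution shifts, maximum
tolerable oxidative/energy load, and viability.

## Thermodynamic bridge

Km is treated as a proxy for the dissociation constant (rapid-equilibrium
binding), giving ΔΔG = R·T·ln(Km_wt/Km_mut) and its inverse
Km_mut/Km_wt = exp(−ΔΔG/(R·T)), R = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹. The
default temperature is 298.15 K: recomputing the G6PD worked example from
its published Km pair (52 vs. 9.71 μM) gives 0.99 kcal/mol at 298.15 K
(310 K would give 1.03), so the standard temperature is the default and is
exposed in `AnalysisConfig`.

The flux-capacity ratio v_mut/v_wt at equal substrate and enzyme
concentration depends on the kinetic regime, which is configurable rather
than fixed because the saturation state of the perturbed enzyme is not an
observable of the inputs:

- `SUBSATURATING` (default): v ∝ kcat/Km, ratio = kcat_ratio/km_ratio;
- `SATURATING`: v ∝ kcat;
- `EXPLICIT_S`: full Michaelis–Menten quotient at a stated S/Km_wt.

The sub-saturating form is the default reading of "equal substrate and
enzyme concentration": most erythrocyte enzyme substrates sit at or below
their Km.

## Constraint-based engine

The flux space is {v : S·v = 0, lb ≤ v ≤ ub}. FBA and FVA are solved with
HiGHS (`scipy.optimize.linprog`); FVA endpoints and FBA objective values
are unique even when optimal vertices are not, so no vertex-identity
assumptions are made. Exchange fluxes are secretion-positive.

Gene knockouts evaluate the reaction's gene–protein–reaction boolean
(AND = all required, OR = any suffices, case-insensitive, isoforms as
opaque ids like `Aldoa.1`) and pin failing reactions to zero. Knockouts
accumulate on the model copy, so sequential knockouts behave like a
double-deletion.

Variant integration scales the wild-type FVA range of the target reaction
by the flux-capacity ratio, symmetrically in both flow directions, and
clamps the result inside the model's original physical bounds; ratio 1
pins the bounds exactly to the wild-type range. A ratio above 1
(strengthened binding) therefore cannot create capacity beyond the
model's physical limits — a deliberate choice, since capacity gains from
tighter binding are not certain to be realizable.

Exchange changes between wild-type and mutant FVA ranges are categorized,
in order: no change (both endpoints within ε), inactivation (active →
confined to [−ε, ε]), activation (zero-confined → forced nonzero),
direction fixed (straddles zero → one side), and magnitude change iff the
mutant span is below 40% of the wild-type span (`span_fraction_threshold`,
default 0.40); otherwise no change. ε = `zero_flux_tol` (default 10⁻⁶)
absorbs LP round-off.

### ACHR sampling

Uniform-ish flux states are drawn with artificial-centering hit-and-run:
warmup vertices from LPs with standard-normal random objectives (at most
min(2·n_reactions, 200)); each step picks a stored point, walks along the
direction from the running center to it (differences of feasible points
stay in the null space of S), line-searches the chord within bounds with a
relative 10⁻⁹ shrink to remain strictly interior, and draws uniformly on
the chord. Every kept point is re-projected onto S·v = 0 through the
pseudoinverse, so steady-state residuals stay at machine precision.
Thinning defaults to 10; the pipeline uses 50 because the
Kolmogorov–Smirnov shift tests treat draws as weakly dependent and
under-thinned chains over-flag shifts. Everything is a pure function of
the seed.

### Distribution shifts

Per-reaction two-sample KS tests (`scipy.stats.ks_2samp`), significant at
p < α (default 0.05) with no multiplicity correction by default — the
plain per-reaction 0.05 rule — and optional Benjamini–Hochberg. The
particular two-sample test is a documented, swappable choice; identical
constant columns report p = 1.

### Essentiality screen

Per gene: knockout → exchange FVA → categorization against wild type; a
gene is network-important iff any exchange category differs from
no-change. An infeasible knockout model counts as important.

## Structure QC and target triage

Each candidate structure is scored as
`0.35·coverage + 0.35·identity + 0.20·max(0, 1 − (res − 1 Å)/4 Å)
+ 0.10·exp(−missing_interior/10)`; homology models take the resolution
term's neutral midpoint (0.5). The criteria order (coverage and identity
dominant, then resolution, then completeness) is fixed; the numeric
weights are a package choice and are configurable, as are the group
thresholds: best structures are usable as-is at identity 1, coverage
≥ 0.8 and no interior gaps; need only point modification at identity
≥ 0.95 and coverage ≥ 0.8; otherwise need a homology model. Ties break
lexicographically by structure id so ranking is a total order.

Target triage is a first-match rule cascade: Class I = structure +
variant–drug association + drug-binding info; Class II = structure +
variant-effect data without a drug association; Class III =
network-important with a structure and neither pharmacogenomic flag;
Class IV = network-important alone. The exact II/III/IV predicates are
interpretation where the source material lists examples rather than
rules; dossiers matching nothing are reported unclassified rather than
forced into a class.

## Kinetic engine

Reactions are elementary or pseudo-elementary rate laws. Calibration fixes
each forward constant from the reference state:
kf = v_ref/(Π x_sub^|c| − Π x_prod^|c|/Keq), reverse constant kf/Keq;
irreversible reactions drop the product term; demand reactions take
kf = v_ref directly. The reference state is then a fixed point by
construction. A reaction at equilibrium with zero reference flux keeps a
free kf = 1 and is flagged; zero disequilibrium with nonzero flux is an
error naming the reaction.

Variant enzymes are housed in explicit modules E + S ⇌ ES → E + P with
Km = (k₋₁ + k₂)/k₁ and kcat = k₂. The free constant is fixed by k₋₁ = 4·k₂
(binding equilibrates faster than turnover), and the enzyme total is
chosen so the module's steady-state rate at the reference concentrations
equals the reference flux — whole-model fixed point preserved to
round-off. Co-substrates of the turnover step (cofactors like NADP⁺ or
ADP) enter through a bounded saturation factor g(x) = 2x/(x + x_ref),
normalized to 1 at reference: realized kcat at the reference state is
exactly k₂, turnover stalls as a co-substrate is exhausted, and the boost
from co-substrate accumulation is capped at 2 per stoichiometric unit.
How Km enters the rate law is a mechanistic housing choice of this
package. `apply_variant_kinetics` scales k₂ by the kcat factor and then
recomputes k₁ against the unchanged k₋₁ so the realized Km is exactly the
requested multiple.

### Steady states and viability

Stiff integration (LSODA, rtol 10⁻⁸, atol 10⁻¹⁰) over geometric
checkpoints; a state is feasible when ‖dx/dt‖∞ < tol·max(1, ‖x‖∞) with
tol = `steady_state_tol` (10⁻⁸). Because the integrator's own tolerance
bounds the attainable residual, convergence is finished with a Newton
polish: once the integrated residual falls below 10⁻⁵·scale, the exact
root is located and accepted only if it is adjacent to the integrated
state and nonnegative. Infeasibility (the model's notion of lysis) is
declared when a watched species falls below the extinction threshold
(10⁻⁹ mM; the species is named), when any concentration exceeds a runaway
ceiling (10³ mM — an unconsumed input piling up has no steady state), or
when `t_max` (default 2×10³ time units, ample for a core that equilibrates
within hundreds) passes without convergence. Integration failures are
results, never exceptions.

### Loads and titration

Oxidative load is an NADPH → NADP⁺ demand; energy load an ATP → ADP
demand. The oxidative drain is zero-order (constant flux): oxidant influx
does not slow because NADPH is scarce, and this is what gives a sharp,
finite maximum tolerable load — a first-order drain in a closed
mass-action network simply re-balances at a lower cofactor level and
never fails. The ATP drain is first-order (ATPase demand scales with ATP
availability), which also damps the classic glycolytic investment–payback
instability; with a zero-order ATP demand the reference state is an
unstable spiral. Titration scales the demand constant over an increasing
grid (default 1–4× baseline), starting each solve from the previous
feasible steady state (a gradually increasing stress, not an
instantaneous jump — jumps can overshoot transiently into collapse even
when the target steady state exists), and refines the feasibility
boundary by bisection to 1% relative width. Reported alongside: the
NADPH/NADP⁺ (or ATP/ADP) ratio at baseline and at the maximum tolerated
load.

### Parameter recovery

`infer_kinetic_factors` grid-searches (Km factor, kcat factor) pairs,
simulating each candidate from the reference state and minimizing the
summed squared relative deviation from an observed trajectory. At
noise-free desk scale an 11×11 geometric grid over [0.2, 2] recovers true
factors to within the grid resolution (<10%).

## The synthetic fixtures

The toy genome-scale model (~25 reactions, 16 synthetic genes) emulates
the features the analyses exercise: glycolysis split around a GAPDH-like
step, a pentose-phosphate branch with a G6PD-like step feeding an
NADPH-consuming oxidant-detoxification path, lactate export, a
catechol-methylation pair (substrates imported, methylated products
exported, both gated by one gene) so reduced methylated-product export is
observable, an isozyme pair and a complex transporter rule for the GPR
cases. It is not a reconstruction of any organism; bounds and topology
are fixture constants.

The mini-RBC kinetic core (12 lumped reactions, 12 metabolites + module
species; pools ATP/ADP, NAD/NADH, NADP/NADPH) has a constant glucose
supply, hexokinase and upper-glycolysis lumps, a GAPDH lump (ATP payback,
NADH production), lactate dehydrogenase and export, a G6PD lump feeding
R5P and NADPH, a partial pentose recycle (R5P → 5/3 G3P) with a small R5P
drain, a small first-order G3P leak (a methylglyoxal-like shunt that
keeps the G3P pool bounded), and the two load drains. The recycle exists
because without carbon return from the pentose branch the maximum
oxidative load would be pinned by the energy constraint for wild type and
every mutant alike, making kcat comparisons undiscriminating. Reference
concentrations are physiologically plausible magnitudes (mM scale) and
reference fluxes satisfy S·v = 0 exactly by construction; all are fixture
constants at desk scale, not estimates of any published erythrocyte
model, and time units are arbitrary. The G6PD module's Km (0.052 mM)
mirrors the published wild-type Km for glucose-6-phosphate; the G6PD
scenario's kcat reduction factor (0.15) is a fixture constant standing in
for an experimentally reported turnover loss whose value is not in the
extracted source. COMT-like ΔΔG values are synthetic stand-ins with the
reported sign (weakened binding); the G6PD and GAPDH ΔΔG values are the
published central estimates.

What passing tests show, and what they do not: the fixtures demonstrate
that the machinery propagates perturbations with the right directions and
invariants (reduced methylated export for weakened methylation; oxidative
fragility only when turnover drops, not from tighter binding alone; a
lethality threshold in GAPDH Km). Magnitudes — maximum load multiples,
cofactor ratios, which exchanges shift — are properties of the surrogate
networks and carry no quantitative claim about real erythrocytes.

## Numerical choices and limitations

- LP: HiGHS; categorization tolerances absorb solver round-off.
- ODE: LSODA with the tolerances above; moiety pools are conserved by
  stoichiometry and verified to 10⁻⁸ relative along trajectories.
- The KS tests assume weakly dependent draws; the pipeline's thinning
  (50) was chosen so the null scenario flags nothing beyond the nominal
  rate on the toy model. Heavier models may need more.
- Sampling and FVA are serial; no loopless FVA, no thermodynamic
  (ΔG-constrained) FBA.
- SBML import covers the Level 3 + fbc subset (species, reactions, flux
  bounds, gene associations); unsupported constructs are reported, not
  silently dropped. Full round-trip fidelity is out of scope.
- The titration's feasibility boundary is resolved to 1% by bisection
  under continuation; boundaries reached through qualitatively different
  routes (e.g. an abrupt parameter jump) can differ transiently.
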