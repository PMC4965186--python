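# varflux

Multi-scale integration of protein variant effects into metabolic
phenotypes. `varflux` takes the output of molecular binding calculations —
wild-type vs. mutant binding free-energy differences ΔΔG = ΔG_WT − ΔG_mut —
and propagates them through two systems-level models of erythrocyte-style
metabolism:

- a **constraint-based** model (stoichiometric matrix S, flux bounds,
  gene–protein–reaction rules), analysed with flux balance analysis (FBA),
  flux variability analysis (FVA), gene knockouts, artificial-centering
  hit-and-run (ACHR) flux sampling, and Kolmogorov–Smirnov tests for
  flux-distribution shifts;
- a **mass-action kinetic** model whose pseudo-elementary rate constants
  (PERCs) are calibrated from a reference steady state,
  `kf = v_ref / (Π x_sub − Π x_prod / Keq)`, with explicit enzyme modules
  `E + S ⇌ ES → E + P` so Michaelis parameters (Km, kcat) can be edited
  directly and oxidative (NADPH-demand) and energy (ATP-demand) loads can
  be titrated to the cell's maximum tolerable multiple.

The bridge between scales is thermodynamic: treating Km as a dissociation
constant,

```
ΔΔG = R T ln(Km_wt / Km_mut)        Km_mut / Km_wt = exp(−ΔΔG / R T)
```

with R = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹, and a flux-capacity ratio
v_mut/v_wt computed from the Km and kcat ratios in a chosen kinetic regime
(sub-saturating by default, v ∝ kcat/Km). Negative ΔΔG means the wild type
binds more strongly, so the mutant loses catalytic capacity.

The package is aimed at systems pharmacology work that triages enzyme
variants: which exchange fluxes (candidate biomarkers) change, whether the
change is an activation, inactivation, a fixed direction, or a magnitude
change (a mutant flux span below 40% of wild type), and whether the
kinetic cell model remains viable under stress.

It also ships the bookkeeping around that workflow: a structure-quality
ranking per gene (coverage, identity, resolution, interior completeness)
with three QC groups, and a four-class pharmacogenomic triage of targets
by available structure, drug-binding and variant-effect evidence, and
network importance.

Everything runs on packaged synthetic inputs — a ~25-reaction toy
genome-scale model and a 12-reaction "mini-RBC" kinetic core with an
exactly balanced reference state — so no downloads are needed.

## Worked example

```python
import varflux as vf

# the G6PD "Andalus" variant: experimental Km pair for glucose-6-phosphate
print(round(vf.ddg_from_km(52.0, 9.71, 298.15), 2))   # 0.99 kcal/mol

# predicted tightened substrate binding (ddG = +3.00 kcal/mol)
km_factor = vf.km_ratio_from_ddg(3.00)                 # 0.0063

kin = vf.make_mini_rbc_with_modules()
cfg = vf.AnalysisConfig(rng_seed=1)

wt  = vf.titrate_load(kin, vf.LoadType.OXIDATIVE, cfg=cfg)
mut = vf.titrate_load(
    vf.apply_variant_kinetics(kin, "G6PD", km_factor, 0.15),  # + kcat loss
    vf.LoadType.OXIDATIVE, cfg=cfg)

print(wt.max_load,  round(wt.ratio_at_baseline, 1))    # 2.3125 30.0
print(mut.max_load, round(mut.ratio_at_baseline, 2))   # 1.1375 2.18
```

Reading: the wild-type mini-RBC tolerates an NADPH demand about 2.3× its
baseline before the steady state is lost; with the variant's tightened Km
*and* reduced turnover the tolerable oxidative load drops to ~1.14× and
the resting NADPH/NADP⁺ ratio falls from 30 to ~2.2 — the oxidative
fragility expected of a severe G6PD deficiency. With the Km change alone
(`kcat_factor=1.0`) the tolerable load is not reduced. The analogous GAPDH
scenario (`vf.apply_variant_kinetics(kin, "GAPDH", 400.0, 1.0)`) has no
feasible steady state at all — lethality — while mild Km increases are
tolerated.

The same scenarios run end to end (thermo conversion → bound adjustment →
FVA → exchange categorization → flux sampling → shift tests → kinetics)
via the pipeline or the CLI:

```bash
varflux run --scenario g6pd_like --seed 1 --out results/
varflux make-fixtures --out fixtures/
varflux fva --model fixtures/toy_gem.json --out fva.tsv
```

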