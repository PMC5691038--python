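# Methods

`heteroflux` implements constraint-based analysis of obligate
heterofermentative lactic acid bacteria — organisms such as
*Leuconostoc mesenteroides* that lack fructose-1,6-bisphosphate aldolase
and catabolize sugars exclusively through the phosphoketolase pathway
(PKP). This note records the models, conventions, numerical choices and
known limitations.

## Flux balance analysis

The engine solves

```
max  Z = Σ_j c_j v_j
s.t. Σ_j S_ij v_j = 0      for every metabolite i
     v_min,j ≤ v_j ≤ v_max,j
```

with scipy's HiGHS solver (primal/dual feasibility 1e-9). Reported
fluxes are rounded at 1e-6 so structural zeros survive yield-ratio
arithmetic. Exchange reactions follow the COBRA convention
(`met_e <->`, negative flux = uptake); default bounds are (−1000, 1000)
for reversible and (0, 1000) for irreversible reactions, in
mmol gDCW⁻¹ h⁻¹.

**Alternate optima.** Headline scenario numbers are computed through a
parsimonious tie-break: among flux vectors within relative 1e-9 of the
optimum, the vector minimizing Σ|v| (an LP after flux splitting) is
returned. This makes degenerate aerobic states deterministic. Plain FBA
remains available.

**Flux variability** (FVA) re-optimizes each flux subject to
Z ≥ fraction·Z\* (with a 1e-9 slack so the optimal vertex stays
feasible). **Blocked reactions** are those whose FVA range is {0} with
every exchange opened — a deliberate, behaviourally equivalent
replacement for MILP dead-end detection. The **flux-sum**
φ_i = ½ Σ_j |S_ij v_j| measures metabolite turnover; for any
mass-balanced metabolite it equals both total production and total
consumption.

**Sampling** uses artificial-centering hit-and-run: warm-up points from
per-reaction min/max LPs, chord directions from stored points minus the
running center (differences of feasible points stay in the null space
of S, so no projection is needed and no clipping is applied — clipping
would leave the steady-state subspace). Warm-up is 10×dimension steps;
the convergence setting used for regulation Z-scores is 5000 kept
points at 500-step thinning; tests and small studies scale this down
(150–500 points, 10–20-step thinning) to keep runtimes in seconds. The
seed is a mandatory argument (default 0).

**Essentiality and auxotrophy** both use the >90 % growth-reduction
rule: a gene is essential (a nutrient auxotrophic) when deleting it
(closing its uptake) drops growth below 10 % of the reference. The
essentiality threshold deliberately reuses the auxotrophy rule.

## The central-metabolism fixture

`heteroflux.central` builds an ~60-reaction, fully mass- and
charge-balanced model of heterofermentative central carbon metabolism:
oxidative pentose-phosphate entry (G6P → 6PG → Ru5P, 2 NAD(P)H),
ribulose-phosphate epimerase, phosphoketolase (X5P + Pi → acetyl-P +
GAP), lower glycolysis, lactate/acetate/ethanol branches, pyruvate
oxidase + NADH peroxidase + NADH oxidase aerobic machinery, the
fructose→mannitol redox valve, malolactic fermentation (one-step
malolactic enzyme or the three-step MDH/OAA-decarboxylase/LDH variant),
PTS and permease glucose entry, F₀F₁-ATPase, and a small biomass
equation. An EMP variant swaps the phosphoketolase route for
PFK + aldolase + triose-phosphate isomerase.

### Proton closure

Protons and water are ordinary metabolites. There is no free
transmembrane proton leak: with a reversible ATPase a leak would allow
ATP synthesis from nothing. The proton ledger closes through

* proton-coupled efflux of lactate and acetate (equivalently, export of
  the undissociated acids); ethanol and CO₂ diffuse freely;
* a malate–H⁺ symporter, with the malolactic decarboxylation consuming
  one cytosolic proton;
* the F₀F₁-ATPase written with its true chemistry,
  `adp + pi + h + n h_e <-> atp + h2o + n h` (n = 4 by default), so one
  full synthesis–hydrolysis cycle translocates exactly n protons per
  ATP;
* ATP-consuming maintenance/drain reactions releasing their hydrolysis
  proton into the cytosol.

Under this convention the textbook substrate-level yields are exact:
1 ATP/glucose (PKP), 2 ATP/glucose (EMP), and malolactic fermentation
returns 1/n ATP per malate (0.25 at n = 4): the net cytosolic proton
consumed per malate is worth one ATPase translocation cycle. Glucose
entry under the `symporter` option is modelled as a proton-neutral
permease: without a membrane potential, a proton-symport stoichiometry
would make the co-transported proton a hard cytosolic burden and push
the anaerobic drain yield to zero rather than the substrate-level
value; the organism's putative glucose permease (glcU) supports the
proton-neutral reading.

### Biomass equation

The fixture's biomass draws G6P, PEP, PYR, OAA, acetyl-CoA,
NAD(P)H-equivalent reducing power, three amino acids
(glutamate/glutamine/aspartate) and GAM ATP (13.613 mmol gDCW⁻¹, the
estimated growth-associated maintenance; NGAM defaults to 0 in the
fixture and is configurable). Two structural identities pin the
redox-forced fermentation stoichiometry:

* acetyl-CoA draw = PEP + OAA + PYR draws, and
* NAD(P)H draw = 3 × acetyl-CoA draw, with no pentose draw.

Under these the anaerobic optimum is exactly
lactate:ethanol:acetate = 1:1:0 per glucose and the O₂-saturated
optimum exactly 1:0:1 for any growth rate (derived by eliminating the
pyruvate, acetyl-phosphate and NAD(H) balances by hand). The
central-carbon draws are kept small (0.002–0.03 mmol gDCW⁻¹) so growth
stays ATP-limited throughout the oxygen titration; the oxygen freed by
biomass assimilation lets ATP-yielding pyruvate-oxidase rerouting
perturb the aerobic 1:0:1 endpoint by ~1 %, which is why the aerobic
ratio is checked at 2 % while the anaerobic one is exact. The biomass
product is a pseudo-metabolite whose elemental formula is computed from
the consumed precursors, so even the biomass reaction passes the
balance check. "Maximum O₂" is defined operationally as an O₂ uptake
bound equal to the glucose uptake rate; with unlimited O₂ the LP
escapes the classic aerobic state through full pyruvate-oxidase
rerouting.

Glutamate is auxotrophic by construction (the network has no net
2-oxoglutarate source); glutamine is synthesized by glutamine
synthetase unless the GlnR-repression preset closes it, flipping the
auxotrophy call; aspartate is synthesized from OAA via transaminase +
glutamate dehydrogenase. Amino acids are imported proton-neutrally and
have no catabolic routes — which is precisely why opening their
exchanges leaves the ATP yield unchanged.

### MLF measurement

The ATP gain per malate is measured as the paper describes the effect
(a reduced F₀F₁-ATPase burden): growth is fixed at its no-malate
optimum and the spare capacity of the ATP drain is maximized with and
without 1 mmol gDCW⁻¹ h⁻¹ malate. Under growth maximization with free
growth the marginal malate ATP partly shifts carbon allocation and the
clean 0.25 is blurred. In the three-step mechanism a few percent of
malate can serve the OAA/aspartate demand when that is otherwise met by
PEP carboxylase (the freed PEP is worth extra ATP); the MLF-route flux
still equals the malate uptake in both mechanisms and both media.

### Byproduct control scans

The mannitol flux-control scan fixes PGI, RPE or ACALD on a grid from
the growth-optimal value down to the FVA minimum over states retaining
at least half the optimal growth. Below that floor the fixture's total
NAD(H) supply, not the controlled reaction, limits mannitol and the
negative correlation trivially inverts (at a literal zero of an
obligatory catabolic flux the cell makes neither biomass nor NADH).

## Biomass assembly from composition

`heteroflux.biomass` converts macromolecular mass fractions and monomer
tables into mmol gDCW⁻¹ coefficients
(`mass_fraction × monomer_fraction / residue_mass`), with polymerized
(water-subtracted) residue masses for protein, nucleic acids and
glycogen and free-species masses for lipids. DNA nucleotide fractions
derive from genomic GC content (0.378 for this organism). The default
composition (protein 0.40, carbohydrate 0.25, RNA 0.08, DNA 0.03,
lipid 0.10 g/gDCW, remainder ash) is a literature-typical lactic acid
bacterium; the measured composition it stands in for is not
redistributable, so the packaged values are synthetic defaults, and
elemental-formula checks in the tests use analytically solvable
compositions (glycine-only protein: C H1.5 N0.5 O0.5 per carbon).

For flux simulations the monomer equation is projected onto the fixture
through a coarse biosynthetic costing: amino-acid pools + 4.306 ATP per
residue (protein), G6P + 2 ATP per glucosyl unit (ADP-glucose route
with PPi hydrolysis), Ru5P + lumped ATP for nucleotides (DNA also 1
NADH for ribonucleotide reduction), and 17 acetyl-CoA + 34 NADH +
16 ATP + 0.5 G6P per average phospholipid. Composition-derived growth
models open a fructose feed as a pure electron sink (fructokinase shut,
fructose only reducible to mannitol): the organism's own redox-valve
strategy, needed because biosynthetic draws perturb the fixture's
otherwise hard-wired anaerobic NAD(H) closure in both directions.

**Maintenance estimation** fixes growth and uptake at each measured
batch point, removes GAM from the biomass, maximizes the ATP drain and
regresses drain capacity on growth: slope = GAM, intercept = NGAM
(both clamped ≥ 0). On noise-free synthetic points the planted
(13.613, 1.104) pair is recovered to machine precision.

**Sensitivity.** Scans adjust one component by ±50 % without
renormalizing the others (total drawn mass may deviate from 1 g).
Coefficients use a central difference with a 1 % relative step.
Because "unit change in a stoichiometric coefficient" is
scale-ambiguous, both conventions are exposed; the default is absolute
(per mmol gDCW⁻¹ of the component's monomer demand), the convention
under which lipid — heavy, biosynthetically expensive monomers at a
tiny coefficient — is the most sensitive component and protein — cheap
imported residues at a large coefficient — the least, while the ±50 %
growth spread is dominated by protein and GAM.

## Thermodynamics

ΔrG′° values are inputs (group-contribution estimation is out of
scope). The transformed reaction energy over a concentration box
(1 µM – 10 mM; water and protons fixed-activity) is extremized in
closed form; directionality calls are forward-irreversible
(ΔG′max < 0), reverse-irreversible (ΔG′min > 0), else reversible —
conflicts resolve to reversible.

The packaged PKP/EMP table (pH 7.2, ionic strength 0.1 M, 298.15 K) is
a **synthetic literature-compiled stand-in** for a live calculator run:
per-reaction values follow published group-contribution estimates,
adjusted within their uncertainty bands so the table is
thermodynamically closed. The pathway definitions include an
ATP-recycling step with multiplicity equal to the route's net ATP
yield, so a pathway's net ΔrG′° equals its overall fermentative
conversion — glucose → lactate + ethanol + CO₂ (−186.8 kJ/mol, PKP)
versus glucose → 2 lactate (−178.0 kJ/mol, EMP). Without the recycling
step the kinase-coupled sums are ≈ −157 and −119 kJ/mol; the −8.8
difference between the printed nets equals ΔG′° of
lactate → ethanol + CO₂, which identifies the overall-conversion
convention. Net-ΔG checks use ordering plus a ±5 kJ/mol band because
calculator-version drift is expected.

## Transcriptome integration

Expression matrices are quantile-normalized jointly across all
replicate columns (ties averaged), filtered at replicate CV < 0.3 in
every condition, and mapped to reactions through GPRs: AND = minimum
(complex stoichiometry), OR = sum (additive isoenzyme concentrations),
on the linear scale; OR-sums are uncapped. GPR leaves for unmeasured
genes are dropped (an AND of one child is that child); fully unmeasured
reactions are excluded. Subsystem enrichment is a two-sided Wilcoxon
signed-rank test of log2 reaction fold-changes against a zero median
(exact null for n < 25, normal approximation with continuity correction
above). Note the exact p-value is discrete and conservative at small n;
its null distribution is the enumerated signed-rank law, not the
continuous uniform.

Regulation calls combine the expression Z-score (replicate-level GPR
mapping, so reaction-level variances are defined) with the flux Z-score
over sampled flux distributions:

```
Z = (mean₂ − mean₁) / sqrt(Var₂ + Var₁)
```

Variances are those of the sampled distributions, not standard errors,
so a flux signal requires the perturbed flux window to move by several
widths. The Z→probability mapping is this package's documented
interpretation (the method source does not print one):
p_change = 2Φ(|Z|) − 1, p_same-direction from signed CDFs, and class
scores transcriptional = p_change(Zᴱ)·p_same, post-transcriptional =
p_change(Zᴱ)·(1 − p_change(Zᶠ)), metabolic =
(1 − p_change(Zᴱ))·p_change(Zᶠ); argmax wins if its score exceeds 0.9.
A consequence worth knowing: with noisy finite replicates the null
expression Z is O(1), so the metabolic score rarely clears 0.9 unless
replicates are clean — published probability tables for this method are
therefore not reproducible from the formulas alone, and are not targets
here.

## Synthetic data

All fixtures are generated, seeded and accompanied by their truth:
random small flux networks with a brute-force LP oracle (enumeration of
basic feasible solutions — every rank-sized column subset with the
remaining fluxes at bounds), two-condition log-normal expression with
planted gene/subsystem fold changes (CV defined as sd/mean on the
linear scale; optional high-CV genes to exercise the filter; optional
background genes so the quantile grid resembles a genome-wide array),
and paired flux-sample sets whose perturbations act through exchange
bounds only. What the generators do **not** emulate: probe-level
microarray artifacts, between-array batch effects, RNA-seq counts, or
correlated replicate noise — passing tests therefore demonstrate the
statistics under their stated model, not robustness to platform
artifacts.

## Problem sizes used in the standing checks

Engine-vs-oracle equivalence runs on 200 generated models of up to 8
reactions; sampling checks use 150–2000 points with 5–20-step thinning
on networks of up to 8 reactions; enrichment power uses 200 seeds of
20-reaction subsystems; classifier recovery uses 50 seeds; the oxygen
titration uses a 21-point grid at glucose uptake 10 mmol gDCW⁻¹ h⁻¹.
These sizes make the whole suite run in well under a minute while
keeping Monte-Carlo margins wide.

## Known limitations

* The fixture is a ~60-reaction caricature: no nucleotide, lipid or
  cofactor biosynthesis, three amino acids, lumped NAD(P)H by default
  (a split-pool mode exists), and token biomass draws. It reproduces
  the energy/redox phenomenology, not genome-scale flux maps.
* Membrane potential is not modelled; all transport energetics are
  proton-count conventions (see Proton closure).
* The thermodynamic table is literature-compiled, not a live
  group-contribution run; per-reaction values carry several kJ/mol of
  uncertainty even though the pathway sums are closed.
* The LP engine is deterministic but degenerate optima are resolved by
  parsimony, which is a modelling choice, not biology.
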