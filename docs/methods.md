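# Methods

## Model representation and conventions

A metabolic model is a list of metabolites (id, compartment, optional
elemental formula) and reactions (signed stoichiometry, flux bounds in
mmol g-DW⁻¹ h⁻¹, optional gene association).  Conventions:

* Exchange reactions are written in the secretion direction (`met_e0 →`,
  stoichiometric coefficient −1): positive flux secretes, uptake is a
  negative flux enabled by a negative lower bound, so "fix methane uptake
  at 14.9" means bounds (−14.9, −14.9) on the methane exchange.
* Irreversibility is encoded only through bounds; no reaction is duplicated
  in reverse.
* SEED-style compartment suffixes (`_c0`, `_e0`, `_p0`) are part of the
  metabolite id and are also parsed into the compartment field.
* The biomass reaction is scaled so a flux of 1 equals a specific growth
  rate of 1 h⁻¹.

SBML is written as Level 3 Version 1 with the fbc-v2 package (shared bound
parameters, flux objective, gene products); on reading, fbc bounds are
preferred and legacy Level 2 `LOWER_BOUND`/`UPPER_BOUND` kinetic-law
parameters are accepted.  The tab-separated dialect stores one reaction per
row (`id, name, equation, lower_bound, upper_bound, gene_association,
ec_numbers`); a headerless minimal dialect (`id, equation[, rev|irrev[,
genes]]`) is also read, with the arrow style (`->` vs `<=>`) setting
default bounds (0, 1000) or (−1000, 1000).  Biomass coefficients are
rounded to nine decimals at construction so both formats round-trip
bit-exactly.

## Linear programming

All operations reduce to one solver contract (minimise `c'x` under
equality/inequality constraints and bounds), currently served by scipy's
HiGHS interface with feasibility/optimality tolerances of 1e-9; post-hoc
mass-balance checks use 1e-6.  Flux balance analysis maximises one
reaction's flux at steady state.  Degenerate optima are the norm, so any
reported individual flux comes from parsimonious FBA: each flux is split
into non-negative halves, total |v| is minimised subject to the objective
staying within a relative 1e-6 of the FBA optimum, and tie-breaking among
equal-norm solutions is solver-determined and non-contractual.  Flux
variability analysis reports per-reaction min/max flux at a fraction of the
optimum; a reaction is essential iff forcing it to zero drops the optimum
below 1e-6 of the wild type (the underlying experimental definition —
"no biomass from methane" — is qualitative, so a relative cutoff is used
for numerical robustness).  Pareto sweeps fix a product-secretion level,
maximise the objective, and record the electron-acceptor consumption from
the parsimonious solution; infeasible grid points are flagged, never
dropped, and the default grid is 21 even steps from zero to the product's
stoichiometric maximum.

## The methane-oxidation mechanism variants

The three hypotheses are toggled as bound sets on the same network: the
redox arm opens only the ubiquinol-coupled pMMO with complex III forward;
direct coupling opens only the cytochrome-c-coupled pMMO; uphill electron
transfer opens the ubiquinol-coupled pMMO *and* lets complex III run
backwards, so cytochrome-c electrons can be pushed onto ubiquinone at the
cost of translocated protons.  (Pairing the uphill variant with the
cytochrome-c pMMO instead would make the reverse complex-III flux
purposeless and collapse the variant onto direct coupling, which is why
the ubiquinol pMMO carries the flux here.)  Electron bookkeeping then
orders the predicted yields redox arm < uphill < direct coupling: per CH₄
activated, the redox arm forgoes the proton translocation of complexes
I+III+IV downstream of one NADH, uphill forgoes complex IV's pumping plus
the protons spent on reverse complex III, and direct coupling forgoes only
complex IV's pumping.

In the redox-arm variant the O₂/CH₄ ratio of 1.5 is structural: one O₂ is
consumed by pMMO itself and the two cytochrome-c electrons that methanol
dehydrogenase produces per methanol have no sink but complex IV (0.5 O₂)
whenever complex III is idle at the optimum.  This is exactly the measured
ratio, which is part of why the yield data identify this mechanism.

## The core fixture model

The packaged model (74 reactions, 67 metabolites, compartments c0/e0 plus a
periplasmic pseudo-compartment for the translocated proton) contains: both
pMMO stoichiometries; methanol → formaldehyde (cytochrome-c-coupled),
formaldehyde → formate → CO₂ (NAD-coupled) and formaldehyde condensation
onto tetrahydrofolate; the serine cycle (serine hydroxymethyltransferase,
serine-glyoxylate aminotransferase, hydroxypyruvate reductase, glycerate
kinase + enolase lumped, PEP carboxylase, malate dehydrogenase, malate
thiokinase, malyl-CoA lyase); glycine synthase (CO₂ + methylene-THF + NH₄⁺
+ NADH → glycine); PHB synthesis (thiolase, synthesis-directed
acetoacetyl-CoA reductase, PHB synthase) and a lumped depolymerase/ligase
entry (PHB monomer + CoA + ATP → 3-hydroxybutyryl-CoA) whose flux is the
reported "PHB degradation" rate; the ethylmalonyl-CoA-type degradation
route, with the interior steps (crotonase through mesaconyl-CoA hydratase)
lumped into one desk-scale reaction ending at l-erythro-3-methylmalyl-CoA,
cleaved by the same malyl-CoA lyase into glyoxylate + propionyl-CoA;
propionyl-CoA carboxylation to succinyl-CoA (lumped); an oxidative
mobilisation branch (thioesterase → free 3-hydroxybutyrate → acetoacetate →
succinyl-CoA:acetoacetate CoA-transferase → thiolysis) that honestly
forfeits the CoA-activation ATP; the TCA cycle; a glycerate pathway
(glyoxylate carboligase + tartronate-semialdehyde reductase); a
serine-deaminating transaminase shuttle (serine-pyruvate aminotransferase +
alanine dehydrogenase); pyruvate oxidase (quinone-linked) and
phosphotransacetylase/acetate kinase for acetate, and the
acetolactate route for butane-2,3-diol; a four-step denitrification chain
(nitrate → nitrite → NO → N₂O → N₂); and exchanges for CH₄, O₂, CO₂, NH₄⁺,
NO₃⁻, N₂, acetate, butane-2,3-diol, water, protons, a PHB storage boundary
and biomass.

Two deliberate topology choices shape the fixture's predictions.  First,
there is no pyruvate dehydrogenase: acetyl-CoA on methane can only come
from malyl-CoA lyase, which keeps that enzyme strictly essential for
growth on methane (with a pyruvate → acetyl-CoA link, the C1 → glycine →
serine → pyruvate chain would bypass it).  Pyruvate oxidase plus acetate
kinase cover the acetate chemistry without re-creating that bypass, since
secreted acetate cannot be re-activated.  Second, the oxidative
mobilisation branch re-enters through free 3-hydroxybutyrate rather than
by reversing the synthesis reductase, reflecting the distinct degradative
enzymes, and pays the activation ATP — which is what commits co-consumed
PHB to the ethylmalonyl route at the optimum while still permitting
complete anoxic oxidation of PHB to CO₂.

### Electron and proton accounting

Reduced carriers carry their electrons as hydrogen in the elemental
formulas (ubiquinol = ubiquinone + 2H, reduced cytochrome c = oxidised +
H), which lets a single C/H/O/N/P/S bookkeeping check certify every
non-exchange, non-biomass reaction.  Proton translocation is explicit:
complexes I/III/IV pump 4/2/4 protons per NADH-equivalent into a dedicated
periplasmic proton species, and the ATP synthase consumes 20 /
(target ATP per O₂) of them per ATP — 4 at the default target of 5 ATP per
O₂, i.e. 2.5 ATP per NADH.  Because the translocated proton is a separate
species, proton-motive force cannot short-circuit through the free
cytosolic proton pool.

### Biomass calibration

The biomass reaction drains acetyl-CoA, serine, α-ketoglutarate and
oxaloacetate in fixed proportions (3.0 : 1.5 : 1.1 : 1.8 mmol per g DW
before scaling) plus ammonium, net biosynthetic NADH and growth-associated
ATP (40 mmol/g DW).  A single multiplier on the carbon precursors was tuned
once (scripts/calibrate_biomass.py, bisection on the redox-arm optimum) so
that growth at methane uptake 14.9 and maintenance 3.5 gives
μ = 0.107 h⁻¹; the O₂/CH₄ ratio of 1.5 then follows structurally.  The
calibrated value (carbon scale 3.598252) implies a biomass that is denser
in carbon and electrons than textbook biomass composition — this is not a
free choice: a degree-of-reduction balance over the exchanges shows that
the measured yield (7.2 g-DW/mol CH₄) and ratio (1.5 mol O₂/mol CH₄) are
jointly attainable only with an electron-dense biomass, so the fixture
inherits that property from the measurements it is anchored to.  Only the
carbon scale is binding at the reference optimum; energy (ATP) is in
surplus there, which is why the growth-associated ATP value is not a
sensitive parameter.

### Degeneracy and reported flux patterns

The fixture's optima are heavily degenerate: the formaldehyde branch point
(assimilate vs oxidise) locks the relative shadow prices of carbon and
reducing power, making many route combinations exactly equivalent in
yield.  All reported flux patterns therefore come from parsimonious FBA.
The anaplerosis comparison (growth on methane alone vs methane + PHB) is
run at specific rates — methane 14.9 vs 13.2 mmol g-DW⁻¹ h⁻¹ with PHB
degradation fixed at 0.608, maintenance 3.5 in both — where the
parsimonious optimum shows the expected displacement: glycine synthase
falls from 1.69 to 0.91 mmol g-DW⁻¹ h⁻¹, l-erythro-3-methylmalyl-CoA lysis
rises from zero to exactly the PHB degradation rate, and propionyl-CoA
carboxylation to succinyl-CoA switches on.  The bottle-scale co-consumption
prediction instead feeds the measured totals (1.8 mmol CH₄, 0.083 mmol PHB
per bottle) directly as flux-scale quantities — valid because the LP is
linear and time-invariant — and excludes maintenance by default, since how
maintenance should be charged over the 15 h incubation is not determined by
the data; a flag charges maintenance × duration × trapezoidal mean biomass
as a sensitivity run.  On the fixture this predicts 18.3 mg biomass and
2.70 mmol O₂ per bottle against measured 21 ± 3 mg and 2.6 ± 0.13 mmol (the
O₂ prediction is pinned by the structural 1.5 ratio).

## Anoxic PHB and denitrification

With oxygen and methane shut off and PHB degradation forced, every
catabolic route generates quinol or NADH that only the denitrification
chain can re-oxidise; with nitrate closed the constraint set is infeasible,
which the scenario reports as zero ATP — the model-level statement that PHB
cannot be fermented.  With nitrate open, maintenance-ATP maximisation
couples PHB oxidation to denitrification (9.7 mol ATP per mol PHB on the
fixture, at 3.6 mol nitrate); forcing acetate or butane-2,3-diol secretion
monotonically lowers both the attainable ATP and the nitrate demand, which
is why product secretion is interpreted as overflow when PHB mobilisation
outruns the denitrification capacity.

## Topology statistics

A metabolite's degree is the number of reactions it participates in
(optionally restricted to reactions that can carry flux at the growth
optimum, via flux variability at fraction 1).  The power-law fit is
ordinary least squares on (log₁₀ k, log₁₀ n(k)) over all degrees with
n(k) ≥ 1 after excluding metabolites above the 99th percentile of the
degree distribution — highly connected co-factors (ATP, NADH, water,
protons) sit above the power law; a percentile rule makes the exclusion
reproducible.  The fit is invariant to the logarithm base.  On desk-scale
networks (the 74-reaction fixture) the fitted slope is necessarily
shallower than on genome-scale models; the slope test therefore uses the
scale-free generator, which samples metabolite degrees directly from
P(k) ∝ k^(−γ) (truncated at k = 60) so the generating exponent is well
defined, and checks that the fitted slope recovers γ = 2.5 within ±0.2
averaged over 20 seeds at 1500 metabolites.

Model comparison matches reactions by a canonical stoichiometric signature
(sorted coefficient multiset over compartment-stripped metabolite ids,
direction-invariant), because independently reconstructed models spell ids
differently; exact-id matching is reported as a fallback.

## Random networks

The "pathway" generator used for LP cross-checks builds a connected network
from a spanning conversion chain plus random mass-conserving conversions
(each internal reaction's coefficients sum to zero, so the all-ones vector
certifies stoichiometric consistency), one source and one sink exchange,
and random bounds; it is deterministic per seed.  The brute-force oracle in
the test suite enumerates candidate vertices of {S v = 0, lb ≤ v ≤ ub} by
fixing every (n − rank S)-subset of variables at a bound and solving the
residual linear system — independent of the HiGHS path it checks.

## What the fixture does and does not show

The fixture reproduces the measured growth anchors, the mechanism
discrimination, the anaplerotic displacement pattern and the anoxic
denitrification coupling, and it exercises every pipeline stage.  It does
not reproduce genome-scale statistics (reaction/metabolite/essential
counts, the −2.5 degree slope); those are properties of the deposited
genome-scale reconstruction, which the scenario code accepts via SBML plus
a reaction-id map.  Passing tests on the fixture demonstrate the
correctness of the machinery and the qualitative physiology, not the
numerical detail of any genome-scale model.

## Known limitations

* Single NAD(H) pool: NADPH-specific cofactor usage is not distinguished,
  so cofactor-specificity effects on pathway choice are not modelled.
* No dynamic (time-course) bottle simulation, no gas–liquid transfer; the
  totals-mode co-consumption relies on linearity alone.
* No thermodynamic or loopless constraints beyond parsimonious FBA's
  practical suppression of futile cycles; no MILP (gene-level knockouts via
  boolean compilation are out of scope — essentiality is reaction-level).
* The lumped reactions (glycerate kinase + enolase, ethylmalonyl interior,
  propionyl-CoA carboxylase + mutase, transaminase shuttles) are
  stoichiometrically faithful in C/H/O/N/P/S but hide intermediate-level
  regulation and per-step flux detail.
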