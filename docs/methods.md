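# Methods

## Scope and units

The package reconciles steady-state chemostat measurements of glucose-grown
*P. putida* KT2440 with a constraint-based metabolic model. Package-wide
conventions: fluxes in mmol · g_DCW⁻¹ · h⁻¹, growth rates in h⁻¹, yields in
g_DCW · g_glc⁻¹, concentrations in g · L⁻¹ (glucose feeds in mmol · L⁻¹).
The biomass reaction flux numerically equals the specific growth rate mu.
Glucose molar mass defaults to 180.16 g · mol⁻¹ and is configurable
everywhere it enters a conversion.

## Chemostat analytics

At steady state the dilution rate D fixes mu = D. Per record the module
computes R_x = D · C_x, R_glc = D · (feed − residual) · M_glc / 1000,
q_s = R_glc / C_x and Y_x/s = R_x / R_glc (so Y_x/s = D / q_s identically).
CO₂ production is derived from the in/out mole-fraction difference of the
gas stream via the ideal gas law at the record's temperature and pressure,
normalized per liter of culture (0.75 L default, matching the bioreactor
working volume; air flow 0.75 L · min⁻¹).

Dry weight comes from two routes: an OD₆₀₀ calibration forced through the
origin (default slope 0.35 g · L⁻¹ per OD unit; the regression has no
intercept term because the calibration law has none), and direct filtration
corrected by a filter blank (0.356 g · L⁻¹) and a culture factor
(0.35/0.399). When both measurements are present their unweighted mean is
used. Corrections are applied per measurement, before any averaging.

The Pirt fit is ordinary least squares of q_s on D: Y_x/s^max is the
inverse slope, m_s the intercept. A non-positive slope is an error — it
signals the culture was not substrate-limited. Washout fitting is
log-linear least squares of ln C_x on t (mu_max = slope + D): the stated
decay law is exactly linear in logs, and the linearization keeps the
estimator deterministic and closed-form. Monod-type residual-substrate
modeling is deliberately excluded; the residual-glucose/D relationship in
this organism is not Monod-like.

Carbon balance: (glucose carbon in − CO₂ carbon out) / R_x per record,
averaged; nitrogen balance: consumed ammonium-N / C_x, averaged.

## Biomass equation

For each macromolecule class with mass fraction f and monomer mol
fractions x_i of residue mass M_i, monomer coefficients are
c_i = f · 1000 · x_i / Σ_j x_j M_j (mmol · g_DCW⁻¹), which makes each
class contribute exactly f grams. Residue masses are always computed from
elemental formulas (water-loss-corrected polymer residues), so
formula/mass consistency holds by construction. The assembled equation
must draw 1.000000 g from the network per unit flux (checked to 1e-6).

Composition closure. The measured fractions (soluble protein 52.8%,
lipid 8.4%, carbohydrate 2.1%, RNA 22.6%, DNA 2.2%) plus the
insoluble-protein increment (+12.2 percentage points, membrane proteins
invisible to the soluble assay) plus assumed peptidoglycan (8.6%) sum to
roughly 109% — over-closure is a real feature of these data. Three closure
policies are provided:

- `pinned` (default): peptidoglycan and a small cofactor pool (0.5%)
  keep their stated shares; measured fractions (with the protein
  increment) are scaled proportionally into the remaining 91%-ish of mass.
  This keeps the assumed peptidoglycan share exact while closing to 1 g.
- `proportional`: everything rescaled uniformly.
- `remainder`: fractions kept as-is, remaining mass to the cofactor pool;
  available for compositions that sum below 1, an error otherwise.

Whether the protein assay total already includes the insoluble increment
is ambiguous in the source data; `add_insoluble_protein` exposes both
readings (default: add the increment to the soluble measurement).

Monomer composition choices:

- Protein: measured amino-acid mol% at D = 0.2 h⁻¹; Cys/Met/Trp are not
  quantified by the ninhydrin assay and are filled in at *E. coli*
  reference mol% (1.7 / 2.9 / 1.1), then the profile is renormalized to
  100%. Fill-in never overwrites a measured entry (idempotent). The
  unresolved Asx/Glx pools are split 50:50 into acid/amide residues.
- DNA: paired-base model from GC content (default 0.615, genome-derived
  reference, overridable) or counted directly from a genome FASTA.
- RNA: *E. coli* base composition at D = 0.6 h⁻¹ (reference-derived).
- Lipids: phospholipid head groups at the *P. putida* S12 measurement
  (PE 73.7%, CL 21.3%, PG 4.9%; printed percentages summing to 99.9% are
  renormalized); each species is its de-acylated backbone plus a
  fatty-acid-profile-averaged acyl residue (2 chains, 4 for cardiolipin),
  giving averaged species with fractional elemental formulas. LPS enters
  as a single *E. coli*-type aggregate (lipid A + core oligosaccharide,
  CDP-ethanolamine moiety removed; synthetic approximate formula) at
  0.034 g/g_DCW taken out of the lipid fraction.
- Carbohydrates: entirely glycogen (anhydroglucose residues).
- Peptidoglycan: GlcNAc-MurNAc-tetrapeptide repeat unit.
- Cofactor pool: five representative species (NAD, CoA, FAD, THF, PLP)
  splitting a negligible mass share equally; their inclusion matters for
  essentiality predictions, not yields.

Polymerization energy is not itemized per bond; it is lumped into the
single fitted GAM term. GAM enters the equation as the element- and
mass-neutral hydrolysis quartet ATP + H₂O → ADP + Pi, so the elemental
composition (net consumed minus produced elements per 1 g) is unaffected
by GAM. On the default inputs the assembled biomass is C 49.0%, H 6.3%,
N 15.2%, O 26.3%, P 2.5%, S 0.8% (computed, not asserted as data).

## Maintenance

Predicted Y_x/s^max is the inverse slope of minimal glucose demand
q_glc(mu) between mu = 0.1 and 0.5 h⁻¹ (two FBA solves, minimizing
uptake at fixed growth). The two-point slope cancels the NGAM offset by
construction, keeping the GAM fit separable from NGAM. GAM is fitted by
bisection on [0, 1000] mmol · g⁻¹ (≤ 60 iterations, relative tolerance
1e-4); yield is strictly decreasing and continuous in GAM, so bisection
converges. A GAM at which the probe growth rates are unreachable under the
uptake cap counts as yield 0. NGAM = m_s · (1000 / M_glc) · Y_ATP; with
m_s = 0.037 and Y_ATP = 19.25 this gives 3.95, matching the published
3.96 within the 0.5% molar-mass convention band. Y_ATP on a model is
computed by maximizing the ATP-drain flux at unit glucose uptake and zero
biomass; on the toy network it equals 4 + 12 · P:O exactly.

## FVA distance

"Square distance" is implemented as the sum of per-reaction squared
distances to the nearest (d_min) and farthest (d_max) interval endpoint —
the simplest reading consistent with summed minimal and maximal distances,
stated here prominently because no formula is published. Unbounded
intervals contribute infinity to d_max and the offending reactions are
listed. Measured fluxes are aligned to model reactions through an explicit
mapping table with a sign column (measurement conventions may run
reactions backwards); unmapped measurements are reported, never silently
dropped. SD-weighting (dividing each squared term by the measurement
variance) is available by flag; unnormalized sums are the default since no
normalization is documented for the original distances.

## Transcriptome consistency

A gene is "potentially not expressed" if any of: > 2 absent calls out of
4, < 3 present calls out of 4, or mean log₂ expression < 7.5. Marginal
calls count as neither present nor absent. Reaction-level expression
aggregates gene means over the GPR: OR (isozymes) → max, AND (complex) →
min, so an isozyme reaction is flagged only when every isozyme is low.
"Forced" reactions are those with minimal |flux| > 1e-9 in FVA (the
epsilon is reported); "idle" reactions have maximal |flux| below
0.1 mmol · g_DCW⁻¹ · h⁻¹ with the reference growth rate at 0.2 h⁻¹.
Absolute values make reversible reactions symmetric. The high-expression
cutoff for the third assessment has no published numeric value; it
defaults to the dataset grand mean and is always echoed in reports as an
explicit threshold.

## Toy network and generators

The toy network fixes ~16–19 reactions: glucose exchange and transport
(two-subunit complex), hexokinase, lumped EMP glycolysis (isozyme pair,
net +2 ATP and 2 NADH per glucose after the hexokinase), pyruvate
dehydrogenase (complex), lumped TCA (1 ATP, 3 NADH, 1 FADH₂ per
acetyl-CoA), respiration at P:O ATP per ½ O₂ for both NADH and FADH₂, an
ATP-maintenance drain, and a biomass reaction. An optional periplasmic
branch (glucose → gluconate → 6-phosphogluconate → Entner–Doudoroff)
mirrors the organism's glucose-side oxidation loop; it is ATP-inferior by
one substrate-level phosphorylation, so it never changes optima but opens
genuine flux variability for FVA tests. Free phosphate is not tracked:
lumped glycolysis cannot balance a Pi pool without re-introducing every
phosphorylated intermediate, so the ATP/ADP couple carries the energy
bookkeeping alone.

The toy biomass consumes glucose-6-phosphate at the carbon density of the
full biomass equation (elemental carbon per gram / 6 ≈ 6.79 mmol · g⁻¹)
plus the GAM quartet. This preserves the carbon balance
(glucose C = biomass C + CO₂ C exactly at optimum) and yields the
closed-form maximal yield
Y(GAM, P:O) = 1000 / (M_glc · (n + (n + GAM)/(4 + 12 · P:O))) used as the
independent oracle in tests. Lumping means the toy cannot probe
monomer-level essentiality (e.g. amino-acid auxotrophies) — its
essentiality structure covers transport, glycolysis, oxidation and
respiration only.

Generator defaults are the study conditions: Y_x/s^max = 0.397,
m_s = 0.037, mu_max = 0.59 (washout at D = 1.2 from 10 time points over
3 h), dilution rates 0.05–0.5 h⁻¹, 10 mM glucose feed, biomass carbon
fraction 0.488 closing the off-gas CO₂ balance, GAM 85, NGAM 3.96,
P:O 1.33, four expression arrays. Noise is multiplicative log-normal on
concentration channels (positivity) and additive Gaussian on log₂
expression and measured fluxes; sigma = 0 makes every downstream estimator
exact, which is what the round-trip tests exercise. Planted expression
signals use well-separated distributions (background N(9, 0.5) with P
calls; not-expressed N(6.5, 0.3) with A calls; high N(11, 0.3)), so
noise-free recovery is exact by design. What passing these tests shows is
that the estimators and rules are implemented correctly — not that they
are robust to the failure modes of real data (probe cross-hybridization,
drifting baselines, correlated measurement error, model misspecification),
which the generators deliberately do not emulate.

## Numerical choices

LPs are solved with HiGHS (scipy.optimize.linprog) at feasibility/
optimality tolerance 1e-9; assertions on solutions use 1e-6. Alternate
optima are expected in underdetermined networks: objective values and FVA
intervals are contract-stable, individual FBA flux vectors are not, and
tests never assert non-unique fluxes. Gene deletions zero the bounds of
reactions whose GPR evaluates inactive; empty-GPR (spontaneous) reactions
are never affected. Infeasibility and unboundedness are reported through
an explicit status field, never silently. FVA fixes the objective flux at
the stated value and solves two LPs per reaction; whether the growth rate
or the glucose uptake is held fixed during comparisons is a genuine
degree of freedom (the original analysis does not state it), so both are
expressible by fixing the corresponding reactions.

## Pipeline

`run_pipeline` chains the stages (growth → biomass → maintenance → FVA
concordance → omics) and writes `report.json` (schema version, package
version, seed, every threshold actually used, SHA256 of every input),
`params.json`, `fva.tsv` and `omics_report.tsv`. Any stage failure aborts
with a stage-tagged error. Reruns on identical inputs are byte-identical
apart from output paths.

## Known limitations

- Genome-scale magnitudes (a GAM fitted on the full reconstruction of the
  organism, FVA-distances in the thousands, essential-gene counts in the
  hundreds) require the external genome-scale model file and the original
  microarray data and are out of scope; the toy network validates the
  procedures, not those magnitudes.
- The LPS and peptidoglycan species, fill-in amino-acid fractions, RNA
  base composition and fatty-acid profile are reference-derived defaults,
  clearly marked, and should be replaced with organism-specific
  measurements when available.
- Fractional-formula (averaged) lipid species cannot be exported as SBML
  chemical formulas; stoichiometry, bounds, GPRs and objectives round-trip
  losslessly.
- No thermodynamic constraints, loopless FVA or parsimonious FBA.
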