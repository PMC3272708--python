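# Methods

## The model class and its assumptions

`snfba` treats a bacteroid as a two-compartment (cytosol `[c]`,
extracellular `[e]`) stoichiometric network at pseudo-steady state. FBA
solves the LP `max c·v` subject to `S v = 0` and per-reaction bounds in
mmol/gDW/hr. Reversibility is an input property (lower bound < 0), never
inferred thermodynamically. Exchange reactions are single-metabolite
boundary reactions `M[e] ->`; uptake is negative flux. No mass/charge
balancing is enforced (formulas are optional annotations).

### The coupled SNF objective

Because bacteroids are non-dividing, the objective is not biomass but the
nutrient-sharing pseudo-reaction, which consumes cytosolic alanine,
aspartate, arginine, glycogen, hexadecanoate and pool ammonia (1 each) plus
0.01 units of an assembled cofactor pool, and produces extracellular
alanine, aspartate and ammonia. Nitrogenase carries its conventional
printed stoichiometry (16 ATP, 6 reduced ferredoxin, 16 H2O, 1 N2 in;
16 ADP, 6 oxidised ferredoxin, 8 H+, 2 NH3, 16 Pi out). Two notes:

- As printed, 6 ferredoxin electrons accompany an 8-electron reduction
  (2 NH3 + 8 H). The coefficients are used verbatim; the package does not
  rebalance them.
- Coupling is structural ("pool" mode): nitrogenase is the sole producer
  of the dedicated species `nh3fix[c]` and the sharing reaction consumes
  it 1:1, so exported ammonia ≤ 2 × nitrogenase flux in *every* feasible
  point. A weighted-sum mode (default 1:1 over both reactions) is provided
  for comparison; because surplus fixation can be vented through the
  assimilation valve (below), the two modes genuinely diverge on the toy
  network, and reports flag rather than reconcile this.

The cofactor pool combines eight components equimolarly (heme, FeS
cluster, molybdate, homocitrate, pyridoxine, adenosylcobalamin, thiamine,
glutathione). Equimolarity is the minimal assumption — no stoichiometry is
published for the pool — and is configurable via `ObjectiveSpec`. Because
the pool is an AND over components, losing any single biosynthesis branch
drives the objective to zero.

### The symbiotic medium

`data/snf_medium.yaml` fixes the microaerobic nutrient-sharing habitat:
malate −1.112 **or** succinate −1.326 (mutually exclusive via
`carbon_source`), oxygen −1.26, inositol −0.01 mmol/gDW/hr, glutamate free
in both directions (−1000, 1000), amino-acid/ammonia export open, mineral
exchanges open. Homocitrate — plant-supplied in rhizobia lacking
homocitrate synthase — has no published rate; it is capped at −0.01, the
same order as the inositol sink, as a trace plant-supplied compound. Under
`glutamate_only` both C4 exchanges are closed and glutamate is the sole
carbon and nitrogen source.

## Numerical choices

- LP solver: `scipy.optimize.linprog` (HiGHS); feasibility/optimality
  tolerances 1e-9, configurable per call.
- Pathway-activity threshold epsilon = 1e-6 mmol/gDW/hr — far above LP
  tolerance, far below any meaningful flux.
- Activity calls always use flux variability at objective fraction 1.0
  (with a 1e-9-scaled slack on the optimum constraint), never a single
  flux vector: alternate optima would otherwise make the calls
  solver-dependent. Blocked-reaction detection is FVA at fraction 0.
- Essentiality threshold: deletion/wild-type ratio < 0.01. The screen is
  binary; 1% separates numerically-abolished from reduced-but-viable and
  is exposed as a parameter for sensitivity analysis. Deletions that make
  the LP infeasible count as objective 0.
- GPR grammar: `and` binds tighter than `or`; parentheses override;
  deletion is binary (no dosage effects).
- RBH thresholds are strict inequalities exactly as printed (E < 1e-6,
  identity > 30%, coverage > 60%); "matched length" is interpreted as
  alignment length / *query* length (subject-basis is a parameter). Best
  hit = lowest E-value, ties by higher bitscore, then lexicographic
  subject id, which makes the filter deterministic.
- SBML: written as L3V1 + fbc v2 (bounds as shared parameters, GPRs as
  gene-product associations, subsystem/kind in notes); read accepts both
  that dialect and the legacy pre-fbc COBRA conventions (notes-encoded
  GENE_ASSOCIATION, kinetic-law LOWER_BOUND/UPPER_BOUND/
  OBJECTIVE_COEFFICIENT), so 2012-era published supplements load
  unchanged. Native metabolite ids carry `[c]`/`[e]`; the SBML compartment
  attribute is authoritative on read and suffixes are regenerated.
  Where an input gives no bounds: (−1000, 1000) reversible, (0, 1000)
  irreversible.

## What the synthetic generator emulates — and what it does not

`generate_toy_snf_model` builds a ~70-reaction bacteroid with a known
answer to every question the pipeline asks: C4-dicarboxylate and glutamate
import, an 8-reaction TCA loop, gluconeogenesis entered through a
single-gene malic enzyme, a 2-reaction oxidative PPP proxy (sole NADPH
source) with a lumped non-oxidative pentose return, oxygen-capped
respiration (P/O = 2) as sole ATP source, an NADH→ferredoxin reductase,
nitrogenase gated by a three-gene AND complex, transaminase-based
amino-acid cycling, one single-gene branch per cofactor, and optional
glyoxylate-shunt and PHB-cycle branches plus optional isozyme OR-pairs.
Topology is deterministic given the flags; the seed only shuffles list
order and decoy parameters, so the ground-truth labels (33 essential / 16
non-essential genes by default) follow from construction: a gene is
essential iff it gates the only route to something the sharing reaction
consumes.

Deliberate simplifications, and why:

- **Glutamate transporter capacity ±0.5 mmol/gDW/hr.** With unbounded
  glutamate the optimum is purely oxygen-limited and carbon is free, which
  creates degenerate optima in which wasteful routes (glyoxylate shunt,
  PHB cycle) can carry flux; a finite amino-donor supply keeps the optimum
  carbon-limited, where any waste of carbon or reducing power is strictly
  suboptimal and the shunt/PHB inactivity calls are robust. The *medium*
  still leaves the glutamate exchange unconstrained — the cap is an
  enzyme-capacity bound.
- **ATP-neutral succinyl-CoA synthetase** (GTP pool untracked), so
  oxidative phosphorylation is provably the sole ATP source and the
  respiration-complex genes have a derivable essentiality label.
- **Fixed-ammonia assimilation valve** (`nh3fix -> nh3`, a glutamine-
  synthetase stand-in) and a spontaneous ammonium-efflux diffusion. Without
  the efflux, every glutamate deamination would strand one nitrogen and
  glutamate could not act as sole carbon source; without the assimilation
  valve the network could never synthesise net glutamate and the
  surplus-carbon efflux behaviour would be unreachable. Exported-ammonia
  provenance is unaffected: the sharing reaction still draws only on the
  nitrogenase pool.
- **Cobalamin branch consumes magnesium** as a stand-in divalent metal
  (cobalt is not modelled), giving the magnesium exchange a consumer.
- Sizes and rates are those of the stated habitat (malate 1.112, oxygen
  1.26, inositol 0.01); nothing in the generator is tuned to test
  outcomes.

A green test on this network therefore establishes that each algorithm
recovers a provably correct answer on a realistic topology; it does not
establish genome-scale performance, atom-balanced stoichiometry, or the
published model's quantitative flux values — for those, load the published
SBML supplement and re-run the same pipeline.

`generate_tiny_model` emits ≤8-reaction random chain/branch models with
finite bounds whose optimum is checked against an independent brute-force
vertex-enumeration oracle. `generate_hit_tables` plants reciprocal best
hits among decoys each violating exactly one criterion (including decoys
sitting exactly on the strict 30%/60% boundaries).

## Degenerate inputs and error behaviour

Infeasible and unbounded LPs return a status, not an exception; validation
violations are returned as data naming the entity and rule; unknown gene
ids in deletion sets, unknown exchange ids in media, missing species in
objective builders, and malformed hit-table rows raise errors naming the
offender (and line number for tables). The pipeline raises a diagnostic
error listing closed exchanges and dead ends when the wild type cannot fix
nitrogen.

## Known limitations

- No thermodynamic reversibility inference, no mass/charge balancing, no
  double-deletion screens, no parsimonious or dynamic FBA.
- Annotation refinement is reported (gap × RBH-candidate join), never
  applied automatically: real refinements need literature evidence.
- The published genome-scale reconstruction is consumed, never re-derived;
  its headline numbers can only be reproduced with the journal
  supplement present (`data/iHZ565.xml`), which this repository cannot
  redistribute.
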