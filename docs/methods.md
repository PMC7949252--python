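# Methods

## Model and scope

gapsmith reconstructs constraint-based metabolic models in a
two-compartment world: cytosol (`c0`) and extracellular space (`e0`).
Transport reactions span both; a periplasm is deliberately omitted
because every algorithm implemented here (pathway calling, draft
assembly, LP gap-filling, flux simulation) is insensitive to it, and the
smallest sufficient compartment model keeps the fixtures auditable.
Exchange reactions follow the dominant constraint-based convention:
`EX_<met>` with stoichiometry {met: −1}, uptake negative, secretion
positive. Unbounded reactions get ±1000 mmol·gDW⁻¹·h⁻¹ (configurable);
flux balance assumes steady state, S·v = 0.

## Evidence reduction

Homology hits carry bitscore, reference coverage and identity. The
binary *match* call uses bitscore ≥ 200 and coverage ≥ 75% (defaults),
plus optional per-reaction exception criteria (e.g. minimum identity).
The per-reaction evidence score b used for gap-filling weights is the
**maximum bitscore over all hits, irrespective of coverage**: coverage
gates only the binary call. The alternative (coverage-filtered maxima)
was considered; since the weight mapping is defined purely on "the
reaction's highest bitscore", the unfiltered maximum is used and the
match cutoffs stay where they belong, in the presence call. A reference
sequence mapping to several reactions contributes its score to each.

## Protein complexes

Subunit labels are text-mined from reference FASTA headers after the
keywords *subunit*, *chain*, *polypeptide*, *component* (first keyword
occurrence wins, case-insensitive). Roman numerals I–XX, greek letters
(spelled or unicode), letters A–H and arabic numbers map to one arabic
canonical form. Two noise filters apply **in this order**: labels seen
fewer than 5 times are demoted to "undefined subunit", then a label
covering ≥ 66% of the remaining labelled entries demotes all others.
The order matters only in corner cases; this order is stable when
unlabelled noise is added, which is why it was chosen. A complex is
present when more than half of its recognised subunits have a passing
hit; at exactly one half, a passing hit in the undefined pool tips the
balance — undefined entries that merely exist without a passing hit do
not, since tipping requires positive signal.

## Pathway presence

Statuses per pathway member: spontaneous members are always present;
members without reference sequences are *vague*; otherwise found iff
matched. Completeness is f/(n−v) while vague members are strictly fewer
than ⅓ of the pathway, else f/n — i.e. vague reactions are excluded
from the denominator, not counted as found, because counting them as
found would inflate completeness beyond what homology supports. A
pathway is present at completeness ≥ 0.8, or ≥ ⅔ when it has key
reactions and all of them have status *found* (a vague key does not
qualify: keys are the positive signal that justifies the relaxed
cutoff).

## Draft assembly and provenance

Inclusion rules stamp `gs_origin`: 0 direct match (including selected
transporters and spontaneous reactions), 6 biomass, 7 exchange, 8
diffusion (H₂, O₂, CO₂, H₂O, NH₃ by default — membrane crossing without
an enzyme), 9 pathway completion. When several rules apply the lowest
code wins. Codes 1–4 mark the four gap-filling steps; 5 is reserved and
10 (manual post-hoc curation) is out of scope. Diffusion carriers are
also part of the universal model, for the same reason they are part of
every draft: they need no genetic evidence.

GPR expressions are assembled from passing hits: one pseudo-gene per
passing reference sequence, OR-joined; for complexes, AND across
recognised subunit labels with OR inside a label. This construction is
the package's own design (no canonical rule exists for hits → GPR) and
is what makes the essentiality screen exercisable end to end.

Gram staining selects between two biomass templates (they differ in the
cell-envelope component); it is a required parameter with default
"negative" rather than an inferred property — a 16S-based classifier
would drag in external reference data without touching any algorithm
tested here. A hook for plugging one in is the `gram` argument itself.

## The gap-filling LP

One LP per objective, derived from parsimonious FBA:

max v_obj − c·Σᵢ wᵢ|vᵢ|, s.t. S·v = 0, lb ≤ v ≤ ub, with

- wᵢ = w_min (0.005) if i is in the draft or bᵢ ≥ u (200),
- wᵢ = (bᵢ − u)·(w_min − w_max)/(u − l) + w_min for l ≤ bᵢ < u,
- wᵢ = w_max (100) if bᵢ < l (50) or i has no evidence,
- c = 0.001.

|vᵢ| is linearised with nonnegative split variables v⁺, v⁻ whose bounds
also encode one-sided flux bounds (so forced fluxes survive the split).
Complementarity is not imposed; with strictly positive weights the
optimum never carries both split parts. Reactions outside the draft with
|v| > 10⁻⁶ (the global flux tolerance; the value is a numerical choice,
exposed in `GapfillParams`) are added. The weighted sum runs over **all**
reactions including exchanges and biomass; an `exempt_exchanges` flag
exists for sensitivity analysis. Variables are ordered lexicographically
by reaction id and solved with HiGHS, so results are deterministic.

Degenerate alternate optima are possible in principle; tests assert
solution *properties* (growth restored, weight of the added set) except
on fixtures constructed to have unique optima.

## Four-step protocol

Step 1 gap-fills the biomass objective on the user's growth medium
(complete medium when none is given) over the full universal reaction
set. Steps 2–4 are restricted to *core* reactions — best bitscore
strictly above 50 — so that specific capabilities are only completed
when genomic evidence exists, which also decouples the final model from
the particular gap-filling medium. Exchange reactions are
medium-controlled, not evidence-gated, so they remain eligible in the
restricted steps (and are stamped with the exchange code when added).

Step 2 re-constrains to an M9-like minimal medium (minerals, ammonia,
phosphate, CO₂; glucose as default carbon source when an exchange
exists) and maximises a temporary sink for one biomass component at a
time, twice — with and without oxygen; the sink is removed afterwards.
Components that would require any non-core reaction stay unresolved and
are flagged. Step 3 inserts three temporary recycling reactions
(menaquinol→menaquinone+2H⁺, quinol→quinone+2H⁺, NADH→NAD⁺+H⁺), plus a
pseudo-metabolite pool and drain so a single LP objective equals their
summed flux, and asks per test substance whether the substance can
drive recycling on minimal medium. Step 4 maximises each substance's
secretion exchange on the original medium. The oxygen toggle applies to
step 2 only, as specified for the component protocol; the recycling trio
is a single shared definition between step 3 and the carbon-source
assay. Temporary reactions never remain in any returned model.

## Phenotypes

Carbon sources: a substance is an energy source when the summed
recycling flux is positive on minimal medium + substance (all secretion
bounds stay open). Fermentation: minimal-total-flux FBA at the growth
optimum (with 10⁻⁹ relative slack on the pinned objective); exchanges
with flux > 10⁻⁶ are products, normalised by growth rate to
mmol·gDW⁻¹; flux variability at 100% of the optimum gives each
product's maximum release ("all optimal solutions"). Essentiality:
per gene, reactions whose GPR evaluates false under the deletion are
closed and growth recomputed; essential below 0.01 h⁻¹. GPR equivalence
is decided by full truth-table comparison, capped at 20 distinct genes.

## Network similarity

For a model built from a fragmented genome, T = Σ aᵢbᵢ / Σ bᵢ over the
union of *gene-associated* reactions in the reference panel (non-empty
GPR; biomass, exchange and diffusion pseudo-reactions excluded), bᵢ the
panel frequency, aᵢ membership of the query model.

## The synthetic world

The fixture generator emits a ~50-reaction, 64-metabolite database:
glycolysis, a full TCA cycle, NADH/quinone/menaquinone electron
transport with proton pumping and ATP synthase, mixed-acid fermentation
branches (lactate, acetate, ethanol, formate→H₂+CO₂), anaplerosis via
spontaneous carbonate equilibration, lumped biosynthesis of eight
biomass precursors, and eight transporters spanning all four TC classes
(including a PTS complex and an ABC system). Every reaction is mass-
and charge-balanced against real small-molecule formulas (synthetic but
balanced species for the cell-envelope analogues), the closed-exchange
ATP maximum is exactly zero, and a deliberately mis-annotated ATP
synthase copy provides the positive control for the energy-cycle
detector. Growth rates on the toy media are 2.18 h⁻¹ (glucose minimal,
aerobic) and 0.69 h⁻¹ (anaerobic) — deliberately high-yield, as the toy
network has no maintenance drain enforced.

Organism profiles plant one story each: *complete* (every enzymatic
reaction strongly hit), *fermenter* (lactate dehydrogenase at bitscore
140 and the fructose route at 130 — core but sub-threshold), *single
gap* (the anaplerotic carboxylase missing entirely; its two-member
pathway then fails every presence rule, so only the LP can restore
growth, and the carboxylase is provably the unique minimal addition),
*auxotroph* (alanine synthesis at 120 = step-2-recoverable, fatty-acid
synthesis at 20 = non-core, hence a permanently flagged component), and
*fragmented(p)* (each hit dropped independently with probability p).
Strong bitscores are drawn uniformly from [250, 420] and coverages from
[80, 95]; all randomness flows through one seeded generator.

What the fixtures do **not** emulate: real sequence alignment (hit
tables are the interface; an external aligner adapter parses standard
12-column tabular output but is not exercised against a live aligner),
promiscuous enzymes and incomplete EC mappings, genome-scale database
size, thermodynamic constraints, or maintenance energy. Passing tests
therefore demonstrate algorithmic correctness on controlled inputs, not
predictive accuracy on real genomes.

## Numerical choices

- LP backend: HiGHS via scipy (`milp` with continuous variables);
  deterministic under the fixed lexicographic variable order.
- Flux tolerance 10⁻⁶ for "carries flux"; energy-cycle tolerance 10⁻⁹
  (the curation check demands exact silence within solver precision).
- MTF/FVA pin the objective at 100% of the optimum with 10⁻⁹ relative
  slack.
- Balance checking treats missing formulas as "unknown composition",
  never as pass or fail; exchanges and biomass are rejected outright.
- Dead-end pruning is an explicit utility and never applied implicitly;
  the universal model keeps its dead ends by design.
- Transporter class fallback order: detected class first, then
  ascending class number.

## Known limitations

Two compartments only; no MILP or loopless gap-filling variants; no
thermodynamic constraints; single-gene deletions only; the similarity
score ignores reaction directionality; SBML round-trips preserve the
model exactly but normalise GPR parenthesisation on first import.
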