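# Methods

## Scope and data model

`evigem` treats a genome-scale metabolic model as a constraint-based
network (compartments, metabolites, reactions with flux bounds in
mmol·gDW⁻¹·h⁻¹, GPR boolean gene associations, one active linear
objective) plus a curation payload of evidence items and phenotype test
cases that travels inside the SBML file. All identifiers are opaque
strings stored verbatim; in particular strain transcript identifiers
(e.g. JGI Aspni7 numbers such as `1178899`) are never normalized, because
strain translation must be lossless.

## SBML encoding

Models are written as SBML Level 3 Version 1 with the flux-balance
(fbc v2) extension: bounds as fbc flux-bound parameters (one pair per
reaction), the objective as an fbc objective, GPRs as fbc gene-product
association trees, ChEBI accessions as MIRIAM identifier URIs in RDF
annotations, and formulas/charges on the fbc species attributes. SBML SIds
may not start with a digit, so gene products carry a sanitized `fbc:id`
and the verbatim gene id in `fbc:label`; the reader prefers the label.
Metabolite and reaction ids must be valid SIds at write time (the writer
refuses with a diagnostic otherwise).

Boundary reactions may be encoded one-sided (`A →`, the canonical write
form) or with an explicit exterior species flagged
`boundaryCondition="true"`; the reader accepts both, flags boundary
reactions structurally (exactly one internal metabolite), and records the
encoding seen on `model.boundary_encoding_seen`.

### The evidence annotation dialect

Evidence, test cases and subsystem labels live in a model-level
`<annotation>` child in the namespace `urn:evigem:evidence:1`:

```xml
<ev:evidence xmlns:ev="urn:evigem:evidence:1">
  <ev:listOfEvidenceItems>
    <ev:evidenceItem id="e1" assertion="gene_catalyzes_reaction"
                     subject="1178899" target="R_TAN_TRANSPORT"
                     eco="ECO:0000314" description="direct assay">
      <ev:reference kind="pubmed" value="12345678" description=""/>
    </ev:evidenceItem>
  </ev:listOfEvidenceItems>
  <ev:listOfTestCases>
    <ev:testCase id="t1" name="growth on D-glucose">
      <ev:setting reaction="EX_glc" lowerBound="-10.0" upperBound="0.0"/>
      <ev:deletedGene gene="g1"/>
      <ev:outcome reaction="BIOMASS" cmp="greater" value="1e-06"/>
    </ev:testCase>
  </ev:listOfTestCases>
  <ev:listOfSubsystems>
    <ev:subsystem reaction="R1" label="Glycolysis"/>
  </ev:listOfSubsystems>
</ev:evidence>
```

Seven assertion kinds are supported (`gene_catalyzes_reaction`,
`gene_not_catalyzes_reaction`, `reaction_present`, `reaction_absent`,
`metabolite_present`, `metabolite_absent`,
`gene_localizes_to_compartment`); reference kinds are `pubmed`, `doi`,
`pmc`, `patent`, `url`. Numeric attributes are written with `repr` so the
dialect round-trips bit-exactly; XML escaping is delegated to lxml.
Unknown assertion kinds are preserved as opaque records and counted;
malformed blocks are skipped, logged and counted — an annotation problem
never aborts a model read. Absence assertions are stored but never applied
to the network; they only feed the conflict report, because a recorded
negative result (e.g. a knockout that merely *reduces* growth, indicating
partial redundancy) is a curation signal, not a network edit.

Subsystem labels are carried in this namespace rather than the SBML
groups extension so that one documented dialect covers the whole payload
with an exact round-trip guarantee.

## Simulation

FBA solves `max/min c·v s.t. S·v = 0, lb ≤ v ≤ ub`, with one row per
*internal* metabolite (boundary species are exterior pools). The LP
backend is pluggable behind a minimal contract (matrix, bounds, objective
in; status, objective, primal out); the default wraps
`scipy.optimize.linprog` (HiGHS) with feasibility tolerance 1e−9 and
optimality tolerance 1e−6. Infeasible and unbounded statuses are surfaced
explicitly, never returned as silent zeros. Only optimal objective
*values* are contractual: FBA flux vectors are degenerate in general and
are reported as one optimum among possibly many.

pFBA re-solves with each flux split into non-negative forward/backward
parts, minimizing their sum subject to the original constraints plus the
objective pinned at `c·v ≥ (1−10⁻⁶)·Z` for maximization (mirrored for
minimization). The relative slack means reported pFBA objectives can sit
up to one part in 10⁶ below the FBA optimum; tests compare accordingly.

Gene deletions are applied by evaluating each reaction's GPR with deleted
genes set to false; inactive reactions get bounds (0, 0). The empty GPR is
always active — reactions without genes (a large fraction of any curated
model, e.g. spontaneous and boundary reactions) are never disabled by
knockouts. Unknown gene ids raise instead of silently doing nothing.

## Test-case execution

For each test: clone bounds; restrict every boundary reaction not named in
the settings to its drain half-space (the drain direction is read off the
sign of the internal metabolite's coefficient, so both boundary encodings
work; "restricted" means intersected with the half-space — stored bounds
are not widened); apply the settings overrides; apply knockouts (knockout
wins over medium); then for each outcome maximize the outcome's reaction
and compare the achieved maximum to the threshold. `greater` outcomes are
capability checks; `less` outcomes are impossibility certificates, which
is what a no-growth phenotype requires (minimizing would make any `less`
outcome trivially true, since zero flux is always feasible). A test passes
iff all outcomes hold. Tests with unresolvable references or infeasible
LPs are reported as *errored*, never as failed, and suite totals always
satisfy passed + failed + errored = run. FBA is the default method with a
per-test `method` override (`pfba`); for threshold outcomes of this kind
the two give identical verdicts, since pFBA preserves the optimum.

The canonical growth/no-growth threshold used when *generating* tests is
10⁻⁶ mmol·gDW⁻¹·h⁻¹ — small against any biological flux, large against
solver tolerance (1e−9). Stored tests carry their own explicit numbers.

System checks generate tests programmatically: per biomass precursor, a
temporary drain is added and its maximal flux must exceed the threshold;
per essential medium component, closing that uptake must drive maximal
growth below it; named capability reactions (e.g. a peroxisomal
fatty-acid oxidation step) must be able to carry flux on the medium.

## Quality control

* **Mass balance**: per element, `Σ products coeff·count − Σ substrates`;
  balanced iff all element imbalances are zero and, when every participant
  has a charge, the charge imbalance is zero too. Formulas are Hill
  notation with integer counts; metabolites follow the undissociated-form
  convention (formulas carry the protons, charge optional). Wildcard
  R-group elements (`R`, `X`, `*`) and missing/unparseable formulas give
  an "undetermined" verdict rather than a guess. Boundary reactions are
  unbalanced by construction and are excluded from the census count.
* **Dead ends**: connectivity-based — a non-boundary metabolite that,
  considering reaction reversibility via the bounds, can only be produced
  or only be consumed (or participates in no reaction). LP-based blocked
  reaction analysis is deliberately out of scope; this is the standard
  census notion, and dead ends are retained as curation targets, not
  pruned.
* **Census** (`StatsReport`): reaction counts (total, transport = a
  non-boundary reaction spanning ≥ 2 compartments, boundary, unbalanced,
  annotated, no-genes, evidence-for-presence, known-gene), metabolite
  counts (total, ChEBI-annotated, dead-end), gene counts (total,
  known-function, verified/predicted localization), evidence counts by
  family, test counts. Two presence countings exist by design: the
  reaction-level `evidence_for_presence` (reactions with ≥ 1 presence
  item) and the item-level `reaction_presence` family count; both are
  emitted.
* **Support classification**: each reaction gets the strongest class its
  evidence affords — `characterized_enzyme` (experimental gene link) >
  `measured_unknown_enzyme` (experimental reaction-presence but no
  characterized gene) > `strong_similarity` (similarity-based gene link) >
  `other` (any remaining or unknown-ECO evidence) > `no_evidence`. The
  ECO→rank mapping ships as an editable table
  (`src/evigem/data/eco_ranks.tsv`); unknown codes rank "other" with a
  warning. Localization assertions rank genes, not reactions. Because the
  ontology is large, any fixed cut is a curation choice; the shipped
  defaults cover the accessions most used in fungal curation.
* **Conflicts**: presence/absence pairs about the same link or entity are
  listed for the curator and never auto-resolved.

## Strain translation

Reciprocal best hits over two 12-column tabular alignment hit files:
best(q) = subject with maximal bitscore, ties broken by minimal e-value,
then lexicographically smallest subject id; duplicate (query, subject)
rows keep the best-scoring one with a warning. (a, b) are paired iff each
is the other's best. No e-value/identity pre-filter is applied by default;
both are available as arguments. Translation rewrites every GPR leaf
through the map; an OR losing members keeps the rest, an AND losing
members keeps the rest but flags the reaction *degraded* (silently
requiring fewer subunits would change knockout semantics), and a fully
emptied GPR leaves the reaction in place, gene-less. Reaction and
metabolite content is untouched. Gene-subject evidence is rewritten or
dropped with a log entry; the report lists unmapped source genes.

## Expression contextualization

Input is a pre-normalized log2 gene × condition matrix (normalization is
out of scope). Pathway membership is the union of GPR leaves over
reactions sharing a subsystem label. The per-gene change is
log2(condition) − log2(reference); the reference condition is a required
argument and is never defaulted, because the biologically meaningful
baseline depends on the experiment. Genes missing from the matrix are
reported as missing, never imputed as zero — public compendia genuinely
lack probes for some genes. Co-expression scoring is the Pearson
correlation of a candidate profile against each cluster member across ≥ 3
shared conditions plus the mean over defined correlations; zero-variance
profiles yield an undefined (None) correlation rather than 0.

## Fixtures and what they do (not) show

The fixture generator builds six topologies with hand-derived ground
truth: `chain` (optimum = uptake bound), `branch`, `yield_half`
(2 A → B, optimum = half the uptake), `compartmented` (one transport
step), `dead_end_k` (k engineered dead ends), `redundant_routes`
(2-step vs 3-step route; minimal total flux 4·ub). Suites built on them
have their pass/fail composition guaranteed by construction. Seeds are
explicit parameters everywhere; identical spec + seed gives identical
serialized output.

These networks exercise every code path (steady state, yields,
reversibility, compartments, knockout logic, parsimony, medium closure)
at sizes where brute-force oracles are exact: vertex enumeration for the
LP, truth tables for GPRs, double-argmax for RBH. They do not emulate
genome-scale properties — thousands of reactions, degenerate alternate
optima webs, extensive dead-end regions, noisy annotation — so passing
tests certify algorithmic correctness, not curation quality of any real
model. Checks that need the published *A. niger* strain models (census
reproduction, support-class fractions) run only when those distributed
files are placed under `data/`.

## Numerical choices and limitations

LP feasibility 1e−9, optimality 1e−6, pFBA pin slack 1e−6 (relative);
balance and dead-end arithmetic use exact comparisons with a 1e−9 noise
floor. Problem sizes in the test suite and the reproduction script stay
at fixture scale (≤ 15 reactions, 20×20 hit matrices, 10-condition
profiles), where the independent oracles are exhaustive. Known
limitations: no flux variability or blocked-reaction analysis; no
gap-filling or automatic repair of failing tests (failures are curation
targets by design); SBML Level 2 import, kinetic elements and layout
extensions are unsupported; the evidence dialect reader accepts only the
namespace documented above — foreign annotation dialects are surfaced in
the parse report rather than guessed at.
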