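# evigem

Evidence-annotated genome-scale metabolic models.

Genome-scale metabolic reconstructions of organisms like *Aspergillus
niger* are distilled from hundreds of publications, but the literature
trail usually vanishes once the model is published: nothing in the SBML
file says *why* a gene was assigned to a reaction, and nothing re-checks
the model against the experiments that motivated it. `evigem` is a library
and CLI for models that carry their own curation payload:

* **Evidence items** — structured, referenced assertions (a gene catalyzes
  a reaction, a reaction or metabolite is present/absent, a gene product
  localizes to a compartment), each tagged with an Evidence and Conclusion
  Ontology (ECO) accession — live inside the SBML file, in a dedicated
  annotation namespace that does not break format compliance.
* **Test cases** — stored phenotype experiments: medium composition as
  boundary-bound overrides, gene knockouts, and flux-threshold outcomes —
  are simulated automatically, so every model edit can be validated against
  the full body of recorded experiments.
* Quality control (mass balance, dead-end metabolites, census statistics,
  support classification, evidence conflicts), strain translation via
  reciprocal best hits, and pathway-level contextualization of expression
  data round out the toolkit.

It is aimed at curators of constraint-based models who want continuous,
test-driven reconstruction, and at modelers who want to know how well a
reaction is supported before trusting a prediction.

## The model and the method

A metabolic network with reactions $j$ and internal metabolites $i$ is
simulated by flux balance analysis (FBA): find fluxes $v$ solving

$$\max\; c^\top v \quad \text{s.t.}\quad S\,v = 0,\qquad lb \le v \le ub,$$

with $S$ the stoichiometric matrix. Parsimonious FBA (pFBA) then fixes the
optimum $Z$ and minimizes total flux $\sum_j |v_j|$ subject to
$c^\top v \ge (1-10^{-6})Z$. Gene deletions propagate through
gene–protein–reaction (GPR) boolean rules: a reaction whose GPR evaluates
false with the deleted genes set to false gets bounds $(0,0)$.

A test case is run by (1) restricting every boundary reaction *not* named
in its settings to the drain direction (nothing can be taken up that is not
in the medium; anything may be excreted), (2) applying the settings and
knockouts, and (3) maximizing each outcome's reaction: `greater` outcomes
check capability (the optimum exceeds the threshold), `less` outcomes
certify impossibility (not even the optimum reaches it — the no-growth
phenotype).

## Worked example

Generate a three-metabolite linear pathway with an embedded suite of four
phenotype tests (three engineered to pass, one to fail), then validate it:

```bash
$ evigem fixtures chain --n 3 --ub 10
chain_3.xml
$ evigem validate chain_3.xml
test      status  passed  detail
t_fail_0  ok      False   EX_M2 greater 1e-06: achieved -0 (VIOLATED)
t_pass_0  ok      True    EX_M2 greater 1e-06: achieved 10 (ok)
t_pass_1  ok      True    EX_M2 less 1e-06: achieved -0 (ok)
t_pass_2  ok      True    EX_M2 greater 1e-06: achieved 10 (ok)
INFO evigem: ran 4 tests: 3 passed, 1 failed, 0 errored
$ echo $?
1
```

`t_pass_0` opens the carbon source and demands product export above
10⁻⁶ mmol·gDW⁻¹·h⁻¹; the achieved maximum (10, the uptake bound) passes.
`t_pass_1` deletes the single pathway gene and demands *no* product: the
certified maximum is 0, so the no-growth phenotype holds. `t_fail_0`
demands product on a closed medium — steady state forbids it, and the
failure drives the nonzero exit code (CI-friendly). The census:

```bash
$ evigem stats chain_3.xml --format json
{
  "reactions":   {"total": 4, "boundary": 2, "unbalanced": 0, "no_genes": 2, ...},
  "metabolites": {"total": 3, "annotated": 0, "dead_end": 0},
  "evidences":   {"gene_reaction": 2, "reaction_presence": 2,
                  "metabolite_presence": 2, "localization": 1, "total": 7},
  "tests":       {"total": 4, "passing": 3, "failing": 1}, ...
}
```

The same operations are available as a library (`evigem.fba.fba`,
`evigem.runner.run_suite`, `evigem.qc.model_statistics`,
`evigem.strains.reciprocal_best_hits`, ...), all built on plain
dataclasses and a pluggable LP backend.

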