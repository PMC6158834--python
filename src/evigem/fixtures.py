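"""Deterministic toy networks with analytically known behavior.

Every topology here has its ground truth (optimal objective value,
dead-end set, balance verdicts, suite pass/fail composition) worked out by
hand and attached to the returned object, so simulation, QC and the test
runner can all be checked against known answers without any external file.
The same spec and seed always produce the identical object — seeds are
explicit parameters, there is no global random state.

Boundary reactions are written in canonical drain form ({met: -1}; positive
flux leaves the system, uptake is a negative flux).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Tuple

from .evidence import EvidenceItem, Outcome, Reference, TestCase
from .gpr import parse_gpr
from .model import Compartment, Gene, Metabolite, MetabolicModel, Reaction
from .runner import GROWTH_THRESHOLD

__all__ = ["FixtureSpec", "ModelFixture", "make_model", "make_suite", "TOPOLOGIES"]

TOPOLOGIES = (
    "chain",
    "branch",
    "yield_half",
    "compartmented",
    "dead_end_k",
    "redundant_routes",
)


@dataclass(frozen=True)
class FixtureSpec:
    topology: str
    n: int = 3          # chain length / dead-end count, topology-dependent
    ub: float = 10.0    # uptake capacity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; know {TOPOLOGIES}")


@dataclass
class ModelFixture:
    model: MetabolicModel
    #: documented ground truth: optimal objective, dead-end ids, ...
    truth: Dict[str, Any] = field(default_factory=dict)


def _exchange(rid: str, met: str, lb: float, ub: float) -> Reaction:
    return Reaction(id=rid, stoichiometry={met: -1.0},
                    lower_bound=lb, upper_bound=ub, is_boundary=True)


def _chain(spec: FixtureSpec) -> ModelFixture:
    """Linear pathway M0 -> M1 -> ... with open uptake; optimum = ub."""
    m = MetabolicModel(id=f"chain_{spec.n}")
    m.add_compartment(Compartment("c", "cytosol"))
    names = [f"M{i}" for i in range(spec.n)]
    for i, mid in enumerate(names):
        m.add_metabolite(Metabolite(mid, "c", formula="C6H12O6"))
    m.add_reaction(_exchange("EX_M0", "M0", -spec.ub, 1000.0))
    for i in range(1, spec.n):
        m.add_reaction(Reaction(
            id=f"R{i}", stoichiometry={names[i - 1]: -1.0, names[i]: 1.0},
            lower_bound=0.0, upper_bound=1000.0, gpr=parse_gpr(f"g{i}"),
            subsystem="Linear pathway",
        ))
    sink = f"EX_{names[-1]}"
    m.add_reaction(_exchange(sink, names[-1], 0.0, 1000.0))
    m.objective = {sink: 1.0}
    truth = {"optimum": spec.ub, "dead_ends": [], "sink": sink,
             "uptake": "EX_M0", "essential_genes": [f"g{i}" for i in range(1, spec.n)]}
    m.notes["ground_truth"] = json.dumps(truth)
    return ModelFixture(m, truth)


def _branch(spec: FixtureSpec) -> ModelFixture:
    """A splits into B and C; both exported; optimum(EX_B + EX_C) = ub."""
    m = MetabolicModel(id="branch")
    m.add_compartment(Compartment("c"))
    for mid in ("A", "B", "C"):
        m.add_metabolite(Metabolite(mid, "c", formula="C3H6O3"))
    m.add_reaction(_exchange("EX_A", "A", -spec.ub, 1000.0))
    m.add_reaction(Reaction("RB", {"A": -1.0, "B": 1.0}, 0.0, 1000.0,
                            gpr=parse_gpr("gB"), subsystem="Branch B"))
    m.add_reaction(Reaction("RC", {"A": -1.0, "C": 1.0}, 0.0, 1000.0,
                            gpr=parse_gpr("gC1 and gC2"), subsystem="Branch C"))
    m.add_reaction(_exchange("EX_B", "B", 0.0, 1000.0))
    m.add_reaction(_exchange("EX_C", "C", 0.0, 1000.0))
    m.objective = {"EX_B": 1.0}
    truth = {"optimum": spec.ub, "dead_ends": [],
             "S_shape": (3, 5), "uptake": "EX_A", "sink": "EX_B"}
    m.notes["ground_truth"] = json.dumps(truth)
    return ModelFixture(m, truth)


def _yield_half(spec: FixtureSpec) -> ModelFixture:
    """2 A -> 1 B; uptake ub; max B export = ub/2 (hand LP)."""
    m = MetabolicModel(id="yield_half")
    m.add_compartment(Compartment("c"))
    m.add_metabolite(Metabolite("A", "c", formula="C3H6O3"))
    m.add_metabolite(Metabolite("B", "c", formula="C6H12O6"))
    m.add_reaction(_exchange("EX_A", "A", -spec.ub, 1000.0))
    m.add_reaction(Reaction("COND", {"A": -2.0, "B": 1.0}, 0.0, 1000.0,
                            gpr=parse_gpr("gCond"), subsystem="Condensation"))
    m.add_reaction(_exchange("EX_B", "B", 0.0, 1000.0))
    m.objective = {"EX_B": 1.0}
    truth = {"optimum": spec.ub / 2.0, "dead_ends": [],
             "uptake": "EX_A", "sink": "EX_B"}
    m.notes["ground_truth"] = json.dumps(truth)
    return ModelFixture(m, truth)


def _compartmented(spec: FixtureSpec) -> ModelFixture:
    """Cytosol + mitochondrion with one transport step; optimum = ub."""
    m = MetabolicModel(id="compartmented")
    m.add_compartment(Compartment("c", "cytosol"))
    m.add_compartment(Compartment("m", "mitochondrion"))
    m.add_metabolite(Metabolite("pyr_c", "c", formula="C3H4O3", chebi="CHEBI:32816"))
    m.add_metabolite(Metabolite("pyr_m", "m", formula="C3H4O3", chebi="CHEBI:32816"))
    m.add_metabolite(Metabolite("accoa_m", "m", formula="C23H38N7O17P3S"))
    m.add_reaction(_exchange("EX_pyr", "pyr_c", -spec.ub, 1000.0))
    m.add_reaction(Reaction("T_pyr", {"pyr_c": -1.0, "pyr_m": 1.0}, -1000.0, 1000.0,
                            gpr=parse_gpr("gT"), subsystem="Transport"))
    m.add_reaction(Reaction("PDH", {"pyr_m": -1.0, "accoa_m": 1.0}, 0.0, 1000.0,
                            gpr=parse_gpr("gPdh1 and gPdh2"), subsystem="TCA cycle"))
    m.add_reaction(_exchange("EX_accoa", "accoa_m", 0.0, 1000.0))
    m.objective = {"EX_accoa": 1.0}
    truth = {"optimum": spec.ub, "dead_ends": [], "transport_reactions": ["T_pyr"],
             "uptake": "EX_pyr", "sink": "EX_accoa"}
    m.notes["ground_truth"] = json.dumps(truth)
    return ModelFixture(m, truth)


def _dead_end_k(spec: FixtureSpec) -> ModelFixture:
    """Chain plus k metabolites that are produced but never consumed."""
    fx = _chain(FixtureSpec("chain", n=3, ub=spec.ub, seed=spec.seed))
    m = fx.model
    m.id = f"dead_end_{spec.n}"
    dead = []
    for i in range(spec.n):
        did = f"D{i}"
        m.add_metabolite(Metabolite(did, "c"))
        m.add_reaction(Reaction(f"PD{i}", {"M0": -1.0, did: 1.0}, 0.0, 1000.0,
                                subsystem="Dead branches"))
        dead.append(did)
    truth = dict(fx.truth)
    truth["dead_ends"] = dead
    m.notes["ground_truth"] = json.dumps(truth)
    return ModelFixture(m, truth)


def _redundant_routes(spec: FixtureSpec) -> ModelFixture:
    """A -> B via a 2-reaction route and a 3-reaction route.

    FBA optimum is ub either way; parsimony must place all flux on the
    short route (total |v| = 4·ub vs 5·ub, uptake and export included).
    """
    m = MetabolicModel(id="redundant_routes")
    m.add_compartment(Compartment("c"))
    for mid in ("A", "X1", "Y1", "Y2", "B"):
        m.add_metabolite(Metabolite(mid, "c", formula="C2H4O2"))
    m.add_reaction(_exchange("EX_A", "A", -spec.ub, 1000.0))
    m.add_reaction(Reaction("S1", {"A": -1.0, "X1": 1.0}, 0.0, 1000.0,
                            gpr=parse_gpr("gS1"), subsystem="Short route"))
    m.add_reaction(Reaction("S2", {"X1": -1.0, "B": 1.0}, 0.0, 1000.0,
                            gpr=parse_gpr("gS2"), subsystem="Short route"))
    m.add_reaction(Reaction("L1", {"A": -1.0, "Y1": 1.0}, 0.0, 1000.0,
                            gpr=parse_gpr("gL1"), subsystem="Long route"))
    m.add_reaction(Reaction("L2", {"Y1": -1.0, "Y2": 1.0}, 0.0, 1000.0,
                            gpr=parse_gpr("gL2"), subsystem="Long route"))
    m.add_reaction(Reaction("L3", {"Y2": -1.0, "B": 1.0}, 0.0, 1000.0,
                            gpr=parse_gpr("gL3"), subsystem="Long route"))
    m.add_reaction(_exchange("EX_B", "B", 0.0, 1000.0))
    m.objective = {"EX_B": 1.0}
    truth = {
        "optimum": spec.ub,
        "dead_ends": [],
        "short_route": ["S1", "S2"],
        "long_route": ["L1", "L2", "L3"],
        "min_total_flux": 4.0 * spec.ub,
        "uptake": "EX_A",
        "sink": "EX_B",
    }
    m.notes["ground_truth"] = json.dumps(truth)
    return ModelFixture(m, truth)


_BUILDERS = {
    "chain": _chain,
    "branch": _branch,
    "yield_half": _yield_half,
    "compartmented": _compartmented,
    "dead_end_k": _dead_end_k,
    "redundant_routes": _redundant_routes,
}


def make_model(spec: FixtureSpec) -> ModelFixture:
    """Build the fixture named by `spec.topology` with its ground truth."""
    return _BUILDERS[spec.topology](spec)


# ---------------------------------------------------------------------------
# evidence + test suites


def _one_of_each_evidence(model: MetabolicModel) -> List[EvidenceItem]:
    """One evidence item of each of the seven assertion kinds, wired to
    entities that exist in the given model."""
    ref = Reference("pubmed", "123456", "toy source")
    rxn = next(r for r in model.reactions.values() if not r.gpr.is_empty)
    gene = sorted(rxn.gpr.genes())[0]
    met = next(iter(model.metabolites))
    comp = next(iter(model.compartments))
    other_rxn = next(r.id for r in model.reactions.values() if r.id != rxn.id)
    return [
        EvidenceItem("ev1", "gene_catalyzes_reaction", gene, rxn.id,
                     "ECO:0000314", "direct assay of activity", (ref,)),
        EvidenceItem("ev2", "gene_not_catalyzes_reaction", gene, other_rxn,
                     "ECO:0000315", "knockout retains activity", (ref,)),
        EvidenceItem("ev3", "reaction_present", rxn.id, "",
                     "ECO:0000314", "activity measured in extract", (ref,)),
        EvidenceItem("ev4", "reaction_absent", other_rxn, "",
                     "ECO:0000315", "no activity detected", (ref,)),
        EvidenceItem("ev5", "metabolite_present", met, "",
                     "ECO:0000314", "compound detected by MS", (ref,)),
        EvidenceItem("ev6", "metabolite_absent", met, "",
                     "ECO:0000269", "below detection limit", (ref,)),
        EvidenceItem("ev7", "gene_localizes_to_compartment", gene, comp,
                     "ECO:0000314", "GFP fusion", (ref,)),
    ]


def make_suite(
    fixture: ModelFixture,
    n_pass: int = 3,
    n_fail: int = 1,
    seed: int = 0,
) -> Tuple[List[EvidenceItem], List[TestCase]]:
    """Evidence items plus a test suite with a guaranteed pass/fail split.

    Built on a fixture that declares ``uptake``/``sink`` ground truth
    (chain, branch, yield_half, compartmented, redundant_routes). Passing
    tests alternate growth (open uptake → sink flux attainable) and
    knockout (delete an essential gene → sink flux provably zero); failing
    tests demand sink flux on a closed medium, which steady state forbids.
    """
    model, truth = fixture.model, fixture.truth
    uptake, sink = truth["uptake"], truth["sink"]
    ub = -model.reactions[uptake].lower_bound
    rng = random.Random(seed)
    thr = GROWTH_THRESHOLD
    ref = Reference("pubmed", "999999", "toy phenotype source")
    essential = truth.get("essential_genes") or []

    tests: List[TestCase] = []
    for i in range(n_pass):
        if i % 2 == 1 and essential:
            gene = essential[rng.randrange(len(essential))]
            tests.append(TestCase(
                id=f"t_pass_{i}", name=f"no product after deleting {gene}",
                settings=((uptake, -ub, 0.0),),
                deleted_genes=(gene,),
                outcomes=(Outcome(sink, "less", thr),),
                references=(ref,),
            ))
        else:
            tests.append(TestCase(
                id=f"t_pass_{i}", name="product formed on open medium",
                settings=((uptake, -ub, 0.0),),
                outcomes=(Outcome(sink, "greater", thr),),
                references=(ref,),
            ))
    for i in range(n_fail):
        tests.append(TestCase(
            id=f"t_fail_{i}", name="product demanded on closed medium",
            outcomes=(Outcome(sink, "greater", thr),),
            references=(ref,),
        ))
    return _one_of_each_evidence(model), tests
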