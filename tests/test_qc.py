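"""Mass balance, dead ends, census statistics, support classes, conflicts."""

import random

import pytest

from evigem.evidence import EvidenceItem, Reference
from evigem.fixtures import FixtureSpec, make_model, make_suite
from evigem.gpr import parse_gpr
from evigem.model import Compartment, Metabolite, MetabolicModel, Reaction
from evigem.qc import (
    SUPPORT_ORDER,
    check_mass_balance,
    classify_support,
    conflict_report,
    find_dead_ends,
    load_eco_ranks,
    metabolite_measured_fraction,
    model_statistics,
    support_fractions,
)
from evigem.runner import run_suite


def _ref():
    return Reference("pubmed", "1", "")


def _model(*mets, reactions=()):
    m = MetabolicModel(id="qc")
    m.add_compartment(Compartment("c"))
    for mid, formula in mets:
        m.add_metabolite(Metabolite(mid, "c", formula=formula))
    for r in reactions:
        m.add_reaction(r)
    return m


# ---------------------------------------------------------------------------
# mass balance


def test_balanced_reaction():
    m = _model(("A", "CH4"), ("B", "O2"), ("C", "CH4O2"),
               reactions=(Reaction("R", {"A": -1, "B": -1, "C": 1}),))
    rep = check_mass_balance(m.reactions["R"], m)
    assert rep.verdict == "balanced"
    assert rep.element_imbalance == {}


def test_hydrogen_deficit_detected():
    m = _model(("A", "CH4"), ("C", "CH3"),
               reactions=(Reaction("R", {"A": -1, "C": 1}),))
    rep = check_mass_balance(m.reactions["R"], m)
    assert rep.verdict == "unbalanced"
    assert rep.element_imbalance == {"H": -1}


def test_missing_formula_undetermined():
    m = _model(("A", "CH4"), ("C", None),
               reactions=(Reaction("R", {"A": -1, "C": 1}),))
    assert check_mass_balance(m.reactions["R"], m).verdict == "undetermined"


def test_wildcard_formula_undetermined():
    m = _model(("A", "C2H4R"), ("C", "C2H4R"),
               reactions=(Reaction("R", {"A": -1, "C": 1}),))
    assert check_mass_balance(m.reactions["R"], m).verdict == "undetermined"


def test_unparseable_formula_undetermined_with_diagnostic():
    m = _model(("A", "not a formula!"), ("C", "CH4"),
               reactions=(Reaction("R", {"A": -1, "C": 1}),))
    rep = check_mass_balance(m.reactions["R"], m)
    assert rep.verdict == "undetermined"
    assert rep.notes


def test_reverse_reaction_same_verdict():
    m = _model(("A", "CH4"), ("C", "CH3"),
               reactions=(Reaction("R", {"A": -1, "C": 1}),
                          Reaction("Rrev", {"A": 1, "C": -1})))
    a = check_mass_balance(m.reactions["R"], m)
    b = check_mass_balance(m.reactions["Rrev"], m)
    assert a.verdict == b.verdict == "unbalanced"


def test_charge_imbalance():
    m = _model(("A", "C3H5O3"), ("C", "C3H5O3"))
    m.metabolites["A"].charge = -1
    m.metabolites["C"].charge = 0
    m.add_reaction(Reaction("R", {"A": -1, "C": 1}))
    rep = check_mass_balance(m.reactions["R"], m)
    assert rep.verdict == "unbalanced"
    assert rep.charge_imbalance == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# dead ends


def test_only_produced_is_dead_end():
    m = _model(("A", None), ("B", None),
               reactions=(Reaction("R", {"A": -1, "B": 1}, 0, 10),
                          Reaction("EX_A", {"A": -1}, -10, 10, is_boundary=True)))
    assert find_dead_ends(m) == {"B"}


def test_reversible_interior_not_dead_end():
    m = _model(("A", None), ("B", None), ("C", None),
               reactions=(Reaction("R1", {"A": -1, "B": 1}, -10, 10),
                          Reaction("R2", {"B": -1, "C": 1}, -10, 10),
                          Reaction("EX_A", {"A": -1}, -10, 10, is_boundary=True),
                          Reaction("EX_C", {"C": -1}, -10, 10, is_boundary=True)))
    assert find_dead_ends(m) == set()


def test_engineered_dead_ends_recovered_exactly(dead_end_3):
    assert find_dead_ends(dead_end_3.model) == set(dead_end_3.truth["dead_ends"])


def test_orphan_metabolite_is_dead_end():
    m = _model(("A", None))
    assert find_dead_ends(m) == {"A"}


def test_dead_ends_invariant_under_reordering_and_relabeling(dead_end_3):
    model = dead_end_3.model
    expected = find_dead_ends(model)
    # reorder reactions
    items = list(model.reactions.items())
    random.Random(5).shuffle(items)
    model.reactions = dict(items)
    assert find_dead_ends(model) == expected
    # relabel metabolites
    rename = {mid: f"met_{mid}" for mid in model.metabolites}
    relabeled = MetabolicModel(id="relabel")
    relabeled.compartments = model.compartments
    for mid, met in model.metabolites.items():
        relabeled.add_metabolite(Metabolite(rename[mid], met.compartment,
                                            is_boundary_species=met.is_boundary_species))
    for r in model.reactions.values():
        relabeled.add_reaction(Reaction(
            r.id, {rename[k]: v for k, v in r.stoichiometry.items()},
            r.lower_bound, r.upper_bound, is_boundary=r.is_boundary))
    assert find_dead_ends(relabeled) == {rename[m] for m in expected}


# ---------------------------------------------------------------------------
# census


def test_hand_counted_stats(compartmented):
    model = compartmented.model
    evidences, tests = make_suite(compartmented, 2, 1)
    suite = run_suite(model, tests)
    stats = model_statistics(model, evidences, tests, suite)
    assert stats.reactions["total"] == 4
    assert stats.reactions["transport"] == 1       # T_pyr spans c and m
    assert stats.reactions["boundary"] == 2
    assert stats.reactions["no_genes"] == 2        # the two exchanges
    assert stats.metabolites["total"] == 3
    assert stats.metabolites["annotated"] == 2     # the two ChEBI-tagged pyruvates
    assert stats.genes["total"] == len(model.genes)
    assert stats.evidences["total"] == 7
    assert stats.tests == {"total": 3, "passing": 2, "failing": 1}


def test_subcategories_never_exceed_totals(chain_suite):
    model, evidences, tests = chain_suite
    stats = model_statistics(model, evidences, tests, run_suite(model, tests))
    for block in (stats.reactions, stats.metabolites, stats.genes):
        for key, value in block.items():
            if key != "total":
                assert value <= block["total"], key
    families = {k: v for k, v in stats.evidences.items() if k != "total"}
    assert sum(families.values()) == stats.evidences["total"]


def test_both_presence_countings_emitted(chain):
    items = [
        EvidenceItem("e1", "reaction_present", "R1", eco_code="ECO:0000314",
                     references=(_ref(),)),
        EvidenceItem("e2", "reaction_present", "R1", eco_code="ECO:0000269",
                     references=(_ref(),)),
    ]
    stats = model_statistics(chain.model, items)
    assert stats.reactions["evidence_for_presence"] == 1   # reaction-level
    assert stats.evidences["reaction_presence"] == 2       # item-level


# ---------------------------------------------------------------------------
# support classification


def test_support_class_examples(chain):
    model = chain.model
    cases = {
        "characterized": EvidenceItem(
            "e1", "gene_catalyzes_reaction", "g1", "R1", "ECO:0000314",
            references=(_ref(),)),
        "similarity": EvidenceItem(
            "e2", "gene_catalyzes_reaction", "g2", "R2", "ECO:0000250"),
    }
    classes = {c.reaction_id: c.support
               for c in classify_support(model, list(cases.values()))}
    assert classes["R1"] == "characterized_enzyme"
    assert classes["R2"] == "strong_similarity"
    assert classes["EX_M0"] == "no_evidence"  # no evidence, empty GPR


def test_measured_unknown_enzyme_and_precedence(chain):
    items = [
        EvidenceItem("e1", "reaction_present", "R1", eco_code="ECO:0000314",
                     references=(_ref(),)),
    ]
    classes = {c.reaction_id: c.support for c in classify_support(chain.model, items)}
    assert classes["R1"] == "measured_unknown_enzyme"
    # a characterized gene link outranks measured-presence
    items.append(EvidenceItem("e2", "gene_catalyzes_reaction", "g1", "R1",
                              "ECO:0000314", references=(_ref(),)))
    classes = {c.reaction_id: c.support for c in classify_support(chain.model, items)}
    assert classes["R1"] == "characterized_enzyme"


def test_unknown_eco_code_warns_and_is_other(chain):
    items = [EvidenceItem("e1", "gene_catalyzes_reaction", "g1", "R1",
                          "ECO:9999999", references=(_ref(),))]
    with pytest.warns(UserWarning, match="ECO:9999999"):
        classes = {c.reaction_id: c.support
                   for c in classify_support(chain.model, items)}
    assert classes["R1"] == "other"


def test_support_fractions_sum_to_one(chain):
    classes = classify_support(chain.model, [])
    fracs = support_fractions(classes)
    assert set(fracs) == set(SUPPORT_ORDER)
    assert sum(fracs.values()) == pytest.approx(1.0)


def test_metabolite_measured_fraction(chain):
    items = [EvidenceItem("e1", "metabolite_present", "M0",
                          eco_code="ECO:0000314", references=(_ref(),))]
    assert metabolite_measured_fraction(chain.model, items) == pytest.approx(1 / 3)


def test_eco_rank_table_loads():
    ranks = load_eco_ranks()
    assert ranks["ECO:0000314"] == "experimental"
    assert ranks["ECO:0000250"] == "similarity"
    assert ranks["ECO:0000255"] == "other"


# ---------------------------------------------------------------------------
# conflicts


def test_presence_absence_conflict_detected():
    items = [
        EvidenceItem("e1", "reaction_present", "R1", eco_code="ECO:0000314",
                     references=(_ref(),)),
        EvidenceItem("e2", "reaction_absent", "R1", eco_code="ECO:0000315",
                     references=(_ref(),)),
    ]
    conflicts = conflict_report(items)
    assert len(conflicts) == 1
    assert {c.id for c in conflicts[0]} == {"e1", "e2"}


def test_disjoint_items_no_conflict():
    items = [
        EvidenceItem("e1", "reaction_present", "R1", eco_code="ECO:0000314",
                     references=(_ref(),)),
        EvidenceItem("e2", "reaction_absent", "R2", eco_code="ECO:0000315",
                     references=(_ref(),)),
    ]
    assert conflict_report(items) == []


def test_two_engineered_conflicts_found_exactly():
    items = [
        EvidenceItem("e1", "gene_catalyzes_reaction", "g1", "R1",
                     "ECO:0000314", references=(_ref(),)),
        EvidenceItem("e2", "gene_not_catalyzes_reaction", "g1", "R1",
                     "ECO:0000315", references=(_ref(),)),
        EvidenceItem("e3", "metabolite_present", "M1",
                     eco_code="ECO:0000314", references=(_ref(),)),
        EvidenceItem("e4", "metabolite_absent", "M1",
                     eco_code="ECO:0000269", references=(_ref(),)),
        EvidenceItem("e5", "reaction_present", "R9",
                     eco_code="ECO:0000314", references=(_ref(),)),
    ]
    assert len(conflict_report(items)) == 2
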