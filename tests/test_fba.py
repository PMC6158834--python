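"""FBA/pFBA against hand LPs, a vertex-enumeration oracle, and cobrapy."""

import numpy as np
import pytest

from evigem.fba import (
    apply_deletions,
    build_problem,
    fba,
    pfba,
    total_flux,
)
from evigem.fixtures import FixtureSpec, make_model
from evigem.gpr import parse_gpr
from evigem.model import Compartment, Metabolite, MetabolicModel, Reaction


def test_chain_matrix_shape_and_signs(chain):
    p = build_problem(chain.model)
    # rows: internal metabolites only; columns: all reactions
    assert p.S.shape == (3, 4)
    dense = p.S.toarray()
    j_up = p.column("EX_M0")
    assert dense[p.metabolite_ids.index("M0"), j_up] == -1.0
    j_r1 = p.column("R1")
    assert dense[p.metabolite_ids.index("M0"), j_r1] == -1.0
    assert dense[p.metabolite_ids.index("M1"), j_r1] == 1.0


def test_reversible_reaction_single_column_negative_lb(compartmented):
    p = build_problem(compartmented.model)
    j = p.column("T_pyr")
    assert p.lb[j] < 0 < p.ub[j]


def test_empty_model_errors():
    m = MetabolicModel(id="empty")
    with pytest.raises(ValueError):
        build_problem(m)


def test_chain_optimum_is_uptake_bound(chain):
    sol = fba(build_problem(chain.model))
    assert sol.ok
    assert sol.objective_value == pytest.approx(10.0, abs=1e-6)


def test_blocked_chain_zero(chain):
    sol = fba(build_problem(chain.model, bounds_override={"R1": (0.0, 0.0)}))
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_yield_half(yield_half):
    sol = fba(build_problem(yield_half.model))
    assert sol.objective_value == pytest.approx(5.0, abs=1e-6)


def test_infeasible_surfaced_not_silent_zero(chain):
    # force net production out of thin air: uptake closed but export forced
    sol = fba(build_problem(chain.model,
                            bounds_override={"EX_M0": (0.0, 0.0),
                                             "EX_M2": (5.0, 10.0)}))
    assert sol.status == "infeasible"
    assert sol.objective_value is None


def test_steady_state_and_bounds_hold_at_optimum(redundant):
    p = build_problem(redundant.model)
    sol = fba(p)
    v = np.array([sol.fluxes[r] for r in p.reaction_ids])
    assert np.max(np.abs(p.S @ v)) < 1e-6
    assert np.all(v >= p.lb - 1e-6) and np.all(v <= p.ub + 1e-6)


@pytest.mark.parametrize(
    "topology", ["chain", "branch", "yield_half", "compartmented", "redundant_routes"]
)
def test_fba_matches_vertex_enumeration_oracle(topology, vertex_oracle):
    fx = make_model(FixtureSpec(topology, n=3, ub=10.0))
    p = build_problem(fx.model)
    assert p.S.shape[1] <= 15
    expected = vertex_oracle(p.S.toarray(), p.lb, p.ub, p.c, p.sense)
    got = fba(p).objective_value
    assert got == pytest.approx(expected, abs=1e-6)
    assert got == pytest.approx(fx.truth["optimum"], abs=1e-6)


@pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
def test_scaling_all_bounds_scales_optimum(yield_half, k):
    m = yield_half.model
    override = {r.id: (r.lower_bound * k, r.upper_bound * k)
                for r in m.reactions.values()}
    sol = fba(build_problem(m, bounds_override=override))
    assert sol.objective_value == pytest.approx(5.0 * k, rel=1e-6)


# ---------------------------------------------------------------------------
# pFBA


def test_pfba_prefers_short_route(redundant):
    sol = pfba(build_problem(redundant.model))
    assert sol.ok
    # enumerate the two route-pure solutions at full uptake: total |v| is
    # 4*ub on the short route, 5*ub on the long one
    short_total, long_total = 40.0, 50.0
    assert total_flux(sol) == pytest.approx(short_total, rel=1e-4)
    assert total_flux(sol) < long_total
    for rid in redundant.truth["long_route"]:
        assert sol.fluxes[rid] == pytest.approx(0.0, abs=1e-6)


def test_pfba_dominance_on_all_fixtures():
    for topology in ("chain", "branch", "yield_half", "compartmented",
                     "redundant_routes"):
        p = build_problem(make_model(FixtureSpec(topology)).model)
        a, b = fba(p), pfba(p)
        assert b.objective_value >= a.objective_value * (1 - 1e-6) - 1e-9
        assert total_flux(b) <= total_flux(a) + 1e-6


def test_pfba_single_route_equals_fba(chain):
    p = build_problem(chain.model)
    a, b = fba(p), pfba(p)
    for rid in p.reaction_ids:
        assert b.fluxes[rid] == pytest.approx(a.fluxes[rid], abs=1e-4)


def test_pfba_zero_objective_all_zero(chain):
    p = build_problem(chain.model, objective={})
    sol = pfba(p)
    assert sol.ok
    assert total_flux(sol) == pytest.approx(0.0, abs=1e-6)


# ---------------------------------------------------------------------------
# knockouts


def test_or_gpr_survives_single_deletion():
    m = MetabolicModel(id="ko")
    m.add_compartment(Compartment("c"))
    m.add_metabolite(Metabolite("A", "c"))
    m.add_reaction(Reaction("R", {"A": -1.0}, 0, 10, gpr=parse_gpr("g1 or g3")))
    assert apply_deletions(m, {"g3"}) == {}
    assert apply_deletions(m, {"g1", "g3"}) == {"R": (0.0, 0.0)}


def test_single_gene_gpr_disabled():
    m = MetabolicModel(id="ko")
    m.add_compartment(Compartment("c"))
    m.add_metabolite(Metabolite("A", "c"))
    m.add_reaction(Reaction("R", {"A": -1.0}, 0, 10, gpr=parse_gpr("g1")))
    assert apply_deletions(m, {"g1"}) == {"R": (0.0, 0.0)}


def test_unknown_gene_id_is_an_error(chain):
    with pytest.raises(KeyError, match="nonexistent"):
        apply_deletions(chain.model, {"nonexistent"})


def test_deleting_empty_set_is_identity(chain):
    p0 = fba(build_problem(chain.model)).objective_value
    overrides = apply_deletions(chain.model, set())
    assert overrides == {}
    p1 = fba(build_problem(chain.model, bounds_override=overrides)).objective_value
    assert p1 == pytest.approx(p0, abs=1e-9)


def test_deleting_unused_gene_leaves_optimum(chain):
    from evigem.model import Gene

    chain.model.add_gene(Gene("bystander"))
    overrides = apply_deletions(chain.model, {"bystander"})
    sol = fba(build_problem(chain.model, bounds_override=overrides))
    assert sol.objective_value == pytest.approx(10.0, abs=1e-6)


def test_empty_gpr_reactions_never_disabled(chain):
    # every gene deleted: boundary reactions (no genes) remain open
    all_genes = set(chain.model.genes)
    overrides = apply_deletions(chain.model, all_genes)
    assert "EX_M0" not in overrides and "EX_M2" not in overrides


# ---------------------------------------------------------------------------
# cross-check against cobrapy (independent implementation)


def test_fba_and_pfba_agree_with_cobrapy(tmp_path, redundant):
    cobra = pytest.importorskip("cobra")
    from evigem.sbml_io import write_sbml

    path = tmp_path / "redundant.xml"
    write_sbml(redundant.model, str(path))
    cm = cobra.io.read_sbml_model(str(path))
    cm.objective = "EX_B"
    ours = fba(build_problem(redundant.model))
    theirs = cm.optimize()
    assert ours.objective_value == pytest.approx(theirs.objective_value, abs=1e-5)
    from cobra.flux_analysis import pfba as cobra_pfba

    ours_p = pfba(build_problem(redundant.model))
    theirs_p = cobra_pfba(cm)
    assert total_flux(ours_p) == pytest.approx(
        float(theirs_p.fluxes.abs().sum()), rel=1e-3
    )
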