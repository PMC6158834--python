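"""Pathway expression profiles and co-expression scoring."""

import numpy as np
import pandas as pd
import pytest

from evigem.expression import (
    ExpressionMatrix,
    coexpression_score,
    pathway_change_profile,
    pathway_members,
)
from evigem.fixtures import FixtureSpec, make_model
from evigem.gpr import parse_gpr
from evigem.model import Gene, Reaction


@pytest.fixture
def pathway_model(chain):
    m = chain.model
    # pathway P: two reactions with GPRs "g1" and "g2 or g3"
    m.reactions["R1"].subsystem = "P"
    m.reactions["R2"].subsystem = "P"
    m.reactions["R2"].gpr = parse_gpr("g2 or g3")
    m.add_gene(Gene("g3"))
    return m


def _matrix(data, conditions):
    return ExpressionMatrix(pd.DataFrame(data, columns=conditions))


def test_members_union_of_gpr_leaves(pathway_model):
    assert pathway_members(pathway_model, "P") == {"g1", "g2", "g3"}


def test_gene_less_pathway_empty(pathway_model):
    pathway_model.reactions["EX_M0"].subsystem = "Exchange"
    assert pathway_members(pathway_model, "Exchange") == set()


def test_shared_gene_in_two_pathways(pathway_model):
    pathway_model.reactions["R2"].subsystem = "Q"
    pathway_model.reactions["R2"].gpr = parse_gpr("g1 or g2")
    assert "g1" in pathway_members(pathway_model, "P")
    assert "g1" in pathway_members(pathway_model, "Q")


def test_unknown_pathway_label(pathway_model):
    with pytest.raises(KeyError):
        pathway_members(pathway_model, "Nonexistent")


def test_flat_expression_zero_changes(pathway_model):
    expr = _matrix({"glc": [5.0, 6.0, 7.0], "xyl": [5.0, 6.0, 7.0]},
                   conditions=None)
    expr.values.index = ["g1", "g2", "g3"]
    expr.values.columns = ["glc", "xyl"]
    profile = pathway_change_profile(pathway_model, expr, "P", "xyl", "glc")
    assert all(v == 0.0 for v in profile.changes.values())


def test_shifted_pathway_median_two(pathway_model):
    df = pd.DataFrame({"glc": [5.0, 6.0, 7.0], "xyl": [7.0, 8.0, 9.0]},
                      index=["g1", "g2", "g3"])
    profile = pathway_change_profile(pathway_model, ExpressionMatrix(df), "P",
                                     "xyl", "glc")
    assert profile.median() == pytest.approx(2.0)


def test_mixed_changes_equal_hand_computed_differences(pathway_model):
    rng = np.random.default_rng(11)
    df = pd.DataFrame(rng.normal(8, 1, size=(3, 4)),
                      index=["g1", "g2", "g3"],
                      columns=["ref", "c1", "c2", "c3"])
    profile = pathway_change_profile(pathway_model, ExpressionMatrix(df), "P",
                                     "c2", "ref")
    for g in ("g1", "g2", "g3"):
        assert profile.changes[g] == pytest.approx(df.at[g, "c2"] - df.at[g, "ref"])


def test_missing_genes_reported_not_imputed(pathway_model):
    df = pd.DataFrame({"ref": [1.0], "c": [3.0]}, index=["g1"])
    profile = pathway_change_profile(pathway_model, ExpressionMatrix(df), "P",
                                     "c", "ref")
    assert profile.missing_genes == ["g2", "g3"]
    assert set(profile.changes) == {"g1"}


def test_reference_vs_itself_identically_zero(pathway_model):
    df = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 3)),
                      index=["g1", "g2", "g3"], columns=["a", "b", "c"])
    profile = pathway_change_profile(pathway_model, ExpressionMatrix(df), "P",
                                     "b", "b")
    assert all(v == 0.0 for v in profile.changes.values())


def test_profiles_invariant_under_condition_reordering(pathway_model):
    df = pd.DataFrame(np.random.default_rng(1).normal(size=(3, 3)),
                      index=["g1", "g2", "g3"], columns=["a", "b", "c"])
    p1 = pathway_change_profile(pathway_model, ExpressionMatrix(df), "P", "c", "a")
    p2 = pathway_change_profile(pathway_model,
                                ExpressionMatrix(df[["c", "a", "b"]]), "P", "c", "a")
    assert p1.changes == p2.changes


def test_duplicate_gene_ids_rejected():
    df = pd.DataFrame({"a": [1, 2]}, index=["g1", "g1"])
    with pytest.raises(ValueError, match="duplicate"):
        ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# co-expression


def _profiles(n_conditions=10, seed=2):
    rng = np.random.default_rng(seed)
    cols = [f"c{i}" for i in range(n_conditions)]
    return {f"m{i}": pd.Series(rng.normal(size=n_conditions), index=cols)
            for i in range(4)}, cols


def test_identical_profile_r_one():
    members, cols = _profiles()
    res = coexpression_score(members["m0"].copy(), {"m0": members["m0"]})
    assert res.correlations["m0"] == pytest.approx(1.0)


def test_negated_profile_r_minus_one():
    members, _ = _profiles()
    res = coexpression_score(-members["m1"], {"m1": members["m1"]})
    assert res.correlations["m1"] == pytest.approx(-1.0)


def test_random_profiles_match_textbook_formula():
    members, cols = _profiles(n_conditions=10, seed=9)
    candidate = pd.Series(np.random.default_rng(10).normal(size=10), index=cols)
    res = coexpression_score(candidate, members)
    for name, profile in members.items():
        x, y = candidate.to_numpy(), profile.to_numpy()
        n = len(x)
        expected = ((n * (x * y).sum() - x.sum() * y.sum())
                    / np.sqrt((n * (x ** 2).sum() - x.sum() ** 2)
                              * (n * (y ** 2).sum() - y.sum() ** 2)))
        assert res.correlations[name] == pytest.approx(expected, abs=1e-12)
    assert res.mean_correlation == pytest.approx(
        np.mean(list(res.correlations.values())))


def test_zero_variance_profile_undefined():
    members, cols = _profiles()
    flat = pd.Series(np.ones(10), index=cols)
    res = coexpression_score(members["m0"], {"flat": flat})
    assert res.correlations["flat"] is None
    assert res.mean_correlation is None


def test_affine_rescaling_invariance():
    members, cols = _profiles(seed=4)
    candidate = members["m2"]
    base = coexpression_score(candidate, {"m3": members["m3"]})
    scaled = coexpression_score(3.5 * candidate + 2.0,
                                {"m3": -0.5 * members["m3"] + 7.0})
    assert abs(scaled.correlations["m3"]) == pytest.approx(
        abs(base.correlations["m3"]))
    assert scaled.correlations["m3"] == pytest.approx(-base.correlations["m3"])


def test_too_few_conditions_rejected():
    s = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(ValueError, match=">=3"):
        coexpression_score(s, {"m": s})


def test_candidate_coregulated_with_cluster():
    """A candidate tracking a cluster across conditions scores near +1 mean
    correlation — the basis for proposing new cluster members."""
    rng = np.random.default_rng(21)
    cols = [f"c{i}" for i in range(12)]
    signal = rng.normal(0, 2, size=12)
    members = {f"ada{k}": pd.Series(signal + rng.normal(0, 0.1, 12), index=cols)
               for k in "ABC"}
    candidate = pd.Series(signal + rng.normal(0, 0.1, 12), index=cols)
    res = coexpression_score(candidate, members, candidate_name="transporter")
    assert res.mean_correlation > 0.95
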