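"""Executing embedded phenotype test cases against a model.

Each test case is simulated under its own medium: bounds are cloned, every
boundary reaction *not* named in the test's settings is restricted to the
drain direction (uptake closed, secretion open — an unspecified medium
component is absent, but the cell may always excrete), the settings
overrides and gene deletions are applied, and then each outcome's reaction
is *maximized* and the achieved maximum compared to the threshold. That
makes "greater" outcomes capability checks (the model can grow/produce) and
"less" outcomes impossibility certificates (not even the best flux
distribution reaches the threshold — the no-growth phenotype). A test
passes iff every outcome holds; infeasible or unresolvable tests are
reported as *errored*, never silently failed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .evidence import Outcome, TestCase
from .fba import LPBackend, ScipyBackend, apply_deletions, build_problem, fba, pfba
from .model import MetabolicModel, Reaction

__all__ = [
    "OutcomeResult",
    "TestResult",
    "SuiteReport",
    "run_test",
    "run_suite",
    "system_checks",
    "GROWTH_THRESHOLD",
]

#: canonical growth/no-growth flux threshold used when *generating* tests
GROWTH_THRESHOLD = 1e-6

_DEFAULT_BACKEND = ScipyBackend()


@dataclass
class OutcomeResult:
    reaction: str
    cmp: str
    threshold: float
    achieved: Optional[float]
    holds: bool


@dataclass
class TestResult:
    test_id: str
    status: str  # "ok" | "error"
    passed: bool
    outcomes: List[OutcomeResult] = field(default_factory=list)
    notes: List[str] = field(default_factory=list)


@dataclass
class SuiteReport:
    run: int
    passed: int
    failed: int
    errored: int
    results: List[TestResult] = field(default_factory=list)
    #: free-text failure categorization (test id -> label, e.g.
    #: "unknown pathway" / "experimental inconsistency" / "undetermined")
    failure_tags: Dict[str, str] = field(default_factory=dict)

    def tag_failure(self, test_id: str, label: str) -> None:
        self.failure_tags[test_id] = label


def _drain_bounds(r: Reaction, model: MetabolicModel) -> Tuple[float, float]:
    """Intersect a boundary reaction's bounds with its drain half-space.

    The drain direction is the one that removes the internal metabolite
    from the system, read off the sign of its stoichiometric coefficient
    (handles both one-sided and explicit-external encodings).
    """
    internal = [
        m for m in r.stoichiometry
        if m in model.metabolites and not model.metabolites[m].is_boundary_species
    ]
    coeff = r.stoichiometry[internal[0]] if internal else -1.0
    if coeff < 0:  # positive flux consumes the metabolite
        return max(r.lower_bound, 0.0), max(r.upper_bound, 0.0)
    return min(r.lower_bound, 0.0), min(r.upper_bound, 0.0)


def _test_bounds(
    model: MetabolicModel, test: TestCase
) -> Tuple[Dict[str, Tuple[float, float]], List[str]]:
    """Medium + knockout bounds for one test; returns (overrides, problems)."""
    problems: List[str] = []
    overrides: Dict[str, Tuple[float, float]] = {}
    specified = {rid for rid, _, _ in test.settings}
    for r in model.boundary_reactions():
        if r.id not in specified:
            overrides[r.id] = _drain_bounds(r, model)
    for rid, lb, ub in test.settings:
        if rid not in model.reactions:
            problems.append(f"setting references unknown reaction {rid!r}")
            continue
        overrides[rid] = (lb, ub)
    try:
        deletions = apply_deletions(model, set(test.deleted_genes))
    except KeyError as exc:
        problems.append(str(exc))
        deletions = {}
    for rid, bounds in deletions.items():
        overrides[rid] = bounds  # knockout wins over medium
    return overrides, problems


def run_test(
    model: MetabolicModel,
    test: TestCase,
    method: str = "fba",
    backend: LPBackend = _DEFAULT_BACKEND,
) -> TestResult:
    """Simulate one test case; method "fba" (default) or "pfba", with the
    test's own ``method`` field taking precedence."""
    method = test.method or method
    if method not in ("fba", "pfba"):
        raise ValueError(f"unknown simulation method {method!r}")
    overrides, problems = _test_bounds(model, test)
    for out in test.outcomes:
        if out.reaction not in model.reactions:
            problems.append(f"outcome references unknown reaction {out.reaction!r}")
    if problems:
        return TestResult(test.id, status="error", passed=False, notes=problems)

    solve = pfba if method == "pfba" else fba
    results: List[OutcomeResult] = []
    notes: List[str] = []
    for out in test.outcomes:
        problem = build_problem(
            model, objective={out.reaction: 1.0}, sense="maximize",
            bounds_override=overrides,
        )
        sol = solve(problem, backend)
        if not sol.ok:
            notes.append(f"outcome {out.reaction}: LP {sol.status}")
            return TestResult(test.id, status="error", passed=False,
                              outcomes=results, notes=notes)
        achieved = sol.objective_value
        results.append(
            OutcomeResult(out.reaction, out.cmp, out.value, achieved, out.holds(achieved))
        )
    return TestResult(
        test.id,
        status="ok",
        passed=all(r.holds for r in results),
        outcomes=results,
        notes=notes,
    )


def run_suite(
    model: MetabolicModel,
    tests: Sequence[TestCase],
    method: str = "fba",
    backend: LPBackend = _DEFAULT_BACKEND,
) -> SuiteReport:
    """Run all tests (deterministic order: sorted by test id) and tally."""
    results = [
        run_test(model, t, method=method, backend=backend)
        for t in sorted(tests, key=lambda t: t.id)
    ]
    passed = sum(1 for r in results if r.status == "ok" and r.passed)
    errored = sum(1 for r in results if r.status == "error")
    failed = len(results) - passed - errored
    return SuiteReport(
        run=len(results), passed=passed, failed=failed, errored=errored, results=results
    )


# ---------------------------------------------------------------------------
# system checks


def system_checks(
    model: MetabolicModel,
    biomass_reaction: str,
    precursors: Iterable[str] = (),
    medium: Sequence[Tuple[str, float, float]] = (),
    essential_components: Iterable[str] = (),
    capability_reactions: Iterable[str] = (),
    threshold: float = GROWTH_THRESHOLD,
    backend: LPBackend = _DEFAULT_BACKEND,
) -> List[TestResult]:
    """Generated whole-system sanity tests.

    * one check per biomass `precursor` metabolite: with the given medium
      and a temporary drain for the precursor, its maximal production must
      exceed `threshold`;
    * one check per `essential_components` boundary reaction: closing its
      uptake must drive maximal growth below `threshold`;
    * one check per `capability_reactions` id: the reaction must be able to
      carry flux above `threshold` on the medium (e.g. a peroxisomal
      fatty-acid oxidation step).
    """
    if biomass_reaction not in model.reactions:
        raise KeyError(f"biomass reaction {biomass_reaction!r} not in model")
    results: List[TestResult] = []

    for met in precursors:
        check_id = f"syscheck_precursor_{met}"
        if met not in model.metabolites:
            results.append(TestResult(check_id, status="error", passed=False,
                                      notes=[f"unknown metabolite {met!r}"]))
            continue
        work = copy.deepcopy(model)
        drain_id = f"__DM_{met}"
        work.add_reaction(Reaction(
            id=drain_id, stoichiometry={met: -1.0},
            lower_bound=0.0, upper_bound=1000.0, is_boundary=True,
        ))
        test = TestCase(
            id=check_id,
            name=f"biomass precursor {met} producible",
            settings=tuple(medium) + ((drain_id, 0.0, 1000.0),),
            outcomes=(Outcome(drain_id, "greater", threshold),),
        )
        results.append(run_test(work, test, backend=backend))

    for comp in essential_components:
        check_id = f"syscheck_essential_{comp}"
        if comp not in model.reactions:
            results.append(TestResult(check_id, status="error", passed=False,
                                      notes=[f"unknown reaction {comp!r}"]))
            continue
        reduced = tuple((rid, lb, ub) for rid, lb, ub in medium if rid != comp)
        test = TestCase(
            id=check_id,
            name=f"no growth without {comp}",
            settings=reduced,
            outcomes=(Outcome(biomass_reaction, "less", threshold),),
        )
        results.append(run_test(model, test, backend=backend))

    for rid in capability_reactions:
        check_id = f"syscheck_capability_{rid}"
        if rid not in model.reactions:
            results.append(TestResult(check_id, status="error", passed=False,
                                      notes=[f"unknown reaction {rid!r}"]))
            continue
        test = TestCase(
            id=check_id,
            name=f"{rid} can carry flux",
            settings=tuple(medium),
            outcomes=(Outcome(rid, "greater", threshold),),
        )
        results.append(run_test(model, test, backend=backend))

    return results
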