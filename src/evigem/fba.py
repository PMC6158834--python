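"""Flux balance analysis (FBA) and parsimonious FBA (pFBA).

FBA solves the linear program

    max/min  c·v   s.t.  S·v = 0,  lb ≤ v ≤ ub

where S is the stoichiometric matrix over the *internal* (non-boundary)
metabolites — boundary species are exterior pools and impose no
steady-state row. Only the optimal objective value is contractual: FBA
optima are famously degenerate, so returned flux vectors are one optimum
among possibly many.

pFBA fixes the FBA optimum (to within a relative tolerance) and minimizes
total absolute flux Σ|v| by splitting each flux into non-negative forward
and backward parts — the standard parsimony heuristic that prunes futile
cycles and picks the shortest of alternative routes.

The LP backend is pluggable behind :class:`LPBackend`; the default wraps
``scipy.optimize.linprog`` (HiGHS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import optimize, sparse

from .model import MetabolicModel, Reaction

__all__ = [
    "FluxProblem",
    "FluxSolution",
    "LPBackend",
    "ScipyBackend",
    "build_problem",
    "fba",
    "pfba",
    "apply_deletions",
    "FEASIBILITY_TOL",
    "OPTIMALITY_TOL",
]

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-6
#: relative slack when pinning the FBA optimum inside pFBA
PFBA_RELATIVE_SLACK = 1e-6


@dataclass
class FluxProblem:
    """The LP encoding of a model: S·v = 0, bounds, linear objective."""

    S: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    sense: str = "maximize"
    reaction_ids: Tuple[str, ...] = ()
    metabolite_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m, n = self.S.shape
        if not (len(self.lb) == len(self.ub) == len(self.c) == n):
            raise ValueError("inconsistent problem dimensions")
        if np.any(self.lb > self.ub):
            bad = np.nonzero(self.lb > self.ub)[0]
            raise ValueError(f"lb > ub at columns {bad.tolist()}")

    def column(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)


@dataclass
class FluxSolution:
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    objective_value: Optional[float] = None
    fluxes: Optional[Dict[str, float]] = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class LPBackend:
    """Minimal solve contract: matrix, bounds, objective in; status,
    objective, primal out. Subclass to plug a different solver."""

    def solve(
        self,
        A_eq: sparse.spmatrix,
        b_eq: np.ndarray,
        lb: np.ndarray,
        ub: np.ndarray,
        c_min: np.ndarray,
        A_ub: Optional[sparse.spmatrix] = None,
        b_ub: Optional[np.ndarray] = None,
    ) -> Tuple[str, Optional[float], Optional[np.ndarray]]:
        raise NotImplementedError


class ScipyBackend(LPBackend):
    """linprog/HiGHS backend (minimization form)."""

    def solve(self, A_eq, b_eq, lb, ub, c_min, A_ub=None, b_ub=None):
        res = optimize.linprog(
            c_min,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options={
                "primal_feasibility_tolerance": FEASIBILITY_TOL,
                "dual_feasibility_tolerance": OPTIMALITY_TOL,
            },
        )
        if res.status == 0:
            return "optimal", float(res.fun), np.asarray(res.x)
        if res.status == 2:
            return "infeasible", None, None
        if res.status == 3:
            return "unbounded", None, None
        return "error", None, None


_DEFAULT_BACKEND = ScipyBackend()


# ---------------------------------------------------------------------------
# problem construction


def build_problem(
    model: MetabolicModel,
    objective: Optional[Dict[str, float]] = None,
    sense: Optional[str] = None,
    bounds_override: Optional[Dict[str, Tuple[float, float]]] = None,
) -> FluxProblem:
    """Build the steady-state LP: one column per reaction, one row per
    internal metabolite.

    `objective`/`sense` default to the model's; `bounds_override` replaces
    individual reaction bounds without touching the model.
    """
    if not model.reactions:
        raise ValueError("cannot build a flux problem from an empty model")
    reaction_ids = tuple(model.reactions)
    internal = [
        m.id for m in model.metabolites.values() if not m.is_boundary_species
    ]
    row_of = {mid: i for i, mid in enumerate(internal)}
    rows, cols, vals = [], [], []
    lb = np.empty(len(reaction_ids))
    ub = np.empty(len(reaction_ids))
    for j, rid in enumerate(reaction_ids):
        r = model.reactions[rid]
        lo, hi = r.lower_bound, r.upper_bound
        if bounds_override and rid in bounds_override:
            lo, hi = bounds_override[rid]
        lb[j], ub[j] = lo, hi
        for met, coeff in r.stoichiometry.items():
            if met in row_of:
                rows.append(row_of[met])
                cols.append(j)
                vals.append(float(coeff))
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(internal), len(reaction_ids))
    )
    obj = objective if objective is not None else model.objective
    c = np.zeros(len(reaction_ids))
    for rid, w in obj.items():
        c[reaction_ids.index(rid)] = w
    return FluxProblem(
        S=S,
        lb=lb,
        ub=ub,
        c=c,
        sense=sense or model.objective_sense,
        reaction_ids=reaction_ids,
        metabolite_ids=tuple(internal),
    )


# ---------------------------------------------------------------------------
# solving


def fba(problem: FluxProblem, backend: LPBackend = _DEFAULT_BACKEND) -> FluxSolution:
    """Solve the flux LP. Infeasible/unbounded statuses are surfaced,
    never silently returned as zeros."""
    sign = -1.0 if problem.sense == "maximize" else 1.0
    m = problem.S.shape[0]
    status, fun, x = backend.solve(
        problem.S, np.zeros(m), problem.lb, problem.ub, sign * problem.c
    )
    if status != "optimal":
        return FluxSolution(status=status)
    return FluxSolution(
        status="optimal",
        objective_value=sign * fun,
        fluxes=dict(zip(problem.reaction_ids, x)),
    )


def pfba(problem: FluxProblem, backend: LPBackend = _DEFAULT_BACKEND) -> FluxSolution:
    """Parsimonious FBA: pin the FBA optimum, minimize total |flux|.

    Splits v = f − b with f, b ≥ 0 and minimizes Σ(f+b); the reported
    objective_value is the (pinned) original objective and the fluxes are
    the parsimonious vector.
    """
    first = fba(problem, backend)
    if not first.ok:
        return first
    z = first.objective_value

    n = len(problem.reaction_ids)
    S = problem.S.tocsc()
    # variables: [f; b], v = f - b
    A_eq = sparse.hstack([S, -S], format="csr")
    b_eq = np.zeros(S.shape[0])
    lb2 = np.zeros(2 * n)
    ub2 = np.concatenate([np.maximum(problem.ub, 0.0), np.maximum(-problem.lb, 0.0)])
    # original bounds lb <= f - b <= ub
    eye = sparse.eye(n, format="csr")
    bound_rows = sparse.vstack(
        [sparse.hstack([eye, -eye]), sparse.hstack([-eye, eye])], format="csr"
    )
    bound_rhs = np.concatenate([problem.ub, -problem.lb])
    # pin the objective: for maximize, c·v >= (1 - slack)·z (sign-aware)
    slack = PFBA_RELATIVE_SLACK * max(1.0, abs(z))
    cv = np.concatenate([problem.c, -problem.c])
    if problem.sense == "maximize":
        pin_row, pin_rhs = -cv, -(z - slack)
    else:
        pin_row, pin_rhs = cv, z + slack
    A_ub = sparse.vstack([bound_rows, sparse.csr_matrix(pin_row)], format="csr")
    b_ub = np.concatenate([bound_rhs, [pin_rhs]])

    status, fun, x = backend.solve(
        A_eq, b_eq, lb2, ub2, np.ones(2 * n), A_ub=A_ub, b_ub=b_ub
    )
    if status != "optimal":
        return FluxSolution(status=status)
    v = x[:n] - x[n:]
    return FluxSolution(
        status="optimal",
        objective_value=float(problem.c @ v),
        fluxes=dict(zip(problem.reaction_ids, v)),
    )


def total_flux(solution: FluxSolution) -> float:
    """Σ|v| of a solution's flux vector."""
    if solution.fluxes is None:
        raise ValueError("solution carries no flux vector")
    return float(sum(abs(v) for v in solution.fluxes.values()))


# ---------------------------------------------------------------------------
# knockouts


def apply_deletions(
    model: MetabolicModel, genes: Set[str]
) -> Dict[str, Tuple[float, float]]:
    """Bounds overrides implementing a gene-deletion view of the model.

    Every reaction whose GPR evaluates inactive under `genes` gets bounds
    (0, 0); reactions with empty GPRs are never disabled. Unknown gene ids
    raise — a silent no-op knockout would fake a phenotype.
    """
    unknown = sorted(g for g in genes if g not in model.genes)
    if unknown:
        raise KeyError(f"unknown gene ids: {unknown}")
    overrides: Dict[str, Tuple[float, float]] = {}
    for r in model.reactions.values():
        if not r.gpr.evaluate(genes):
            overrides[r.id] = (0.0, 0.0)
    return overrides
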