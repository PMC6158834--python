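import itertools

import numpy as np
import pytest

from evigem.fixtures import FixtureSpec, make_model, make_suite


@pytest.fixture
def chain():
    return make_model(FixtureSpec("chain", n=3, ub=10.0))


@pytest.fixture
def yield_half():
    return make_model(FixtureSpec("yield_half", ub=10.0))


@pytest.fixture
def branch():
    return make_model(FixtureSpec("branch", ub=10.0))


@pytest.fixture
def compartmented():
    return make_model(FixtureSpec("compartmented", ub=10.0))


@pytest.fixture
def redundant():
    return make_model(FixtureSpec("redundant_routes", ub=10.0))


@pytest.fixture
def dead_end_3():
    return make_model(FixtureSpec("dead_end_k", n=3, ub=10.0))


@pytest.fixture
def chain_suite(chain):
    evidences, tests = make_suite(chain, n_pass=3, n_fail=1, seed=0)
    return chain.model, evidences, tests


# ---------------------------------------------------------------------------
# independent LP oracle: brute-force vertex enumeration
#
# A vertex of {S v = 0, lb <= v <= ub} fixes n - rank(S) variables at a
# bound; enumerate all such choices, solve the resulting linear system,
# keep feasible points, and take the best objective. Exponential, so only
# for the tiny fixture networks — but entirely independent of any LP
# solver.


def vertex_enumeration_optimum(S, lb, ub, c, sense="maximize"):
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    best = None
    tol = 1e-8
    for fixed_idx in itertools.combinations(range(n), k):
        for bounds_choice in itertools.product((0, 1), repeat=k):
            fixed_vals = np.array(
                [lb[i] if b == 0 else ub[i] for i, b in zip(fixed_idx, bounds_choice)]
            )
            if not np.all(np.isfinite(fixed_vals)):
                continue
            A = np.vstack([S] + [np.eye(n)[list(fixed_idx)]]) if k else S
            b = np.concatenate([np.zeros(m), fixed_vals]) if k else np.zeros(m)
            x, residuals, rk, _ = np.linalg.lstsq(A, b, rcond=None)
            if rk < n:
                continue
            if np.linalg.norm(A @ x - b) > tol:
                continue
            if np.any(x < lb - tol) or np.any(x > ub + tol):
                continue
            val = float(c @ x)
            if best is None:
                best = val
            elif sense == "maximize":
                best = max(best, val)
            else:
                best = min(best, val)
    return best


@pytest.fixture
def vertex_oracle():
    return vertex_enumeration_optimum
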