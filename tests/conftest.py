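"""Shared fixtures: toy models, a global LP-solution invariant hook, oracles.

Every optimal flux vector produced anywhere in the suite is checked against
the steady-state constraint (||S.v||_inf <= 1e-6) and the box constraints
(within 1e-6) by an autouse hook, so no test can silently accept a flux
vector that violates the model.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import null_space
from scipy.optimize import linprog

from fluxspan import flux as flux_module
from fluxspan.model import Model
from fluxspan.synthetic import ToyNetworkSpec, make_toy_network

INVARIANT_TOL = 1e-6


class SolutionRecorder:
    """Collects every optimal LP solution and asserts feasibility invariants."""

    def __init__(self) -> None:
        self.count = 0
        self.max_residual = 0.0
        self.max_bound_violation = 0.0

    def __call__(self, S, lower, upper, x, context) -> None:
        residual = float(np.max(np.abs(S @ x))) if S.size else 0.0
        violation = float(
            max(np.max(lower - x, initial=0.0), np.max(x - upper, initial=0.0))
        )
        self.count += 1
        self.max_residual = max(self.max_residual, residual)
        self.max_bound_violation = max(self.max_bound_violation, violation)
        assert residual <= INVARIANT_TOL, f"steady-state violated in {context}: {residual:.2e}"
        assert violation <= INVARIANT_TOL, f"bounds violated in {context}: {violation:.2e}"


@pytest.fixture(autouse=True)
def solution_invariants():
    recorder = SolutionRecorder()
    flux_module.register_solution_hook(recorder)
    try:
        yield recorder
    finally:
        flux_module.unregister_solution_hook(recorder)


@pytest.fixture
def chain_model() -> Model:
    return make_toy_network(ToyNetworkSpec(kind="chain"))


@pytest.fixture
def branch_model() -> Model:
    return make_toy_network(ToyNetworkSpec(kind="branch"))


@pytest.fixture
def diamond_model() -> Model:
    return make_toy_network(ToyNetworkSpec(kind="diamond"))


# ---------------------------------------------------------------------------
# Independent FVA oracle: null-space parameterization
# ---------------------------------------------------------------------------


def nullspace_fva(model: Model, tol: float = 1e-9) -> dict[str, tuple[float, float]]:
    """Per-reaction flux extrema via a different LP formulation than run_fva.

    The flux polytope {S.v = 0, lb <= v <= ub} is parameterized as v = N.z
    with N a basis of null(S); each reaction's flux is then optimized over z
    subject to lb <= N.z <= ub expressed as pure inequality rows (no equality
    constraints and no per-variable bounds reach the solver).
    """
    S = model.stoichiometric_matrix()
    lower, upper = model.bounds_arrays()
    N = null_space(S)
    out: dict[str, tuple[float, float]] = {}
    if N.size == 0:
        # only v = 0 is steady-state-feasible; it must satisfy the box
        assert (lower <= tol).all() and (upper >= -tol).all()
        return {rid: (0.0, 0.0) for rid in model.reaction_ids}
    A_ub = np.vstack([N, -N])
    b_ub = np.concatenate([upper, -lower])
    for j, rid in enumerate(model.reaction_ids):
        bounds = [(None, None)] * N.shape[1]
        lo = linprog(N[j], A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
        hi = linprog(-N[j], A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
        assert lo.status == 0 and hi.status == 0, f"oracle LP failed for {rid}"
        out[rid] = (float(lo.fun), float(-hi.fun))
    return out


@pytest.fixture
def fva_oracle():
    return nullspace_fva
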