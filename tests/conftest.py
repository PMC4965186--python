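"""Shared fixtures and independent oracles.

The vertex-enumeration oracle solves the steady-state polytope
{S v = 0, lb <= v <= ub} by brute force: every vertex has at least
n - rank(S) coordinates pinned at a bound, so enumerating pinned subsets
and bound assignments and solving the remaining square system recovers
every vertex exactly. LP answers (FBA objective values, FVA endpoints)
are then max/min over vertices — computed without any LP code.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import varflux as vf


@pytest.fixture(scope="session")
def toy_gem():
    return vf.make_toy_gem()


@pytest.fixture(scope="session")
def mini_rbc():
    return vf.make_mini_rbc()


@pytest.fixture(scope="session")
def mini_rbc_modules():
    return vf.make_mini_rbc_with_modules()


@pytest.fixture()
def cfg():
    return vf.AnalysisConfig(rng_seed=1234)


def make_toy_chain(r1_ub: float = 1000.0, r1_lb: float = 0.0) -> vf.MetabolicModel:
    """EX_A (uptake of A), R1: A -> B, EX_B (secretion of B)."""
    return vf.MetabolicModel(
        model_id="chain",
        metabolites=[vf.Metabolite("A", "", "c"), vf.Metabolite("B", "", "c")],
        reactions=[
            vf.Reaction("EX_A", {"A": -1}, -10.0, 0.0, "", True),
            vf.Reaction("R1", {"A": -1, "B": 1}, r1_lb, r1_ub, "g1"),
            vf.Reaction("EX_B", {"B": -1}, 0.0, 1000.0, "", True),
        ],
    )


@pytest.fixture()
def toy_chain():
    return make_toy_chain()


def make_branched_fixture() -> vf.MetabolicModel:
    """A 6-reaction branched network with a bounded polytope.

    A is taken up, split into two branches (one capped), rejoined into B
    which is secreted: enough structure for nontrivial FVA ranges.
    """
    return vf.MetabolicModel(
        model_id="branched",
        metabolites=[
            vf.Metabolite("A", "", "c"),
            vf.Metabolite("X", "", "c"),
            vf.Metabolite("Y", "", "c"),
            vf.Metabolite("B", "", "c"),
        ],
        reactions=[
            vf.Reaction("EX_A", {"A": -1}, -8.0, 0.0, "", True),
            vf.Reaction("R_AX", {"A": -1, "X": 1}, 0.0, 6.0, "g1"),
            vf.Reaction("R_AY", {"A": -1, "Y": 1}, 0.0, 4.0, "g2"),
            vf.Reaction("R_XB", {"X": -1, "B": 1}, 0.0, 10.0, "g3"),
            vf.Reaction("R_YB", {"Y": -1, "B": 1}, -2.0, 10.0, "g4"),
            vf.Reaction("EX_B", {"B": -1}, 0.0, 9.0, "", True),
        ],
    )


@pytest.fixture()
def branched():
    return make_branched_fixture()


def enumerate_vertices(model: vf.MetabolicModel, tol: float = 1e-9) -> np.ndarray:
    """All vertices of {S v = 0, lb <= v <= ub}, by brute force."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    n_pin = n - rank
    vertices = []
    for pinned in itertools.combinations(range(n), n_pin):
        free = [j for j in range(n) if j not in pinned]
        A = S[:, free]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in pinned]):
            rhs = -S[:, pinned] @ np.array(bounds_choice)
            sol, residuals, rk, _ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.empty(n)
            v[list(pinned)] = bounds_choice
            v[free] = sol
            if np.abs(S @ v).max() > 1e-7:
                continue
            if (v < lb - tol).any() or (v > ub + tol).any():
                continue
            vertices.append(np.clip(v, lb, ub))
    assert vertices, "polytope has no vertices (unbounded or infeasible?)"
    uniq: list[np.ndarray] = []
    for row in vertices:
        if not any(np.abs(row - u).max() < 1e-6 for u in uniq):
            uniq.append(row)
    return np.array(uniq)
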