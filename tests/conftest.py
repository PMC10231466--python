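"""Shared fixtures: the synthetic core model, the assembled and constrained
tissue, its parsimonious solution, and small LP test helpers."""

import itertools

import numpy as np
import pytest

import phloemflux as pf
from phloemflux.metnet_core import MetabolicModel, Metabolite, Reaction
from phloemflux.tissue_assembler import TissueModel


@pytest.fixture(scope="session")
def core():
    return pf.make_toy_core_model(pf.ToyModelSpec(seed=0))


@pytest.fixture(scope="session")
def ratios():
    return pf.CellRatios()


@pytest.fixture(scope="session")
def tissue(core):
    t = pf.assemble_tissue(core)
    pf.apply_standard_constraints(t)
    return t


@pytest.fixture()
def tissue_copy(tissue):
    return tissue.copy()


@pytest.fixture(scope="session")
def pfba_solution(tissue):
    sol = pf.parsimonious_solve(tissue)
    assert sol.optimal, sol.message
    return sol


# ---------------------------------------------------------------------------
# Tiny hand-built tissues for oracle tests
# ---------------------------------------------------------------------------


def make_mini_tissue(metabolite_specs, reaction_specs, phloem_id=None, couplings=()):
    """Build a minimal TissueModel from raw specs.

    ``metabolite_specs``: list of (id, name, compartment);
    ``reaction_specs``: list of (id, stoich, lb, ub, tags, cell, phase).
    """
    model = MetabolicModel(id="mini")
    for mid, name, comp in metabolite_specs:
        model.add_metabolite(Metabolite(mid, name=name, compartment=comp))
    tissue = TissueModel(model=model, cell_specs=[])
    for rid, stoich, lb, ub, tags, cell, phase in reaction_specs:
        model.add_reaction(
            Reaction(rid, stoichiometry=dict(stoich), lower_bound=lb,
                     upper_bound=ub, tags=set(tags) | {"exchange"})
        )
        origin = "phloem_export" if rid == phloem_id else "core"
        tissue._register(rid, cell, phase, origin)
    for coupling in couplings:
        tissue.couplings.append(coupling)
    return tissue


def enumerate_vertices(S, lb, ub, tol=1e-8):
    """All vertices of {v : S v = 0, lb <= v <= ub} by basis enumeration.

    Exponential — only for toy systems with <= 8 reactions.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if S.size else 0
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    vertices = []

    def push(v):
        if np.all(np.abs(S @ v) <= tol) and np.all(v >= lb - tol) and np.all(v <= ub + tol):
            for w in vertices:
                if np.allclose(w, v, atol=1e-7):
                    return
            vertices.append(v)

    for basis in itertools.combinations(range(n), rank):
        B = S[:, basis]
        if rank and np.linalg.matrix_rank(B) < rank:
            continue
        nonbasis = [j for j in range(n) if j not in basis]
        for choice in itertools.product(*[(lb[j], ub[j]) for j in nonbasis]):
            v = np.zeros(n)
            for j, val in zip(nonbasis, choice):
                v[j] = val
            if rank:
                rhs = -S[:, nonbasis] @ np.array(choice) if nonbasis else np.zeros(m)
                x, *_ = np.linalg.lstsq(B, rhs, rcond=None)
                v[list(basis)] = x
            push(v)
    return vertices
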