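"""Shared builders and session fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from interdct.structure import (
    Atom,
    Chain,
    ONE_TO_THREE,
    Residue,
    ResidueKey,
    StructureModel,
)


def atom(coords, name="CA", element="C", radius=1.7, serial=1, occupancy=1.0, altloc=""):
    return Atom(
        serial=serial,
        name=name,
        element=element,
        coords=np.asarray(coords, dtype=float),
        occupancy=occupancy,
        altloc=altloc,
        vdw_radius=radius,
    )


def residue(chain_id, number, atoms, name="ALA", icode=""):
    return Residue(key=ResidueKey(chain_id, number, icode, name), atoms=list(atoms))


def point_structure(points_by_chain, radius=1.7, structure_id="toy"):
    """One CA atom per residue at each given point, grouped by chain."""
    chains = []
    for chain_id, points in points_by_chain.items():
        residues = [
            residue(chain_id, i + 1, [atom(p, radius=radius, serial=i + 1)])
            for i, p in enumerate(points)
        ]
        chains.append(Chain(id=chain_id, residues=residues))
    return StructureModel(id=structure_id, chains=chains)


def sequence_chain(sequence, chain_id="A", spacing=5.0, zig=0.3):
    """A bead chain whose residue names encode the given sequence."""
    residues = []
    for i, letter in enumerate(sequence):
        xyz = np.array([i * spacing, 0.0, zig * (1 if i % 2 == 0 else -1)])
        residues.append(
            residue(chain_id, i + 1, [atom(xyz, serial=i + 1)], name=ONE_TO_THREE[letter])
        )
    return StructureModel(id=f"seq_{sequence[:6]}", chains=[Chain(id=chain_id, residues=residues)])


def voronoi_facet_exists(points, i, j, tol=1e-9, box=1e4):
    """Independent oracle: do the Voronoi cells of points i and j share a facet?

    The shared facet is the polytope {x : |x-pi| = |x-pj| <= |x-pk| for all k},
    whose (strict) non-emptiness is a linear-programming feasibility question:
    maximise the slack delta subject to the bisector equality and the linear
    dominance inequalities.
    """
    import numpy as np
    from scipy.optimize import linprog

    points = np.asarray(points, dtype=float)
    pi, pj = points[i], points[j]
    a_eq = np.hstack([2 * (pj - pi), [0.0]]).reshape(1, 4)
    b_eq = [float(pj @ pj - pi @ pi)]
    a_ub, b_ub = [], []
    for k in range(len(points)):
        if k in (i, j):
            continue
        pk = points[k]
        # |x - pi|^2 <= |x - pk|^2 - delta  <=>  2(pk - pi).x + delta <= |pk|^2 - |pi|^2
        a_ub.append(np.hstack([2 * (pk - pi), [1.0]]))
        b_ub.append(float(pk @ pk - pi @ pi))
    res = linprog(
        c=[0, 0, 0, -1],
        A_ub=np.array(a_ub), b_ub=np.array(b_ub),
        A_eq=a_eq, b_eq=b_eq,
        bounds=[(-box, box)] * 3 + [(None, None)],
        method="highs",
    )
    return res.status == 0 and res.x[3] > tol


@pytest.fixture(scope="session")
def family():
    """A 3-group, 12-template synthetic library (seed 1)."""
    from interdct.synthetic import FixtureSpec, generate_family

    return generate_family(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def query_context(family):
    """A group-1 query plus its prediction context over the family library."""
    from interdct.library import PredictionContext
    from interdct.synthetic import make_query

    query, truth = make_query(family, group=1, seed=42)
    context = PredictionContext(family.library, query)
    return context, truth
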