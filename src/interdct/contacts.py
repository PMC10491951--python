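"""Interface residue detection via Voronoi tessellation plus a distance test.

Two atoms of different chains are in contact when (a) their Voronoi cells
share a facet — equivalently, they are joined by a Delaunay edge in the
tessellation of all subject+partner atoms — and (b) their distance is
strictly below the sum of their van der Waals radii plus the diameter of a
solvent molecule (default 2.8 Å).  A residue belongs to the interface when
at least one of its atoms is in contact with the other side.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np

from .structure import Atom, ResidueKey, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "ContactParams",
    "InterfaceDefinition",
    "jitter_coords",
    "delaunay_facet_pairs",
    "detect_interface",
]


@dataclass(frozen=True)
class ContactParams:
    """Parameters of the atomic contact criterion."""

    solvent_diameter: float = 2.8
    probe_radius: float = 1.4
    #: optional hook (atom_a, atom_b) -> bool filtering contacts by atom-class
    #: compatibility; None accepts every heavy-atom pair.
    compatibility_filter: Callable[[Atom, Atom], bool] | None = None

    def __post_init__(self) -> None:
        if self.solvent_diameter <= 0:
            raise ValueError("solvent_diameter must be positive")


@dataclass(frozen=True)
class InterfaceDefinition:
    """A set of interface residues on one chain of a protein."""

    protein_id: str
    subject_chain: str
    partner_chains: frozenset[str]
    residues: frozenset[ResidueKey]

    def sorted_residues(self) -> list[ResidueKey]:
        return sorted(self.residues)

    def write_tsv(self, path: str | Path) -> None:
        lines = ["chain\tresnum\ticode\tresname"]
        for key in self.sorted_residues():
            lines.append(
                f"{key.chain_id}\t{key.seq_number}\t{key.insertion_code}\t{key.residue_name}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def jitter_coords(coords: np.ndarray, scale: float = 1e-6, seed: int = 0) -> np.ndarray:
    """Deterministic sub-numerical jitter to break degenerate tessellations."""
    rng = np.random.default_rng(seed)
    return coords + rng.uniform(-scale, scale, size=coords.shape)


def delaunay_facet_pairs(coords: np.ndarray) -> set[tuple[int, int]]:
    """Index pairs whose Voronoi cells share a facet (Delaunay edges).

    Inputs with fewer than 5 points fall back to the complete pair set.
    Coordinates are jittered deterministically before tessellation so
    coplanar/collinear inputs do not fail.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        return set()
    if n < 5:
        logger.debug("tessellation fallback to all pairs for %d atoms", n)
        return {(i, j) for i, j in itertools.combinations(range(n), 2)}
    from scipy.spatial import Delaunay, QhullError

    jittered = jitter_coords(coords)
    try:
        tri = Delaunay(jittered)
    except QhullError:
        tri = Delaunay(jitter_coords(coords, scale=1e-3, seed=1))
    pairs: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for i, j in itertools.combinations(simplex.tolist(), 2):
            pairs.add((i, j) if i < j else (j, i))
    return pairs


def detect_interface(
    model: StructureModel,
    subject_chain: str,
    partner_chains: Iterable[str],
    params: ContactParams | None = None,
) -> tuple[InterfaceDefinition, InterfaceDefinition]:
    """Interface residues of ``subject_chain`` against ``partner_chains``.

    Returns the subject-side and partner-side interface definitions, both
    derived from the same symmetric atomic contact set.
    """
    params = params or ContactParams()
    partner_chains = frozenset(partner_chains)
    if subject_chain in partner_chains:
        raise ValueError("subject and partner chain sets overlap")

    entries: list[tuple[ResidueKey, Atom, bool]] = []  # (owner, atom, is_subject)
    for key, atom in model.atoms([subject_chain]):
        entries.append((key, atom, True))
    for key, atom in model.atoms(partner_chains):
        entries.append((key, atom, False))
    if not any(e[2] for e in entries) or all(e[2] for e in entries):
        raise KeyError("both subject and partner chains must contain atoms")

    coords = np.asarray([e[1].coords for e in entries], dtype=float)
    radii = np.asarray(
        [e[1].vdw_radius if e[1].vdw_radius is not None else _radii_error() for e in entries],
        dtype=float,
    )
    facet_pairs = delaunay_facet_pairs(coords)

    subject_hits: set[ResidueKey] = set()
    partner_hits: set[ResidueKey] = set()
    for i, j in facet_pairs:
        key_i, atom_i, subj_i = entries[i]
        key_j, atom_j, subj_j = entries[j]
        if subj_i == subj_j:
            continue
        cutoff = radii[i] + radii[j] + params.solvent_diameter
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        if not dist < cutoff:
            continue
        if params.compatibility_filter is not None and not params.compatibility_filter(
            atom_i, atom_j
        ):
            continue
        if subj_i:
            subject_hits.add(key_i)
            partner_hits.add(key_j)
        else:
            subject_hits.add(key_j)
            partner_hits.add(key_i)

    subject_iface = InterfaceDefinition(
        protein_id=model.id,
        subject_chain=subject_chain,
        partner_chains=partner_chains,
        residues=frozenset(subject_hits),
    )
    partner_iface = InterfaceDefinition(
        protein_id=model.id,
        subject_chain=",".join(sorted(partner_chains)),
        partner_chains=frozenset({subject_chain}),
        residues=frozenset(partner_hits),
    )
    return subject_iface, partner_iface


def _radii_error() -> float:
    raise ValueError("vdW radii not assigned; call assign_vdw_radii first")
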