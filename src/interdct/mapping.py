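"""Structural superposition, residue equivalences, interface mapping.

Annotation transfer between homologous proteins: a global sequence alignment
seeds Cα correspondences, a least-squares (Kabsch) fit superposes the pair,
and equivalences are re-assigned as mutually nearest Cα pairs within a
distance gate until the assignment reaches a fixed point.  Interface residue
sets are then carried across the resulting one-to-one partial mapping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .contacts import InterfaceDefinition
from .structure import ResidueKey, SasaMap, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentError",
    "ResidueEquivalenceMap",
    "MappedInterface",
    "superpose",
    "map_interface",
    "burial_filter",
    "sequence_identity",
]


class AlignmentError(RuntimeError):
    """Raised when a superposition cannot be established."""


@dataclass(frozen=True)
class ResidueEquivalenceMap:
    """One-to-one partial residue mapping between two chains plus the transform."""

    source_id: str
    target_id: str
    pairs: tuple[tuple[ResidueKey, ResidueKey], ...]
    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray

    @property
    def mapping(self) -> dict[ResidueKey, ResidueKey]:
        return dict(self.pairs)

    def inverted(self) -> "ResidueEquivalenceMap":
        rot = self.rotation.T
        return ResidueEquivalenceMap(
            source_id=self.target_id,
            target_id=self.source_id,
            pairs=tuple((b, a) for a, b in self.pairs),
            rmsd=self.rmsd,
            rotation=rot,
            translation=-rot @ self.translation,
        )

    def write_tsv(self, path: str | Path) -> None:
        lines = ["src_chain\tsrc_resnum\tsrc_icode\ttgt_chain\ttgt_resnum\ttgt_icode"]
        for a, b in self.pairs:
            lines.append(
                f"{a.chain_id}\t{a.seq_number}\t{a.insertion_code}\t"
                f"{b.chain_id}\t{b.seq_number}\t{b.insertion_code}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def transform_json(self) -> str:
        return json.dumps(
            {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}
        )


@dataclass(frozen=True)
class MappedInterface:
    """An interface annotation carried from a source protein onto a target."""

    target_id: str
    source_id: str
    residues: frozenset[ResidueKey]


# ---------------------------------------------------------------------------
# alignment helpers
# ---------------------------------------------------------------------------

def _make_aligner(gap_open: float = 11.0, gap_extend: float = 1.0):
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _aligned_index_pairs(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return pairs


def _ca_coords(model: StructureModel, chain_id: str) -> tuple[np.ndarray, list[ResidueKey], str]:
    from .structure import extract_sequence

    chain = model.chain(chain_id)
    coords, keys, letters = [], [], []
    seq, index = extract_sequence(model, chain.id)
    for res, letter in zip(chain.residues, seq):
        ca = next((a for a in res.atoms if a.name == "CA"), None)
        if ca is not None:
            coords.append(ca.coords)
            keys.append(res.key)
            letters.append(letter)
    return np.asarray(coords, dtype=float), keys, "".join(letters)


def _kabsch(src: np.ndarray, tgt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation+translation mapping src onto tgt."""
    src_c = src.mean(axis=0)
    tgt_c = tgt.mean(axis=0)
    h = (src - src_c).T @ (tgt - tgt_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tgt_c - rot @ src_c


def superpose(
    source: StructureModel,
    source_chain: str,
    target: StructureModel,
    target_chain: str,
    distance_gate: float = 4.0,
    max_iter: int = 20,
) -> ResidueEquivalenceMap:
    """Iterative sequence-seeded superposition of two chains.

    A global BLOSUM62 alignment seeds Cα correspondences; the fit is then
    refined by re-assigning equivalences as mutually nearest Cα pairs within
    ``distance_gate`` Å until the pair set stops changing (at most
    ``max_iter`` rounds).
    """
    src_xyz, src_keys, src_seq = _ca_coords(source, source_chain)
    tgt_xyz, tgt_keys, tgt_seq = _ca_coords(target, target_chain)
    if len(src_xyz) < 3 or len(tgt_xyz) < 3:
        raise AlignmentError("need at least 3 Cα atoms per chain")

    seed = _aligned_index_pairs(src_seq, tgt_seq)
    if len(seed) < 3:
        raise AlignmentError(
            f"only {len(seed)} seed correspondences between "
            f"{source.id}:{source_chain} and {target.id}:{target_chain}"
        )
    pairs = seed
    # robust seed fit: misaligned seed blocks would otherwise drag the
    # least-squares fit toward a wrong register; trim residual outliers
    for _ in range(3):
        si = np.array([p[0] for p in pairs])
        ti = np.array([p[1] for p in pairs])
        rot, trans = _kabsch(src_xyz[si], tgt_xyz[ti])
        residuals = np.linalg.norm(src_xyz[si] @ rot.T + trans - tgt_xyz[ti], axis=1)
        cut = max(1.5 * float(np.median(residuals)), 1.0)
        keep = residuals < cut
        if keep.all() or keep.sum() < 3:
            break
        pairs = [p for p, k in zip(pairs, keep) if k]
    for _ in range(max_iter):
        si = np.array([p[0] for p in pairs])
        ti = np.array([p[1] for p in pairs])
        rot, trans = _kabsch(src_xyz[si], tgt_xyz[ti])
        moved = src_xyz @ rot.T + trans
        # mutual nearest neighbours within the gate
        d = np.linalg.norm(moved[:, None, :] - tgt_xyz[None, :, :], axis=2)
        nearest_t = d.argmin(axis=1)
        nearest_s = d.argmin(axis=0)
        new_pairs = [
            (i, int(nearest_t[i]))
            for i in range(len(src_xyz))
            if nearest_s[nearest_t[i]] == i and d[i, nearest_t[i]] < distance_gate
        ]
        if len(new_pairs) < 3:
            raise AlignmentError(
                f"no stable equivalences between {source.id}:{source_chain} "
                f"and {target.id}:{target_chain}"
            )
        if new_pairs == pairs:
            pairs = new_pairs
            break
        pairs = new_pairs

    si = np.array([p[0] for p in pairs])
    ti = np.array([p[1] for p in pairs])
    rot, trans = _kabsch(src_xyz[si], tgt_xyz[ti])
    moved = src_xyz[si] @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - tgt_xyz[ti]) ** 2, axis=1))))
    return ResidueEquivalenceMap(
        source_id=source.id,
        target_id=target.id,
        pairs=tuple((src_keys[i], tgt_keys[j]) for i, j in pairs),
        rmsd=rmsd,
        rotation=rot,
        translation=trans,
    )


def map_interface(
    src_iface: InterfaceDefinition | Iterable[ResidueKey],
    eq: ResidueEquivalenceMap,
) -> MappedInterface:
    """Carry an interface annotation across a residue equivalence map.

    Source residues without an equivalence are dropped (count logged).
    """
    residues = (
        src_iface.residues if isinstance(src_iface, InterfaceDefinition) else set(src_iface)
    )
    mapping = eq.mapping
    mapped = frozenset(mapping[r] for r in residues if r in mapping)
    dropped = len(residues) - len([r for r in residues if r in mapping])
    if dropped:
        logger.debug(
            "%d/%d interface residues of %s had no equivalence in %s",
            dropped, len(residues), eq.source_id, eq.target_id,
        )
    return MappedInterface(target_id=eq.target_id, source_id=eq.source_id, residues=mapped)


def burial_filter(
    residues: Iterable[ResidueKey],
    sasa: SasaMap,
    min_sasa: float = 5.0,
) -> frozenset[ResidueKey]:
    """Discard residues with SASA strictly below ``min_sasa`` Å² (buried)."""
    residues = frozenset(residues)
    missing = [r for r in residues if r not in sasa]
    if missing:
        raise KeyError(f"residues missing from SASA map: {sorted(missing)[:3]}...")
    return frozenset(r for r in residues if sasa[r] >= min_sasa)


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over a global BLOSUM62 alignment (gap 11/1).

    The denominator is the full alignment length including gap columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    identical = sum(1 for a, b in zip(row_a, row_b) if a == b and a != "-")
    return 100.0 * identical / len(row_a)
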