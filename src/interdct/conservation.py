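"""Per-residue conservation from a multiple sequence alignment.

Column conservation is the Jensen–Shannon divergence (log base 2, mixture
weight 0.5) between the column's amino-acid distribution and a background
distribution, multiplied by the column's non-gap fraction.  With these
settings every score lies in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure import ResidueKey, StructureModel, extract_sequence

__all__ = [
    "AMINO_ACIDS",
    "BLOSUM62_BACKGROUND",
    "Msa",
    "ConservationProfile",
    "read_msa",
    "jsd_column_score",
    "profile_for_structure",
    "uniform_background",
    "blosum62_background",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Amino-acid background frequencies underlying the BLOSUM62 matrix
# (Henikoff & Henikoff), indexed like AMINO_ACIDS; normalised on use.
BLOSUM62_BACKGROUND = np.array(
    [
        0.078, 0.051, 0.041, 0.052, 0.024, 0.034, 0.059, 0.083, 0.025, 0.062,
        0.092, 0.056, 0.024, 0.044, 0.043, 0.059, 0.055, 0.014, 0.034, 0.072,
    ]
)


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def blosum62_background() -> np.ndarray:
    return BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()


@dataclass(frozen=True)
class Msa:
    """A validated multiple sequence alignment with a designated reference row."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 1:
            raise ValueError("alignment is empty")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("ragged alignment: rows differ in length")
        if self.reference_id not in self.ids:
            raise KeyError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


def _normalise(seq: str) -> str:
    return seq.upper().replace(".", "-")


def read_msa(path: str | Path, reference_id: str) -> Msa:
    """Read a FASTA alignment; lowercase and '.' gaps are normalised."""
    from Bio import SeqIO

    ids: list[str] = []
    rows: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        rows.append(_normalise(str(record.seq)))
    if len(rows) < 2:
        raise ValueError(f"{path}: an alignment needs at least 2 sequences")
    return Msa(ids=tuple(ids), rows=tuple(rows), reference_id=reference_id)


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd_column_score(
    column: str | Sequence[str],
    background: np.ndarray | None = None,
    lam: float = 0.5,
    gap_fraction: float | None = None,
) -> float:
    """Jensen–Shannon conservation score of one alignment column.

    ``score = (1 - gap_fraction) * [H(lam*P + (1-lam)*q) - lam*H(P) - (1-lam)*H(q)]``
    in bits, where P is the column's amino-acid distribution and q the
    background.  Characters outside the 20 standard amino acids count as gaps.
    An effectively empty column scores 0.
    """
    background = blosum62_background() if background is None else np.asarray(background, float)
    if not math.isclose(background.sum(), 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("background must sum to 1")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    chars = list(column)
    if not chars:
        return 0.0
    counts = np.zeros(20)
    n_gap = 0
    for c in chars:
        idx = _AA_INDEX.get(c.upper())
        if idx is None:
            n_gap += 1
        else:
            counts[idx] += 1
    if gap_fraction is None:
        gap_fraction = n_gap / len(chars)
    if counts.sum() == 0:
        return 0.0
    p = counts / counts.sum()
    m = lam * p + (1.0 - lam) * background
    jsd = _entropy_bits(m) - lam * _entropy_bits(p) - (1.0 - lam) * _entropy_bits(background)
    score = (1.0 - gap_fraction) * jsd
    return float(min(1.0, max(0.0, score)))


@dataclass(frozen=True)
class ConservationProfile:
    """Per-residue conservation scores in [0, 1]."""

    protein_id: str
    scores: dict[ResidueKey, float]

    def score(self, key: ResidueKey) -> float:
        return self.scores.get(key, 0.0)

    def write_tsv(self, path: str | Path) -> None:
        lines = ["chain\tresnum\ticode\tresname\tscore"]
        for key in sorted(self.scores):
            lines.append(
                f"{key.chain_id}\t{key.seq_number}\t{key.insertion_code}\t"
                f"{key.residue_name}\t{self.scores[key]:.4f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def profile_for_structure(
    msa: Msa,
    model: StructureModel,
    chain_id: str,
    background: np.ndarray | None = None,
    lam: float = 0.5,
) -> ConservationProfile:
    """Attach column conservation scores to a chain's residues.

    The reference row's ungapped sequence must match the chain sequence
    (positions where either side is 'X' are tolerated).  Residues missing
    from the alignment score 0.
    """
    sequence, index = extract_sequence(model, chain_id)
    ref = msa.reference_row
    ungapped = ref.replace("-", "")
    if len(ungapped) != len(sequence) or any(
        a != b and "X" not in (a, b) for a, b in zip(ungapped, sequence)
    ):
        raise ValueError(
            f"reference row of MSA does not match chain {chain_id!r} sequence "
            f"of {model.id!r}"
        )
    scores: dict[ResidueKey, float] = {key: 0.0 for key in index}
    pos = 0
    for j, c in enumerate(ref):
        if c == "-":
            continue
        scores[index[pos]] = jsd_column_score(msa.column(j), background=background, lam=lam)
        pos += 1
    return ConservationProfile(protein_id=model.id, scores=scores)
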