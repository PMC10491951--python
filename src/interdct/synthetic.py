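"""Synthetic template families with planted interfaces, MSAs, and poses.

Every stage of the predictor is testable without external data through this
generator.  Proteins are coarse bead chains (one Cα and one pseudo side-chain
atom per residue) laid out along a line with 5 Å residue spacing; a partner
chain is placed 5 Å above a chosen contiguous patch so that the
Voronoi+distance contact criterion recovers exactly the planted residues
(contact margin 1.2 Å, nearest-non-patch margin 0.87 Å, far above the
coordinate noise).  Group identity is encoded twice, mirroring the signal
the predictor exploits: geometrically (each group binds a distinct patch)
and statistically (each protein's MSA is conserved at its own patch columns).

Sequences share a fixed scaffold (every ``scaffold_period``-th position) and
differ elsewhere by per-protein cyclic substitutions, pinning every pairwise
sequence identity near 1/scaffold_period — the nontrivial (<35%) regime —
while keeping pairwise alignments in register.

What this generator does not emulate: real side-chain packing, fold-level
structural divergence within a family, alignment errors, and MSAs with
phylogenetic correlation between rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .conservation import AMINO_ACIDS, Msa
from .library import LibraryEntry, TemplateLibrary
from .refinement import DockedPose
from .structure import (
    Atom,
    Chain,
    ONE_TO_THREE,
    Residue,
    ResidueKey,
    StructureModel,
    assign_vdw_radii,
    write_pdb,
)

__all__ = [
    "FixtureSpec",
    "FixtureFamily",
    "generate_family",
    "generate_inconsistent_family",
    "generate_msas",
    "make_query",
    "generate_poses",
    "write_fixture",
]

_SPACING = 5.0          # Å between consecutive residues along the chain
_CONTACT_HEIGHT = 5.0   # Å between partner beads and the patch beads
_CB_OFFSET = 1.5        # pseudo side-chain displacement away from the partner
_ZIGZAG = 0.3           # alternating z displacement (breaks coplanarity)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic template family."""

    n_groups: int = 3
    templates_per_group: int = 4
    residues_per_chain: int = 48
    patch_size: int = 8
    msa_depth: int = 30
    interface_conservation: float = 0.9
    background_conservation: float = 0.3
    noise: float = 1.0        # substitution rate at non-scaffold sequence positions
    coord_noise: float = 0.05  # Å, per-coordinate Gaussian noise per template
    scaffold_period: int = 4   # every k-th position conserved across the family
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 8:
            raise ValueError(
                "patch_size must be >= 8 (the smallest known template interface)"
            )
        if self.patch_size > self.residues_per_chain:
            raise ValueError("patch_size exceeds chain length")
        seg = self.residues_per_chain // self.n_groups
        if seg < self.patch_size + 2:
            raise ValueError(
                "chain too short for non-overlapping group patches: need "
                f"{self.n_groups * (self.patch_size + 2)} residues"
            )
        if not 0.0 < self.interface_conservation <= 1.0:
            raise ValueError("interface_conservation must be in (0, 1]")

    def patch_range(self, group: int) -> tuple[int, int]:
        """0-based [start, end) residue index range of a group's patch."""
        seg = self.residues_per_chain // self.n_groups
        start = group * seg + (seg - self.patch_size) // 2
        return start, start + self.patch_size


@dataclass
class FixtureFamily:
    spec: FixtureSpec
    library: TemplateLibrary
    truths: dict[str, frozenset[ResidueKey]]
    groups: dict[str, int]
    sequences: dict[str, str]
    base_sequence: str = ""
    #: group -> (start, end) 0-based patch residue range; filled by generators
    patch_layout: dict[int, tuple[int, int]] = None  # type: ignore[assignment]

    def patch_range(self, group: int) -> tuple[int, int]:
        if self.patch_layout is not None:
            return self.patch_layout[group]
        return self.spec.patch_range(group)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _bead_chain(
    chain_id: str,
    names: list[str],
    positions: np.ndarray,
    cb_direction: float,
    rng: np.random.Generator,
    coord_noise: float,
) -> Chain:
    """A chain of CA + pseudo-CB beads at the given CA positions."""
    residues = []
    for i, (name, ca) in enumerate(zip(names, positions)):
        key = ResidueKey(chain_id, i + 1, "", name)
        ca_xyz = ca + rng.normal(0.0, coord_noise, size=3)
        cb_xyz = ca + np.array([0.0, cb_direction * _CB_OFFSET, 0.0])
        cb_xyz = cb_xyz + rng.normal(0.0, coord_noise, size=3)
        residues.append(
            Residue(
                key=key,
                atoms=[
                    Atom(serial=2 * i + 1, name="CA", element="C", coords=ca_xyz),
                    Atom(serial=2 * i + 2, name="CB", element="C", coords=cb_xyz),
                ],
            )
        )
    return Chain(id=chain_id, residues=residues)


def _subject_positions(n: int) -> np.ndarray:
    if n > _MAX_CHAIN:
        raise ValueError(f"chains longer than {_MAX_CHAIN} residues not supported")
    xyz = np.zeros((n, 3))
    xyz[:, 0] = np.arange(n) * _SPACING
    xyz[:, 2] = _Z_WIGGLE[:n]
    return xyz


def _build_complex(
    protein_id: str,
    sequence: str,
    patch: tuple[int, int],
    rng: np.random.Generator,
    coord_noise: float,
) -> StructureModel:
    n = len(sequence)
    subject_xyz = _subject_positions(n)
    names = [ONE_TO_THREE[c] for c in sequence]
    chain_a = _bead_chain("A", names, subject_xyz, cb_direction=-1.0, rng=rng,
                          coord_noise=coord_noise)
    start, end = patch
    partner_xyz = subject_xyz[start:end].copy()
    partner_xyz[:, 1] += _CONTACT_HEIGHT
    chain_b = _bead_chain("B", ["ALA"] * (end - start), partner_xyz,
                          cb_direction=+1.0, rng=rng, coord_noise=coord_noise)
    model = StructureModel(id=protein_id, chains=[chain_a, chain_b])
    return assign_vdw_radii(model)


# ---------------------------------------------------------------------------
# sequences and alignments
# ---------------------------------------------------------------------------

# aperiodic position masks (shared by every family): a periodic scaffold or
# zigzag would make shift-by-period alignments and superpositions
# near-degenerate with the true register on these self-similar chains.  The
# golden-ratio Kronecker sequence is equidistributed (density exactly
# 1/period up to O(1)) with no long gaps and no period.
_MAX_CHAIN = 4096
_GOLDEN = 0.6180339887498949
_Z_WIGGLE = np.random.default_rng(778).uniform(-_ZIGZAG, _ZIGZAG, _MAX_CHAIN)


def _is_scaffold(i: int, period: int) -> bool:
    return (i * _GOLDEN) % 1.0 < 1.0 / period


def _protein_sequence(
    base_indices: np.ndarray,
    offset: int,
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> str:
    letters = []
    for i, base_idx in enumerate(base_indices):
        if _is_scaffold(i, spec.scaffold_period) or rng.random() >= spec.noise:
            letters.append(AMINO_ACIDS[base_idx])
        else:
            letters.append(AMINO_ACIDS[(base_idx + offset) % 20])
    return "".join(letters)


def _make_msa(
    protein_id: str,
    sequence: str,
    conserved_columns: set[int],
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> Msa:
    rows = [sequence]
    ids = [protein_id]
    for k in range(1, spec.msa_depth):
        row = []
        for j, ref in enumerate(sequence):
            keep = (
                spec.interface_conservation
                if j in conserved_columns
                else spec.background_conservation
            )
            if rng.random() < keep:
                row.append(ref)
            else:
                row.append(AMINO_ACIDS[rng.integers(20)])
        rows.append("".join(row))
        ids.append(f"{protein_id}_hom{k}")
    return Msa(ids=tuple(ids), rows=tuple(rows), reference_id=protein_id)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_family(spec: FixtureSpec) -> FixtureFamily:
    """Generate the template library: complexes, truths, group labels.

    Deterministic in ``spec`` (including its seed).  MSAs are attached by
    :func:`generate_msas`, which this function calls.
    """
    rng = np.random.default_rng(spec.seed)
    base_indices = rng.integers(0, 20, size=spec.residues_per_chain)
    entries: list[LibraryEntry] = []
    truths: dict[str, frozenset[ResidueKey]] = {}
    groups: dict[str, int] = {}
    sequences: dict[str, str] = {}
    offset = 0
    for g in range(spec.n_groups):
        patch = spec.patch_range(g)
        for t in range(spec.templates_per_group):
            offset += 1
            protein_id = f"T{g}_{t}"
            seq = _protein_sequence(base_indices, offset, spec, rng)
            structure = _build_complex(protein_id, seq, patch, rng, spec.coord_noise)
            truth = frozenset(
                res.key for res in structure.chain("A").residues[patch[0]:patch[1]]
            )
            entries.append(
                LibraryEntry(
                    id=protein_id, structure=structure, chain="A",
                    partner_chains=("B",),
                )
            )
            truths[protein_id] = truth
            groups[protein_id] = g
            sequences[protein_id] = seq
    family = FixtureFamily(
        spec=spec,
        library=TemplateLibrary(entries),
        truths=truths,
        groups=groups,
        sequences=sequences,
        base_sequence="".join(AMINO_ACIDS[i] for i in base_indices),
        patch_layout={g: spec.patch_range(g) for g in range(spec.n_groups)},
    )
    generate_msas(spec, family)
    return family


def generate_msas(
    spec: FixtureSpec,
    family: FixtureFamily,
    conserved_columns: dict[str, set[int]] | None = None,
) -> dict[str, Msa]:
    """Attach one synthetic MSA per protein: its own patch columns are
    conserved at ``interface_conservation``, all other columns at
    ``background_conservation``.  ``conserved_columns`` overrides the
    conserved set per protein."""
    rng = np.random.default_rng(spec.seed + 1_000_003)
    msas: dict[str, Msa] = {}
    for entry in family.library:
        if conserved_columns is not None and entry.id in conserved_columns:
            conserved = conserved_columns[entry.id]
        else:
            conserved = set(range(*spec.patch_range(family.groups[entry.id])))
        msa = _make_msa(entry.id, family.sequences[entry.id], conserved, spec, rng)
        entry.msa = msa
        msas[entry.id] = msa
    return msas


def generate_inconsistent_family(spec: FixtureSpec) -> FixtureFamily:
    """A family whose groups are internally inconsistent.

    The last member of every group is a functional outlier: its MSA is
    conserved at the group's patch — so its mapping profile clusters with
    the group — but its actual complex binds a shared decoy patch elsewhere
    on the chain.  Leave-one-out self-consistency within any selected group
    then mixes good and failed predictions, the signature the confidence
    measure is designed to flag.
    """
    seg = spec.residues_per_chain // (spec.n_groups + 1)
    if seg < spec.patch_size + 2:
        raise ValueError("chain too short for group patches plus a decoy patch")

    def slot(i: int) -> tuple[int, int]:
        start = i * seg + (seg - spec.patch_size) // 2
        return start, start + spec.patch_size

    decoy = slot(spec.n_groups)
    rng = np.random.default_rng(spec.seed)
    base_indices = rng.integers(0, 20, size=spec.residues_per_chain)
    entries: list[LibraryEntry] = []
    truths: dict[str, frozenset[ResidueKey]] = {}
    groups: dict[str, int] = {}
    sequences: dict[str, str] = {}
    conserved_columns: dict[str, set[int]] = {}
    offset = 0
    for g in range(spec.n_groups):
        for t in range(spec.templates_per_group):
            offset += 1
            protein_id = f"T{g}_{t}"
            is_outlier = t == spec.templates_per_group - 1
            patch = decoy if is_outlier else slot(g)
            seq = _protein_sequence(base_indices, offset, spec, rng)
            structure = _build_complex(protein_id, seq, patch, rng, spec.coord_noise)
            truths[protein_id] = frozenset(
                res.key for res in structure.chain("A").residues[patch[0]:patch[1]]
            )
            entries.append(
                LibraryEntry(id=protein_id, structure=structure, chain="A",
                             partner_chains=("B",))
            )
            groups[protein_id] = g
            sequences[protein_id] = seq
            conserved_columns[protein_id] = set(range(*slot(g)))
    family = FixtureFamily(
        spec=spec,
        library=TemplateLibrary(entries),
        truths=truths,
        groups=groups,
        sequences=sequences,
        base_sequence="".join(AMINO_ACIDS[i] for i in base_indices),
        patch_layout={g: slot(g) for g in range(spec.n_groups)},
    )
    generate_msas(spec, family, conserved_columns=conserved_columns)
    return family


def make_query(
    family: FixtureFamily,
    group: int = 0,
    seed: int = 999,
    conserved_groups: tuple[int, ...] | None = None,
) -> tuple[LibraryEntry, frozenset[ResidueKey]]:
    """Generate an extra family member to serve as the query.

    The query binds its group's patch (the withheld truth) and its MSA is
    conserved at that patch — or at several groups' patches when
    ``conserved_groups`` is given, producing a deliberately ambiguous query.
    """
    spec = family.spec
    rng = np.random.default_rng(spec.seed * 1_000_000_007 % (2**31) + seed)
    base = np.array([AMINO_ACIDS.index(c) for c in family.base_sequence], dtype=int)
    # offset 16 keeps the query's substitution alphabet at cyclic distance >=4
    # from every template offset (1..12): near-coincident offsets would
    # correlate the supposedly independent variable positions
    seq = _protein_sequence(base, offset=16, spec=spec, rng=rng)
    patch = family.patch_range(group)
    structure = _build_complex("Q", seq, patch, rng, spec.coord_noise)
    truth = frozenset(res.key for res in structure.chain("A").residues[patch[0]:patch[1]])
    conserved: set[int] = set()
    for g in conserved_groups if conserved_groups is not None else (group,):
        conserved.update(range(*family.patch_range(g)))
    msa = _make_msa("Q", seq, conserved, spec, rng)
    entry = LibraryEntry(id="Q", structure=structure, chain="A",
                         partner_chains=("B",), msa=msa)
    return entry, truth


def generate_poses(
    query: StructureModel,
    patch: frozenset[ResidueKey] | tuple[int, int],
    n_at_patch: int,
    n_elsewhere: int,
    seed: int = 0,
    probe_id: str = "probe0",
    probe_length: int | None = None,
) -> list[DockedPose]:
    """Synthetic docked poses: ``n_at_patch`` contact (a superset of 80% of)
    the patch, ``n_elsewhere`` contact a disjoint chain region."""
    rng = np.random.default_rng(seed)
    chain_a = query.chain("A")
    n = len(chain_a.residues)
    if isinstance(patch, tuple):
        start, end = patch
    else:
        numbers = sorted(k.seq_number for k in patch)
        start, end = numbers[0] - 1, numbers[-1]
    m = probe_length or (end - start)
    subject_xyz = np.array(
        [next(a for a in res.atoms if a.name == "CA").coords for res in chain_a.residues]
    )

    def probe_at(region_start: int, jitter_x: float, lift: float, tag: str, k: int) -> DockedPose:
        base = subject_xyz[region_start:region_start + m].copy()
        base[:, 0] += jitter_x
        base[:, 1] += _CONTACT_HEIGHT + lift
        chain = _bead_chain("P", ["ALA"] * m, base, cb_direction=+1.0,
                            rng=rng, coord_noise=0.0)
        model = assign_vdw_radii(StructureModel(id=f"{probe_id}_{tag}{k}", chains=[chain]))
        return DockedPose(pose_id=f"{probe_id}_{tag}_{k:04d}", probe_id=probe_id, probe=model)

    poses: list[DockedPose] = []
    for k in range(n_at_patch):
        poses.append(probe_at(start, rng.uniform(-1.0, 1.0), rng.uniform(0.0, 0.3), "patch", k))
    # regions at least 2 residues away from the patch on either side
    allowed = [
        s for s in range(0, n - m + 1)
        if s + m <= start - 2 or s >= end + 2
    ]
    if n_elsewhere and not allowed:
        raise ValueError("chain too short to place off-patch poses")
    for k in range(n_elsewhere):
        s = int(allowed[rng.integers(len(allowed))])
        poses.append(probe_at(s, rng.uniform(-1.0, 1.0), rng.uniform(0.0, 0.3), "else", k))
    return poses


# ---------------------------------------------------------------------------
# on-disk export (CLI `interdct simulate`)
# ---------------------------------------------------------------------------

def write_fixture(
    family: FixtureFamily,
    out_dir: str | Path,
    query: tuple[LibraryEntry, frozenset[ResidueKey]] | None = None,
) -> Path:
    """Write PDB files, FASTA MSAs, truth TSVs, and a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"templates": []}

    def dump(entry: LibraryEntry) -> dict:
        pdb = f"{entry.id}.pdb"
        write_pdb(entry.structure, out / pdb)
        item = {"id": entry.id, "pdb": pdb, "chain": entry.chain,
                "partners": list(entry.partner_chains)}
        if entry.msa is not None:
            msa_path = f"{entry.id}.afa"
            lines = []
            for sid, row in zip(entry.msa.ids, entry.msa.rows):
                lines.append(f">{sid}")
                lines.append(row)
            (out / msa_path).write_text("\n".join(lines) + "\n")
            item["msa"] = msa_path
            item["msa_reference"] = entry.msa.reference_id
        return item

    for entry in family.library:
        manifest["templates"].append(dump(entry))
    truth_lines = ["protein\tchain\tresnum\ticode\tresname"]
    for pid, truth in sorted(family.truths.items()):
        for key in sorted(truth):
            truth_lines.append(
                f"{pid}\t{key.chain_id}\t{key.seq_number}\t{key.insertion_code}\t{key.residue_name}"
            )
    if query is not None:
        entry, truth = query
        manifest["query"] = dump(entry)
        for key in sorted(truth):
            truth_lines.append(
                f"{entry.id}\t{key.chain_id}\t{key.seq_number}\t{key.insertion_code}\t{key.residue_name}"
            )
    (out / "truths.tsv").write_text("\n".join(truth_lines) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out / "manifest.json"
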