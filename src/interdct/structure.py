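"""Macromolecular structure model: PDB I/O, van der Waals radii, per-residue SASA.

The in-memory hierarchy is deliberately small: chains hold residues hold atoms,
residues are addressed by :class:`ResidueKey` (author numbering plus insertion
code), and coordinates live in plain numpy arrays.  Hydrogens are stripped on
read and alternate locations are resolved to the highest-occupancy conformer,
so every downstream computation sees a single set of heavy atoms.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueKey",
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "SasaMap",
    "PDBFormatError",
    "BONDI_RADII",
    "DEFAULT_VDW_RADIUS",
    "read_pdb",
    "write_pdb",
    "assign_vdw_radii",
    "compute_sasa",
    "extract_sequence",
    "sphere_points",
]


class PDBFormatError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


class ResidueKey(NamedTuple):
    """Identity of a residue: chain, author sequence number, insertion code, name."""

    chain_id: str
    seq_number: int
    insertion_code: str
    residue_name: str


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: float | None = None


@dataclass
class Residue:
    key: ResidueKey
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


# Bondi (1964) element radii in Angstrom; elements absent from the table fall
# back to DEFAULT_VDW_RADIUS with a logged warning.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.80

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class StructureModel:
    """An ordered chain -> residue -> atom coordinate model."""

    id: str
    chains: list[Chain] = field(default_factory=list)

    # -- access -----------------------------------------------------------
    def chain(self, chain_id: str) -> Chain:
        if chain_id == "" and len(self.chains) == 1:
            return self.chains[0]
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise KeyError(f"chain {chain_id!r} not found in structure {self.id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [ch.id for ch in self.chains]

    def residues(self, chain_ids: Iterable[str] | None = None) -> Iterator[Residue]:
        wanted = None if chain_ids is None else set(chain_ids)
        for ch in self.chains:
            if wanted is None or ch.id in wanted:
                yield from ch.residues

    def atoms(self, chain_ids: Iterable[str] | None = None) -> Iterator[tuple[ResidueKey, Atom]]:
        for res in self.residues(chain_ids):
            for atom in res.atoms:
                yield res.key, atom

    def atom_arrays(
        self, chain_ids: Iterable[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray, list[ResidueKey]]:
        """Coordinates (n,3), radii (n,), and owning residue key per atom."""
        coords, radii, owners = [], [], []
        for key, atom in self.atoms(chain_ids):
            if atom.vdw_radius is None:
                raise ValueError("vdW radii not assigned; call assign_vdw_radii first")
            coords.append(atom.coords)
            radii.append(atom.vdw_radius)
            owners.append(key)
        if not coords:
            return np.empty((0, 3)), np.empty(0), []
        return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float), owners

    def subset(self, chain_ids: Iterable[str]) -> "StructureModel":
        wanted = list(chain_ids)
        chains = [ch for ch in self.chains if ch.id in wanted]
        return StructureModel(id=self.id, chains=chains)

    def copy(self) -> "StructureModel":
        return StructureModel(
            id=self.id,
            chains=[
                Chain(
                    id=ch.id,
                    residues=[
                        Residue(
                            key=res.key,
                            atoms=[replace(a, coords=a.coords.copy()) for a in res.atoms],
                        )
                        for res in ch.residues
                    ],
                )
                for ch in self.chains
            ],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every coordinate mapped through x -> R x + t."""
        out = self.copy()
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        for _, atom in out.atoms():
            atom.coords = rotation @ atom.coords + translation
        return out


SasaMap = dict[ResidueKey, float]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, model_index: int = 0, structure_id: str | None = None) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Water HETATM records are excluded, hydrogens/deuteriums are dropped, and
    disordered atoms are resolved to the alternate location with the highest
    occupancy (ties broken by altloc identifier).  Only the model selected by
    ``model_index`` (default: first) is kept.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        bio_structure = parser.get_structure(structure_id or path.stem, str(path))
    models = list(bio_structure)
    if not models:
        raise PDBFormatError(f"{path}: no coordinate models")
    try:
        bio_model = models[model_index]
    except IndexError:
        raise PDBFormatError(f"{path}: model index {model_index} out of range") from None

    chains: list[Chain] = []
    seen_keys: set[ResidueKey] = set()
    for bio_chain in bio_model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.id
            resname = bio_res.get_resname().strip()
            if resname in _WATER_NAMES:
                continue
            key = ResidueKey(bio_chain.id, int(resseq), icode.strip(), resname)
            atoms: list[Atom] = []
            for bio_atom in bio_res:
                if bio_atom.is_disordered():
                    children = sorted(
                        bio_atom.child_dict.values(),
                        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                    )
                    bio_atom = children[0]
                element = (bio_atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        serial=int(bio_atom.get_serial_number() or 0),
                        name=bio_atom.get_name(),
                        element=element,
                        coords=np.asarray(bio_atom.get_coord(), dtype=float),
                        occupancy=float(bio_atom.get_occupancy() or 1.0),
                        altloc=bio_atom.get_altloc().strip(),
                    )
                )
            if atoms:
                if key in seen_keys:
                    raise PDBFormatError(f"{path}: duplicate residue key {key}")
                seen_keys.add(key)
                residues.append(Residue(key=key, atoms=atoms))
        if residues:
            chains.append(Chain(id=bio_chain.id, residues=residues))
    model = StructureModel(id=structure_id or path.stem, chains=chains)
    if not any(True for _ in model.atoms()):
        raise PDBFormatError(f"{path}: no usable ATOM records")
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write fixed-width ATOM records (with TER separators and END)."""
    lines: list[str] = []
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # atom-name column alignment per PDB convention
                if len(name) < 4 and len(atom.element) < 2:
                    name = " " + name
                key = res.key
                lines.append(
                    "ATOM  {serial:>5} {name:<4}{alt:1}{resn:<3} {ch:1}{num:>4}{ic:1}   "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2}".format(
                        serial=serial,
                        name=name[:4],
                        alt=atom.altloc[:1] or " ",
                        resn=key.residue_name[:3],
                        ch=chain.id[:1] or " ",
                        num=key.seq_number,
                        ic=key.insertion_code[:1] or " ",
                        x=atom.coords[0],
                        y=atom.coords[1],
                        z=atom.coords[2],
                        occ=atom.occupancy,
                        b=0.0,
                        el=atom.element[:2],
                    )
                )
        serial += 1
        lines.append(f"TER   {serial:>5}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def assign_vdw_radii(
    model: StructureModel,
    table: dict[str, float] | None = None,
    default: float = DEFAULT_VDW_RADIUS,
) -> StructureModel:
    """Attach an element-based van der Waals radius to every atom (in place).

    Unknown elements receive ``default`` and are reported once per element via
    the module logger.
    """
    table = BONDI_RADII if table is None else table
    unknown: set[str] = set()
    for _, atom in model.atoms():
        radius = table.get(atom.element.upper())
        if radius is None:
            unknown.add(atom.element)
            radius = default
        atom.vdw_radius = radius
    for element in sorted(unknown):
        logger.warning(
            "element %r not in radius table; using default %.2f A", element, default
        )
    return model


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    chain_ids: Iterable[str] | None = None,
) -> SasaMap:
    """Per-residue solvent-accessible surface area by sphere sampling.

    Each atom's extended sphere (vdW radius + probe) is sampled on a fixed
    ``n_points`` lattice; a sample point is accessible when it lies outside
    every neighbouring atom's extended sphere.  Residue SASA is the sum over
    its atoms.  Deterministic given ``n_points``.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a meaningful lattice")
    coords, radii, owners = model.atom_arrays(chain_ids)
    if len(coords) == 0:
        raise ValueError("structure has no atoms")
    from scipy.spatial import cKDTree

    extended = radii + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    ext_max = extended.max()
    sasa: SasaMap = {key: 0.0 for key in dict.fromkeys(owners)}
    for i in range(len(coords)):
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], extended[i] + ext_max)
            if j != i
        ]
        pts = coords[i] + extended[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > extended[j] ** 2
            if not accessible.any():
                break
        frac = accessible.sum() / n_points
        sasa[owners[i]] += frac * 4.0 * math.pi * extended[i] ** 2
    return sasa


def write_sasa_tsv(sasa: SasaMap, path: str | Path) -> None:
    lines = ["chain\tresnum\ticode\tresname\tsasa_A2"]
    for key in sorted(sasa):
        lines.append(
            f"{key.chain_id}\t{key.seq_number}\t{key.insertion_code}\t{key.residue_name}\t{sasa[key]:.3f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def extract_sequence(
    model: StructureModel,
    chain_id: str,
    mse_as_met: bool = False,
) -> tuple[str, list[ResidueKey]]:
    """One-letter sequence of a chain plus an index of residue keys.

    Non-standard residues map to ``'X'``; selenomethionine maps to ``'M'``
    when ``mse_as_met`` is set.
    """
    chain = model.chain(chain_id)
    letters: list[str] = []
    index: list[ResidueKey] = []
    for res in chain.residues:
        name = res.key.residue_name
        if name == "MSE" and mse_as_met:
            letter = "M"
        else:
            letter = THREE_TO_ONE.get(name, "X")
        letters.append(letter)
        index.append(res.key)
    return "".join(letters), index
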