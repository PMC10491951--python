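"""Template library: manifest loading and cached per-protein derived data.

A library entry couples a complex structure with the chain whose interface is
annotated (the subject chain), the ligand chains it binds, and the protein's
multiple sequence alignment.  :class:`PredivedCache`-style recomputation is
centralised in :class:`PredictionContext`, which lazily derives and caches
interfaces, isolated-chain SASA, conservation profiles, sequences, pairwise
residue equivalences, and query sequence identities for one library+query
combination.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .conservation import (
    ConservationProfile,
    Msa,
    blosum62_background,
    profile_for_structure,
    read_msa,
    uniform_background,
)
from .contacts import ContactParams, InterfaceDefinition, detect_interface
from .mapping import ResidueEquivalenceMap, sequence_identity, superpose
from .structure import (
    SasaMap,
    StructureModel,
    assign_vdw_radii,
    compute_sasa,
    extract_sequence,
    read_pdb,
)

logger = logging.getLogger(__name__)

__all__ = ["InterDCTConfig", "LibraryEntry", "TemplateLibrary", "PredictionContext"]


@dataclass(frozen=True)
class InterDCTConfig:
    """All tunable parameters of the prediction pipeline."""

    contact: ContactParams = field(default_factory=ContactParams)
    sasa_probe: float = 1.4
    sasa_points: int = 960
    min_sasa: float = 5.0          # Å²; residues below are treated as buried
    min_support: float = 0.20      # consensus: fraction of subset templates
    identity_threshold: float = 35.0   # % identity above which a query is trivial
    identity_window: float = 20.0      # trivial path: points below the best template
    top_k: int = 8                 # most-frequently-mapped residues per row
    distance_gate: float = 4.0     # Å, superposition equivalence gate
    background: str = "blosum62"   # or "uniform"
    jsd_lambda: float = 0.5
    tp_min: float = 0.50           # refinement: keep interDCT residues above this
    fp_min: float = 0.35           # refinement: add outside residues above this
    n_top_poses: int = 100
    pose_overlap_metric: str = "fscore"  # or "intersection"
    reliability_cutoff: float = 0.525
    inconsistency_cutoff: float = 0.175
    confidence_repetitions: int = 10
    std_ddof: int = 0              # population standard deviation

    def background_distribution(self) -> np.ndarray:
        if self.background == "uniform":
            return uniform_background()
        return blosum62_background()


@dataclass
class LibraryEntry:
    """One protein of the library: structure, subject chain, ligands, MSA."""

    id: str
    structure: StructureModel
    chain: str
    partner_chains: tuple[str, ...] = ()
    msa: Msa | None = None


class TemplateLibrary:
    """An ordered collection of template entries."""

    def __init__(self, entries: list[LibraryEntry]):
        self._entries = {e.id: e for e in entries}
        if len(self._entries) != len(entries):
            raise ValueError("duplicate entry ids in library")

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[LibraryEntry]:
        return iter(self._entries.values())

    @property
    def ids(self) -> list[str]:
        return list(self._entries)

    def get(self, entry_id: str) -> LibraryEntry:
        return self._entries[entry_id]

    def without(self, entry_id: str) -> "TemplateLibrary":
        return TemplateLibrary([e for e in self if e.id != entry_id])

    @classmethod
    def from_manifest(cls, path: str | Path) -> tuple["TemplateLibrary", LibraryEntry | None]:
        """Load a JSON manifest: template PDB files, chains, ligands, MSAs.

        Returns the template library and the query entry (or None if the
        manifest names no query).
        """
        path = Path(path)
        spec = json.loads(path.read_text())
        base = path.parent

        def load_entry(item: Mapping) -> LibraryEntry:
            structure = assign_vdw_radii(read_pdb(base / item["pdb"], structure_id=item["id"]))
            msa = None
            if item.get("msa"):
                msa = read_msa(base / item["msa"], reference_id=item.get("msa_reference", item["id"]))
            return LibraryEntry(
                id=item["id"],
                structure=structure,
                chain=item["chain"],
                partner_chains=tuple(item.get("partners", ())),
                msa=msa,
            )

        templates = [load_entry(item) for item in spec["templates"]]
        query = load_entry(spec["query"]) if spec.get("query") else None
        return cls(templates), query


class PredictionContext:
    """Lazily computed, cached derived data for one library + query."""

    def __init__(
        self,
        library: TemplateLibrary,
        query: LibraryEntry,
        config: InterDCTConfig | None = None,
    ):
        if query.id in library.ids:
            raise ValueError("query must not be one of the library templates")
        self.library = library
        self.query = query
        self.config = config or InterDCTConfig()
        self._interfaces: dict[str, InterfaceDefinition] = {}
        self._sasa: dict[str, SasaMap] = {}
        self._profiles: dict[str, ConservationProfile] = {}
        self._sequences: dict[str, str] = {}
        self._equivalences: dict[tuple[str, str], ResidueEquivalenceMap] = {}
        self._identities: dict[str, float] = {}

    # -- entry lookup -----------------------------------------------------
    def entry(self, protein_id: str) -> LibraryEntry:
        if protein_id == self.query.id:
            return self.query
        return self.library.get(protein_id)

    @property
    def ids(self) -> list[str]:
        """Template ids followed by the query id (matrix order)."""
        return self.library.ids + [self.query.id]

    # -- derived data -----------------------------------------------------
    def interface(self, protein_id: str) -> InterfaceDefinition:
        """The detected (true) interface of a template complex."""
        if protein_id == self.query.id:
            raise KeyError("the query's interface is withheld by definition")
        if protein_id not in self._interfaces:
            entry = self.library.get(protein_id)
            if not entry.partner_chains:
                raise ValueError(f"template {protein_id} has no partner chains")
            iface, _ = detect_interface(
                entry.structure, entry.chain, entry.partner_chains, self.config.contact
            )
            self._interfaces[protein_id] = iface
        return self._interfaces[protein_id]

    def sasa(self, protein_id: str) -> SasaMap:
        """SASA of the isolated subject chain (prediction context has no ligand)."""
        if protein_id not in self._sasa:
            entry = self.entry(protein_id)
            self._sasa[protein_id] = compute_sasa(
                entry.structure,
                probe_radius=self.config.sasa_probe,
                n_points=self.config.sasa_points,
                chain_ids=[entry.chain],
            )
        return self._sasa[protein_id]

    def profile(self, protein_id: str) -> ConservationProfile:
        if protein_id not in self._profiles:
            entry = self.entry(protein_id)
            if entry.msa is None:
                raise ValueError(f"no MSA supplied for {protein_id}")
            self._profiles[protein_id] = profile_for_structure(
                entry.msa,
                entry.structure,
                entry.chain,
                background=self.config.background_distribution(),
                lam=self.config.jsd_lambda,
            )
        return self._profiles[protein_id]

    def sequence(self, protein_id: str) -> str:
        if protein_id not in self._sequences:
            entry = self.entry(protein_id)
            seq, _ = extract_sequence(entry.structure, entry.chain)
            self._sequences[protein_id] = seq
        return self._sequences[protein_id]

    def equivalence(self, source_id: str, target_id: str) -> ResidueEquivalenceMap:
        key = (source_id, target_id)
        if key not in self._equivalences:
            src = self.entry(source_id)
            tgt = self.entry(target_id)
            eq = superpose(
                src.structure, src.chain, tgt.structure, tgt.chain,
                distance_gate=self.config.distance_gate,
            )
            self._equivalences[key] = eq
            self._equivalences[(target_id, source_id)] = eq.inverted()
        return self._equivalences[key]

    def identity_to_query(self, template_id: str) -> float:
        if template_id not in self._identities:
            self._identities[template_id] = sequence_identity(
                self.sequence(template_id), self.sequence(self.query.id)
            )
        return self._identities[template_id]

    def all_equivalences(self) -> dict[tuple[str, str], ResidueEquivalenceMap]:
        """Equivalences for every ordered pair with a template source."""
        out: dict[tuple[str, str], ResidueEquivalenceMap] = {}
        ids = self.ids
        for source in self.library.ids:
            for target in ids:
                if source != target:
                    out[(source, target)] = self.equivalence(source, target)
        return out
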