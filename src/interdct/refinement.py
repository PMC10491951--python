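"""Refinement of an interface prediction by docked-pose residue frequencies.

Rigid poses of small probe proteins against the query are scored by the
overlap (F1) of their contact interface with the initial prediction; over the
best-overlapping poses, each query residue's occurrence frequency is
tabulated separately for residues inside the initial prediction (true
positive frequency) and outside it (false positive frequency).  The refined
interface keeps inside residues seen in more than 50% of the top poses and
adds outside residues seen in more than 35%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .contacts import ContactParams, detect_interface
from .evaluation import f_score
from .library import InterDCTConfig
from .prediction import InterDCTPrediction
from .structure import ResidueKey, StructureModel, assign_vdw_radii, read_pdb

logger = logging.getLogger(__name__)

__all__ = [
    "DockedPose",
    "RefinedPrediction",
    "load_poses",
    "pose_interface",
    "select_top_poses",
    "frequency_refine",
    "refine",
    "naive_pose_sampler",
]


@dataclass(frozen=True)
class DockedPose:
    """One rigid placement of a probe protein in the query's frame."""

    pose_id: str
    probe_id: str
    probe: StructureModel  # probe chain(s) only, already positioned


@dataclass(frozen=True)
class RefinedPrediction:
    query_id: str
    residues: frozenset[ResidueKey]
    tp_frequency: dict[ResidueKey, float]
    fp_frequency: dict[ResidueKey, float]
    n_top_poses: int
    n_poses_evaluated: int


def load_poses(
    directory: str | Path,
    query: StructureModel,
    probe_chain: str | None = None,
) -> list[DockedPose]:
    """Load poses from a directory of single-pose PDB files.

    Each file must contain the probe chain; the query's chain ids must be
    absent from the probe.  Files missing the probe chain are skipped with a
    warning; duplicate pose ids are an error.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.pdb"))
    if not files:
        raise ValueError(f"no pose PDB files in {directory}")
    query_chains = set(query.chain_ids)
    poses: list[DockedPose] = []
    seen: set[str] = set()
    for path in files:
        model = assign_vdw_radii(read_pdb(path))
        chains = [c for c in model.chain_ids if c not in query_chains]
        if probe_chain is not None:
            chains = [c for c in chains if c == probe_chain]
        if not chains:
            logger.warning("pose file %s has no probe chain; skipped", path.name)
            continue
        pose_id = path.stem
        if pose_id in seen:
            raise ValueError(f"duplicate pose id {pose_id!r}")
        seen.add(pose_id)
        probe_id = pose_id.rsplit("_", 1)[0]
        poses.append(DockedPose(pose_id=pose_id, probe_id=probe_id, probe=model.subset(chains)))
    logger.info("loaded %d poses from %s", len(poses), directory)
    if not poses:
        raise ValueError(f"no usable poses in {directory}")
    return poses


def _combined(query: StructureModel, query_chain: str, probe: StructureModel) -> StructureModel:
    chains = [c for c in query.chains if c.id == query_chain] + list(probe.chains)
    return StructureModel(id=f"{query.id}+{probe.id}", chains=chains)


def pose_interface(
    query: StructureModel,
    query_chain: str,
    pose: DockedPose,
    params: ContactParams | None = None,
) -> frozenset[ResidueKey]:
    """Query-side interface residues against the posed probe."""
    combined = _combined(query, query_chain, pose.probe)
    iface, _ = detect_interface(
        combined, query_chain, [c.id for c in pose.probe.chains], params
    )
    return iface.residues


def select_top_poses(
    poses: Sequence[DockedPose],
    pose_interfaces: Sequence[frozenset[ResidueKey]],
    initial: InterDCTPrediction,
    n: int = 100,
    metric: str = "fscore",
) -> list[int]:
    """Indices of the ``n`` poses whose interfaces best overlap the initial
    prediction (F1 by default, raw intersection size as an alternative);
    ties resolve by pose id.  Returns an empty list when every pose interface
    is empty (the caller should skip refinement)."""
    if len(poses) != len(pose_interfaces):
        raise ValueError("poses and pose_interfaces differ in length")
    if all(len(s) == 0 for s in pose_interfaces):
        return []
    if metric == "fscore":
        scores = [f_score(s, initial.residues).f1 for s in pose_interfaces]
    elif metric == "intersection":
        scores = [float(len(s & initial.residues)) for s in pose_interfaces]
    else:
        raise ValueError(f"unknown overlap metric {metric!r}")
    order = sorted(range(len(poses)), key=lambda i: (-scores[i], poses[i].pose_id))
    if n > len(poses):
        logger.info("only %d poses available for top-%d selection", len(poses), n)
    return order[: min(n, len(poses))]


def frequency_refine(
    top_interfaces: Sequence[frozenset[ResidueKey]],
    initial: InterDCTPrediction,
    tp_min: float = 0.50,
    fp_min: float = 0.35,
    n_poses_evaluated: int | None = None,
) -> RefinedPrediction:
    """Keep/add residues by their occurrence frequency over the top poses.

    True-positive frequency applies to residues inside the initial
    prediction (kept when strictly above ``tp_min``); false-positive
    frequency to residues outside it (added when strictly above ``fp_min``).
    An empty refined set falls back to the initial prediction (warned).
    """
    if not top_interfaces:
        raise ValueError("no top poses supplied")
    n = len(top_interfaces)
    counts: dict[ResidueKey, int] = {}
    for iface in top_interfaces:
        for r in iface:
            counts[r] = counts.get(r, 0) + 1
    tp_freq = {r: counts.get(r, 0) / n for r in initial.residues}
    fp_freq = {r: c / n for r, c in counts.items() if r not in initial.residues}
    refined = {r for r, f in tp_freq.items() if f > tp_min} | {
        r for r, f in fp_freq.items() if f > fp_min
    }
    if not refined:
        logger.warning("refinement produced an empty set; keeping initial prediction")
        refined = set(initial.residues)
    return RefinedPrediction(
        query_id=initial.query_id,
        residues=frozenset(refined),
        tp_frequency=tp_freq,
        fp_frequency=fp_freq,
        n_top_poses=n,
        n_poses_evaluated=n_poses_evaluated if n_poses_evaluated is not None else n,
    )


def refine(
    query: StructureModel,
    query_chain: str,
    poses: Sequence[DockedPose],
    initial: InterDCTPrediction,
    config: InterDCTConfig | None = None,
) -> RefinedPrediction:
    """Full refinement driver: evaluate every pose interface, select the top
    overlap set, and apply the frequency rules.  The number of evaluated pose
    interfaces is recorded on the result (count contract: probes x poses)."""
    config = config or InterDCTConfig()
    interfaces = [
        pose_interface(query, query_chain, pose, config.contact) for pose in poses
    ]
    top = select_top_poses(
        poses, interfaces, initial, n=config.n_top_poses, metric=config.pose_overlap_metric
    )
    if not top:
        logger.warning("all pose interfaces empty; refinement skipped")
        return RefinedPrediction(
            query_id=initial.query_id,
            residues=initial.residues,
            tp_frequency={r: 0.0 for r in initial.residues},
            fp_frequency={},
            n_top_poses=0,
            n_poses_evaluated=len(poses),
        )
    return frequency_refine(
        [interfaces[i] for i in top],
        initial,
        tp_min=config.tp_min,
        fp_min=config.fp_min,
        n_poses_evaluated=len(poses),
    )


# ---------------------------------------------------------------------------
# naive rigid pose sampler (fixture stand-in for an external docking engine)
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def naive_pose_sampler(
    query: StructureModel,
    query_chain: str,
    probe: StructureModel,
    n: int = 2000,
    seed: int = 0,
    params: ContactParams | None = None,
    clash_factor: float = 0.7,
) -> list[DockedPose]:
    """Uniform random surface-contact poses of a probe around the query.

    Each pose applies a random rotation to the probe and slides it along a
    random direction until at least one query-probe atom pair is within the
    contact distance while no heavy-atom pair is closer than ``clash_factor``
    times the radius sum.  Deterministic given ``seed``.
    """
    params = params or ContactParams()
    rng = np.random.default_rng(seed)
    q_xyz, q_rad, _ = query.atom_arrays([query_chain])
    p_xyz0, p_rad, _ = probe.atom_arrays()
    if len(p_xyz0) == 0 or len(q_xyz) == 0:
        raise ValueError("query and probe must both contain atoms")
    p_center = p_xyz0.mean(axis=0)
    q_center = q_xyz.mean(axis=0)
    q_span = np.linalg.norm(q_xyz - q_center, axis=1).max()
    p_span = np.linalg.norm(p_xyz0 - p_center, axis=1).max()
    cutoff = q_rad[:, None] + p_rad[None, :] + params.solvent_diameter
    clash = clash_factor * (q_rad[:, None] + p_rad[None, :])

    poses: list[DockedPose] = []
    attempts = 0
    max_attempts = 100 * n
    while len(poses) < n:
        if attempts >= max_attempts:
            raise RuntimeError(f"could not place probe after {max_attempts} attempts")
        attempts += 1
        rot = _random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        local = (p_xyz0 - p_center) @ rot.T
        t = q_span + p_span + cutoff.max()
        placed = None
        while t > 0:
            p_xyz = local + q_center + t * direction
            d = np.linalg.norm(q_xyz[:, None, :] - p_xyz[None, :, :], axis=2)
            if (d < clash).any():
                break
            if (d < cutoff).any():
                placed = p_xyz
                break
            t -= 0.25
        if placed is None:
            continue
        pose_structure = StructureModel(id=f"{probe.id}_pose{len(poses)}", chains=[])
        probe_copy = probe.copy()
        for ch in probe_copy.chains:
            for res in ch.residues:
                for atom in res.atoms:
                    atom.coords = rot @ (atom.coords - p_center) + q_center + t * direction
            pose_structure.chains.append(ch)
        poses.append(
            DockedPose(
                pose_id=f"{probe.id}_{len(poses):04d}",
                probe_id=probe.id,
                probe=pose_structure,
            )
        )
    return poses
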