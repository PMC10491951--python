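"""Initial interface prediction: clustered consensus or the trivial path.

A query sharing more than 35% sequence identity with any template is routed
to the trivial path (map the best-identity template plus any template within
20 percentage points of it that also exceeds 35%).  All other queries run the
full clustering pipeline and take the consensus of the selected subset:
residues mapped by at least 20% of the subset templates that are solvent
exposed (SASA ≥ 5 Å²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clustering import (
    MappingMatrix,
    TemplateSubset,
    build_mapping_matrix,
    correlation_distance_matrix,
    rank_rows,
    score_matrix,
    select_query_subtree,
    wpgma_cluster,
)
from .library import InterDCTConfig, LibraryEntry, PredictionContext, TemplateLibrary
from .mapping import map_interface
from .structure import ResidueKey

logger = logging.getLogger(__name__)

__all__ = ["InterDCTPrediction", "consensus_predict", "trivial_predict", "predict",
           "clustered_subset", "mapping_matrix_for"]


@dataclass(frozen=True)
class InterDCTPrediction:
    """An interface prediction with per-residue support and provenance."""

    query_id: str
    residues: frozenset[ResidueKey]
    support: dict[ResidueKey, float]
    path_taken: str  # "trivial" | "clustered"
    template_ids: tuple[str, ...]

    def write_tsv(self, path) -> None:
        from pathlib import Path

        lines = ["chain\tresnum\ticode\tresname\tsupport\tpath"]
        for key in sorted(self.residues):
            lines.append(
                f"{key.chain_id}\t{key.seq_number}\t{key.insertion_code}\t"
                f"{key.residue_name}\t{self.support.get(key, 0.0):.3f}\t{self.path_taken}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def consensus_predict(
    subset: TemplateSubset | tuple[str, ...],
    context: PredictionContext,
    target_id: str | None = None,
    min_support: float | None = None,
) -> InterDCTPrediction:
    """Consensus of the subset templates' interfaces mapped onto the target.

    A residue is kept when it is mapped by at least ``min_support`` (default
    20%, inclusive) of the subset templates and its SASA is at least the
    burial threshold.  ``target_id`` defaults to the context's query; passing
    a template id supports the leave-one-out confidence machinery.
    """
    cfg = context.config
    min_support = cfg.min_support if min_support is None else min_support
    template_ids = subset.template_ids if isinstance(subset, TemplateSubset) else tuple(subset)
    if not template_ids:
        raise ValueError("template subset is empty")
    target_id = target_id or context.query.id

    counts: dict[ResidueKey, int] = {}
    for tid in template_ids:
        eq = context.equivalence(tid, target_id)
        mapped = map_interface(context.interface(tid), eq)
        for r in mapped.residues:
            counts[r] = counts.get(r, 0) + 1
    n = len(template_ids)
    sasa = context.sasa(target_id)
    kept: dict[ResidueKey, float] = {}
    for r, c in counts.items():
        if c + 1e-9 >= min_support * n and sasa.get(r, 0.0) >= cfg.min_sasa:
            kept[r] = c / n
    return InterDCTPrediction(
        query_id=target_id,
        residues=frozenset(kept),
        support=kept,
        path_taken="clustered",
        template_ids=template_ids,
    )


def trivial_predict(context: PredictionContext) -> InterDCTPrediction:
    """High-identity path: union of the best template's interface mapping and
    every template above the identity threshold within the identity window of
    the best."""
    cfg = context.config
    identities = {tid: context.identity_to_query(tid) for tid in context.library.ids}
    best_id = max(identities, key=lambda t: (identities[t], t))
    best = identities[best_id]
    if best <= cfg.identity_threshold:
        raise ValueError(
            f"no template above {cfg.identity_threshold}% identity; "
            "use the clustered path"
        )
    selected = [
        tid
        for tid, ident in identities.items()
        if tid == best_id
        or (ident > cfg.identity_threshold and ident >= best - cfg.identity_window)
    ]
    counts: dict[ResidueKey, int] = {}
    for tid in selected:
        eq = context.equivalence(tid, context.query.id)
        mapped = map_interface(context.interface(tid), eq)
        for r in mapped.residues:
            counts[r] = counts.get(r, 0) + 1
    sasa = context.sasa(context.query.id)
    kept = {
        r: c / len(selected)
        for r, c in counts.items()
        if sasa.get(r, 0.0) >= cfg.min_sasa
    }
    return InterDCTPrediction(
        query_id=context.query.id,
        residues=frozenset(kept),
        support=kept,
        path_taken="trivial",
        template_ids=tuple(selected),
    )


def mapping_matrix_for(context: PredictionContext) -> MappingMatrix:
    ids = context.ids
    interfaces = {tid: context.interface(tid) for tid in context.library.ids}
    sasa = {pid: context.sasa(pid) for pid in ids}
    return build_mapping_matrix(
        ids,
        context.query.id,
        interfaces,
        context.all_equivalences(),
        sasa,
        min_sasa=context.config.min_sasa,
    )


def clustered_subset(
    context: PredictionContext,
    matrix: MappingMatrix | None = None,
    score_mode: str = "frequency",
    seed: int | None = None,
    score_override: np.ndarray | None = None,
):
    """Run matrix → scores → ranks → distances → WPGMA → subtree selection.

    ``score_override`` replaces the conservation-sum score values (used by
    the hypothetical-best benchmark mode); otherwise scores come from
    :func:`score_matrix` in the requested mode.
    """
    from .clustering import ScoreMatrix

    matrix = matrix if matrix is not None else mapping_matrix_for(context)
    if score_override is not None:
        sm = ScoreMatrix(ids=matrix.ids, query_id=matrix.query_id, values=score_override)
    else:
        profiles = {pid: context.profile(pid) for pid in matrix.ids}
        sm = score_matrix(matrix, profiles, k=context.config.top_k, mode=score_mode, seed=seed)
    rm = rank_rows(sm)
    dist = correlation_distance_matrix(rm)
    tree = wpgma_cluster(dist, matrix.ids)
    subset = select_query_subtree(tree, context.query.id)
    return subset, tree, matrix


def predict(
    library: TemplateLibrary,
    query: LibraryEntry,
    config: InterDCTConfig | None = None,
    context: PredictionContext | None = None,
) -> InterDCTPrediction:
    """Route the query to the trivial or clustered path and predict."""
    if len(library) == 0:
        raise ValueError("template library is empty")
    context = context or PredictionContext(library, query, config)
    identities = {tid: context.identity_to_query(tid) for tid in library.ids}
    if max(identities.values()) > context.config.identity_threshold:
        logger.info("query %s routed to trivial path", query.id)
        return trivial_predict(context)
    logger.info("query %s routed to clustered path", query.id)
    subset, _, _ = clustered_subset(context)
    return consensus_predict(subset, context)
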