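"""Confidence labelling from template reliability and template inconsistency.

The clustering pipeline is re-run with randomised residue selection (eight
random interface residues per matrix cell instead of the top-eight most
frequent), giving an alternative template subset per repetition.  Within each
alternative subset, every member template's own interface is re-predicted by
leave-one-out consensus and scored against its true interface.  Template
reliability is the mean over repetitions of the per-repetition mean F-score;
template inconsistency is the mean of the per-repetition (population)
standard deviations.  High confidence requires reliability > 0.525 and
inconsistency < 0.175; low requires reliability < 0.525 and inconsistency
> 0.175; everything else — including exact boundary values — is medium.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

from .clustering import MappingMatrix, TemplateSubset
from .evaluation import f_score
from .library import PredictionContext
from .prediction import clustered_subset, consensus_predict, mapping_matrix_for

logger = logging.getLogger(__name__)

__all__ = [
    "RepetitionRecord",
    "ConfidenceReport",
    "classify_confidence",
    "alternative_subset",
    "loo_cluster_fscores",
    "assess_confidence",
]


@dataclass(frozen=True)
class RepetitionRecord:
    seed: int
    subset: tuple[str, ...]
    fscores: tuple[float, ...]
    mean_f: float | None
    std_f: float | None
    skipped: bool = False


@dataclass(frozen=True)
class ConfidenceReport:
    query_id: str
    template_reliability: float
    template_inconsistency: float
    label: str
    n_repetitions: int
    repetitions: tuple[RepetitionRecord, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "template_reliability": self.template_reliability,
            "template_inconsistency": self.template_inconsistency,
            "label": self.label,
            "n_repetitions": self.n_repetitions,
            "repetitions": [vars(r) for r in self.repetitions],
        }


def classify_confidence(
    reliability: float,
    inconsistency: float,
    reliability_cutoff: float = 0.525,
    inconsistency_cutoff: float = 0.175,
) -> str:
    """Strict-inequality three-way rule; boundary equality falls to medium."""
    if reliability > reliability_cutoff and inconsistency < inconsistency_cutoff:
        return "high"
    if reliability < reliability_cutoff and inconsistency > inconsistency_cutoff:
        return "low"
    return "medium"


def alternative_subset(
    context: PredictionContext,
    seed: int,
    matrix: MappingMatrix | None = None,
) -> TemplateSubset:
    """Template subset from one randomised-residue clustering run."""
    if len(context.library) < 2:
        raise ValueError("need at least 2 templates for alternative clustering")
    subset, _, _ = clustered_subset(
        context, matrix=matrix, score_mode="random", seed=seed
    )
    return subset


def loo_cluster_fscores(
    subset: TemplateSubset | tuple[str, ...],
    context: PredictionContext,
) -> tuple[float, float, tuple[float, ...]]:
    """Leave-one-out self-consistency of a template subset.

    Each subset template's interface is predicted by consensus over the
    remaining subset members and scored (F1) against its true interface.
    Returns (mean, population std, per-template F-scores).  A singleton
    subset is undefined and raises.
    """
    ids = subset.template_ids if isinstance(subset, TemplateSubset) else tuple(subset)
    if len(ids) < 2:
        raise ValueError("leave-one-out undefined for a singleton subset")
    fscores = []
    for tid in ids:
        others = tuple(t for t in ids if t != tid)
        pred = consensus_predict(others, context, target_id=tid)
        fscores.append(f_score(pred.residues, context.interface(tid).residues).f1)
    mean = statistics.fmean(fscores)
    ddof = context.config.std_ddof
    n = len(fscores)
    var = sum((f - mean) ** 2 for f in fscores) / (n - ddof)
    return mean, var ** 0.5, tuple(fscores)


def assess_confidence(
    context: PredictionContext,
    repetitions: int | None = None,
    base_seed: int = 0,
) -> ConfidenceReport:
    """Run the alternative-clustering repetitions and label the prediction."""
    if len(context.library) < 2:
        raise ValueError("need at least 2 templates to assess confidence")
    cfg = context.config
    repetitions = cfg.confidence_repetitions if repetitions is None else repetitions
    matrix = mapping_matrix_for(context)
    records: list[RepetitionRecord] = []
    for i in range(repetitions):
        seed = base_seed + i
        subset = alternative_subset(context, seed=seed, matrix=matrix)
        if len(subset.template_ids) < 2:
            logger.info("repetition %d: singleton subset, skipped", i)
            records.append(
                RepetitionRecord(
                    seed=seed, subset=subset.template_ids, fscores=(),
                    mean_f=None, std_f=None, skipped=True,
                )
            )
            continue
        mean, std, fscores = loo_cluster_fscores(subset, context)
        records.append(
            RepetitionRecord(
                seed=seed, subset=subset.template_ids, fscores=fscores,
                mean_f=mean, std_f=std,
            )
        )
    used = [r for r in records if not r.skipped]
    if not used:
        raise RuntimeError("all confidence repetitions were skipped")
    reliability = statistics.fmean(r.mean_f for r in used)
    inconsistency = statistics.fmean(r.std_f for r in used)
    label = classify_confidence(
        reliability, inconsistency, cfg.reliability_cutoff, cfg.inconsistency_cutoff
    )
    return ConfidenceReport(
        query_id=context.query.id,
        template_reliability=reliability,
        template_inconsistency=inconsistency,
        label=label,
        n_repetitions=len(used),
        repetitions=tuple(records),
    )
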