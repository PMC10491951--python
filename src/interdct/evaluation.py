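"""F-score metric, leave-one-out benchmarking, and baseline predictors."""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .library import InterDCTConfig, LibraryEntry, PredictionContext, TemplateLibrary
from .mapping import map_interface
from .prediction import InterDCTPrediction, clustered_subset, consensus_predict, predict
from .structure import ResidueKey

logger = logging.getLogger(__name__)

__all__ = ["FScoreResult", "QueryResult", "BenchmarkReport", "f_score", "leave_one_out",
           "naive_predict", "hypothetical_best_subset"]


@dataclass(frozen=True)
class FScoreResult:
    tp: int
    fp: int
    fn: int

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        if denom == 0:
            # empty prediction vs empty truth: defined as 0 (templates always
            # have non-empty interfaces, so this marks a degenerate case)
            logger.debug("F-score undefined at tp=fp=fn=0; reporting 0")
            return 0.0
        return 2.0 * self.tp / denom


def f_score(predicted: Iterable[ResidueKey], actual: Iterable[ResidueKey]) -> FScoreResult:
    """Standard F1 over residue-key sets: tp=|P∩A|, fp=|P\\A|, fn=|A\\P|."""
    p = frozenset(predicted)
    a = frozenset(actual)
    return FScoreResult(tp=len(p & a), fp=len(p - a), fn=len(a - p))


@dataclass(frozen=True)
class QueryResult:
    query_id: str
    f1: float
    tp: int
    fp: int
    fn: int
    path: str
    n_predicted: int
    max_identity: float
    confidence: str | None = None
    error: str | None = None


@dataclass
class BenchmarkReport:
    mode: str
    results: list[QueryResult] = field(default_factory=list)

    def _subset(self, trivial: bool | None) -> list[QueryResult]:
        ok = [r for r in self.results if r.error is None]
        if trivial is None:
            return ok
        return [r for r in ok if (r.max_identity > 35.0) == trivial]

    def mean_f(self, trivial: bool | None = None) -> float:
        sub = self._subset(trivial)
        return float(statistics.fmean(r.f1 for r in sub)) if sub else float("nan")

    def median_f(self, trivial: bool | None = None) -> float:
        sub = self._subset(trivial)
        return float(statistics.median(r.f1 for r in sub)) if sub else float("nan")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "mean_f": self.mean_f(),
            "median_f": self.median_f(),
            "mean_f_nontrivial": self.mean_f(trivial=False),
            "median_f_nontrivial": self.median_f(trivial=False),
            "mean_f_trivial": self.mean_f(trivial=True),
            "per_query": [vars(r) for r in self.results],
        }


def naive_predict(context: PredictionContext) -> InterDCTPrediction:
    """Baseline: map the single highest-identity template onto the query."""
    identities = {tid: context.identity_to_query(tid) for tid in context.library.ids}
    best = max(identities, key=lambda t: (identities[t], t))
    eq = context.equivalence(best, context.query.id)
    mapped = map_interface(context.interface(best), eq)
    sasa = context.sasa(context.query.id)
    kept = frozenset(r for r in mapped.residues if sasa.get(r, 0.0) >= context.config.min_sasa)
    return InterDCTPrediction(
        query_id=context.query.id,
        residues=kept,
        support={r: 1.0 for r in kept},
        path_taken="naive",
        template_ids=(best,),
    )


def hypothetical_best_subset(context: PredictionContext, truth: frozenset[ResidueKey]):
    """Upper-bound template selection: score rows are pairwise interface F1.

    Each matrix cell is scored by the F1 between its mapped residue set and
    the target's true interface (the withheld query truth included), then the
    ranking/clustering/subtree machinery runs unchanged.
    """
    from .prediction import mapping_matrix_for

    matrix = mapping_matrix_for(context)
    n = matrix.n
    values = np.zeros((n, n))
    for ti, target in enumerate(matrix.ids):
        target_truth = truth if target == context.query.id else context.interface(target).residues
        for si, source in enumerate(matrix.ids):
            if source == context.query.id:
                continue
            values[ti, si] = f_score(matrix.cells[ti][si], target_truth).f1
    subset, tree, _ = clustered_subset(context, matrix=matrix, score_override=values)
    return subset, tree, matrix


def leave_one_out(
    library: TemplateLibrary,
    config: InterDCTConfig | None = None,
    mode: str = "full",
    with_confidence: bool = False,
    confidence_seed: int = 0,
) -> BenchmarkReport:
    """Withhold each template's interface in turn and predict it.

    ``mode="full"`` runs the routed predictor, ``"naive"`` maps the single
    best-identity template, ``"hypothetical_best"`` clusters on pairwise
    interface F-scores (an oracle upper bound that may consult the withheld
    truth when scoring rows).  Failures are recorded per query, not fatal.
    """
    if len(library) < 3:
        raise ValueError("leave-one-out needs at least 3 templates")
    if mode not in ("full", "naive", "hypothetical_best"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or InterDCTConfig()
    report = BenchmarkReport(mode=mode)
    for query_entry in list(library):
        rest = library.without(query_entry.id)
        # the query's true interface, detected from its own complex
        from .contacts import detect_interface

        truth, _ = detect_interface(
            query_entry.structure, query_entry.chain, query_entry.partner_chains,
            config.contact,
        )
        query = LibraryEntry(
            id=query_entry.id,
            structure=query_entry.structure,
            chain=query_entry.chain,
            partner_chains=(),
            msa=query_entry.msa,
        )
        context = PredictionContext(rest, query, config)
        try:
            max_ident = max(context.identity_to_query(t) for t in rest.ids)
            if mode == "naive":
                pred = naive_predict(context)
            elif mode == "hypothetical_best":
                subset, _, _ = hypothetical_best_subset(context, truth.residues)
                pred = consensus_predict(subset, context)
            else:
                pred = predict(rest, query, config, context=context)
            confidence = None
            if with_confidence:
                from .confidence import assess_confidence

                confidence = assess_confidence(
                    context, base_seed=confidence_seed
                ).label
            fs = f_score(pred.residues, truth.residues)
            report.results.append(
                QueryResult(
                    query_id=query_entry.id,
                    f1=fs.f1,
                    tp=fs.tp,
                    fp=fs.fp,
                    fn=fs.fn,
                    path=pred.path_taken,
                    n_predicted=len(pred.residues),
                    max_identity=max_ident,
                    confidence=confidence,
                )
            )
        except Exception as exc:  # per-query failures are recorded, not fatal
            logger.warning("query %s failed: %s", query_entry.id, exc)
            report.results.append(
                QueryResult(
                    query_id=query_entry.id, f1=0.0, tp=0, fp=0, fn=0,
                    path="error", n_predicted=0, max_identity=float("nan"),
                    error=str(exc),
                )
            )
    return report
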