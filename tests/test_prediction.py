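"""Consensus and trivial-path prediction, routing."""

import numpy as np
import pytest

from interdct.conservation import AMINO_ACIDS, Msa
from interdct.library import InterDCTConfig, LibraryEntry, PredictionContext, TemplateLibrary
from interdct.prediction import consensus_predict, predict, trivial_predict
from interdct.synthetic import _build_complex


BASE = ("ACDEFGHIKLMNPQRSTVWY" * 3)[:50]


def variant(sequence, n_substitutions, salt=0):
    """Substitute n spread-out positions with different letters."""
    rng = np.random.default_rng(100 + salt)
    idx = rng.choice(len(sequence), size=n_substitutions, replace=False)
    out = list(sequence)
    for i in idx:
        out[i] = AMINO_ACIDS[(AMINO_ACIDS.index(out[i]) + 7) % 20]
    return "".join(out)


def entry(pid, sequence, patch, with_msa=False):
    rng = np.random.default_rng(0)
    structure = _build_complex(pid, sequence, patch, rng, coord_noise=0.0)
    msa = Msa(ids=(pid, pid + "_h"), rows=(sequence, sequence), reference_id=pid) if with_msa else None
    return LibraryEntry(id=pid, structure=structure, chain="A", partner_chains=("B",), msa=msa)


def make_context(entries, query_entry, config=None):
    return PredictionContext(TemplateLibrary(entries), query_entry, config)


class TestConsensusPredict:
    def _five_template_context(self, config=None):
        # T0 binds patch [10,18); T1-T4 bind patch [20,28)
        templates = [entry("T0", BASE, (10, 18))] + [
            entry(f"T{i}", BASE, (20, 28)) for i in range(1, 5)
        ]
        query = LibraryEntry(
            id="Q", structure=_build_complex("Q", BASE, (20, 28),
                                             np.random.default_rng(1), 0.0),
            chain="A",
        )
        return make_context(templates, query, config)

    def test_support_boundary_inclusive_at_20_percent(self):
        ctx = self._five_template_context()
        pred = consensus_predict(tuple(f"T{i}" for i in range(5)), ctx)
        numbers = sorted(k.seq_number for k in pred.residues)
        # residues 11..18 mapped by 1/5 templates: support 0.20 -> kept
        assert set(range(11, 19)) <= set(numbers)
        assert set(range(21, 29)) <= set(numbers)
        r = next(k for k in pred.residues if k.seq_number == 11)
        assert pred.support[r] == pytest.approx(0.2)

    def test_burial_rule_dominates_support(self):
        ctx = self._five_template_context(InterDCTConfig(min_sasa=1e9))
        pred = consensus_predict(tuple(f"T{i}" for i in range(5)), ctx)
        assert pred.residues == frozenset()

    def test_single_template_returns_its_filtered_interface(self):
        ctx = self._five_template_context()
        pred = consensus_predict(("T1",), ctx)
        assert sorted(k.seq_number for k in pred.residues) == list(range(21, 29))
        assert all(v == pytest.approx(1.0) for v in pred.support.values())

    def test_raising_min_support_never_grows_prediction(self):
        ctx = self._five_template_context()
        subset = tuple(f"T{i}" for i in range(5))
        previous = None
        for support in (0.2, 0.5, 0.9):
            pred = consensus_predict(subset, ctx, min_support=support)
            if previous is not None:
                assert pred.residues <= previous
            previous = pred.residues

    def test_empty_subset_rejected(self):
        ctx = self._five_template_context()
        with pytest.raises(ValueError):
            consensus_predict((), ctx)


class TestTrivialPredict:
    def test_identity_window_excludes_distant_template(self):
        # identities ~80/60/40: the 40% one falls outside best-20
        templates = [
            entry("T80", variant(BASE, 10, salt=1), (10, 18)),
            entry("T60", variant(BASE, 20, salt=2), (20, 28)),
            entry("T40", variant(BASE, 30, salt=3), (30, 38)),
        ]
        query = LibraryEntry(
            id="Q", structure=_build_complex("Q", BASE, (10, 18),
                                             np.random.default_rng(1), 0.0),
            chain="A",
        )
        ctx = make_context(templates, query)
        idents = {t: ctx.identity_to_query(t) for t in ("T80", "T60", "T40")}
        assert idents["T80"] == pytest.approx(80.0)
        assert idents["T60"] == pytest.approx(60.0)
        assert idents["T40"] == pytest.approx(40.0)
        pred = trivial_predict(ctx)
        assert set(pred.template_ids) == {"T80", "T60"}
        numbers = {k.seq_number for k in pred.residues}
        assert numbers == set(range(11, 19)) | set(range(21, 29))

    def test_window_bites_even_above_threshold(self):
        # 36% > 35% but 36 < 90 - 20 -> only the 90% template is used
        templates = [
            entry("T90", variant(BASE, 5, salt=4), (10, 18)),
            entry("T36", variant(BASE, 32, salt=5), (30, 38)),
        ]
        query = LibraryEntry(
            id="Q", structure=_build_complex("Q", BASE, (10, 18),
                                             np.random.default_rng(1), 0.0),
            chain="A",
        )
        ctx = make_context(templates, query)
        assert ctx.identity_to_query("T90") == pytest.approx(90.0)
        assert ctx.identity_to_query("T36") == pytest.approx(36.0)
        pred = trivial_predict(ctx)
        assert pred.template_ids == ("T90",)

    def test_single_template_just_above_threshold(self):
        templates = [entry("T36", variant(BASE, 32, salt=6), (10, 18))]
        query = LibraryEntry(
            id="Q", structure=_build_complex("Q", BASE, (10, 18),
                                             np.random.default_rng(1), 0.0),
            chain="A",
        )
        ctx = make_context(templates, query)
        pred = trivial_predict(ctx)
        assert pred.template_ids == ("T36",)

    def test_no_template_above_threshold_raises(self):
        templates = [entry("T20", variant(BASE, 40, salt=7), (10, 18))]
        query = LibraryEntry(
            id="Q", structure=_build_complex("Q", BASE, (10, 18),
                                             np.random.default_rng(1), 0.0),
            chain="A",
        )
        with pytest.raises(ValueError):
            trivial_predict(make_context(templates, query))


class TestRouting:
    def test_duplicate_query_routes_trivially_with_perfect_f(self, family):
        from interdct.evaluation import f_score

        template = family.library.get("T0_0")
        query = LibraryEntry(
            id="Qcopy", structure=template.structure.copy(), chain="A", msa=template.msa,
        )
        pred = predict(family.library, query)
        assert pred.path_taken == "trivial"
        assert f_score(pred.residues, family.truths["T0_0"]).f1 == 1.0

    def test_low_identity_routes_to_clustered_path(self, family, query_context):
        ctx, truth = query_context
        pred = predict(family.library, ctx.query, context=ctx)
        assert pred.path_taken == "clustered"

    def test_prediction_is_deterministic(self, family, query_context):
        ctx, _ = query_context
        a = predict(family.library, ctx.query, context=ctx)
        b = predict(family.library, ctx.query,
                    context=PredictionContext(family.library, ctx.query))
        assert a.residues == b.residues
        assert a.template_ids == b.template_ids
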