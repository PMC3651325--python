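"""Confidence-based model combination vs a brute-force oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bioner.combination import combine_multi_class, combine_same_class
from bioner.corpus import Annotation, Sentence
from bioner.engine import TaggedSentence
from bioner.tokenization import tokenize

from .conftest import make_sentence


def tagged(sent: Sentence, anns, sent_conf: float) -> TaggedSentence:
    """Build a TaggedSentence from (start, end, type, conf) tuples."""
    annotations = [
        Annotation(t, s, e, confidence=c, sentence_id=sent.id)
        for s, e, t, c in anns
    ]
    labels = ["O"] * len(sent.tokens)
    for a in annotations:
        labels[a.token_start] = f"B-{a.entity_type}"
        for i in range(a.token_start + 1, a.token_end + 1):
            labels[i] = f"I-{a.entity_type}"
    return TaggedSentence(
        sentence=sent,
        labels=labels,
        sentence_confidence=sent_conf,
        annotations=annotations,
        per_annotation_confidence={a: a.confidence for a in annotations},
    )


@pytest.fixture
def sent():
    return make_sentence("w0 w1 w2 w3 w4 w5 w6 w7")


class TestSameClass:
    def test_overlap_takes_most_confident_model(self, sent):
        a = tagged(sent, [(1, 2, "PRGE", 0.9)], 0.9)
        b = tagged(sent, [(2, 3, "PRGE", 0.7)], 0.7)
        out = combine_same_class([a, b])
        assert [(x.token_start, x.token_end) for x in out] == [(1, 2)]

    def test_single_model_identity(self, sent):
        a = tagged(sent, [(0, 0, "PRGE", 0.5), (4, 5, "PRGE", 0.8)], 0.6)
        assert combine_same_class([a]) == a.annotations

    def test_disjoint_union(self, sent):
        a = tagged(sent, [(0, 0, "PRGE", 0.9)], 0.9)
        b = tagged(sent, [(4, 5, "PRGE", 0.7)], 0.7)
        out = combine_same_class([a, b])
        assert sorted((x.token_start, x.token_end) for x in out) == [(0, 0), (4, 5)]

    def test_empty_model_list_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            combine_same_class([])

    def test_permutation_invariant(self, sent):
        a = tagged(sent, [(1, 2, "PRGE", 0.9)], 0.9)
        b = tagged(sent, [(2, 3, "PRGE", 0.7)], 0.7)
        c = tagged(sent, [(6, 6, "PRGE", 0.8)], 0.8)
        results = [
            sorted((x.token_start, x.token_end) for x in combine_same_class(list(perm)))
            for perm in itertools.permutations([a, b, c])
        ]
        assert all(r == results[0] for r in results)


class TestMultiClass:
    def test_cluster_argmax(self, sent):
        prot = tagged(sent, [(2, 4, "protein", 0.8)], 0.8)
        dna = tagged(sent, [(3, 5, "DNA", 0.6)], 0.6)
        out = combine_multi_class([prot, dna])
        assert [(x.entity_type, x.token_start, x.token_end) for x in out] == [
            ("protein", 2, 4)
        ]

    def test_disjoint_all_kept(self, sent):
        models = [
            tagged(sent, [(0, 0, "protein", 0.5)], 0.5),
            tagged(sent, [(2, 2, "DNA", 0.4)], 0.4),
            tagged(sent, [(4, 4, "RNA", 0.9)], 0.9),
        ]
        out = combine_multi_class(models)
        assert len(out) == 3

    def test_tie_break_earlier_start_then_type(self, sent):
        a = tagged(sent, [(2, 3, "protein", 0.5)], 0.5)
        b = tagged(sent, [(3, 4, "DNA", 0.5)], 0.5)
        out = combine_multi_class([a, b])
        assert [(x.entity_type, x.token_start) for x in out] == [("protein", 2)]
        # same span, equal confidence: lexicographically smaller type wins
        c = tagged(sent, [(2, 3, "protein", 0.5)], 0.5)
        d = tagged(sent, [(2, 3, "DNA", 0.5)], 0.5)
        out2 = combine_multi_class([c, d])
        assert [x.entity_type for x in out2] == ["DNA"]

    def test_missing_confidence_is_error(self, sent):
        t = tagged(sent, [(0, 0, "protein", 0.5)], 0.5)
        bare = Annotation("DNA", 2, 2, sentence_id=sent.id)
        other = TaggedSentence(
            sentence=sent, labels=["O"] * len(sent.tokens),
            sentence_confidence=0.5, annotations=[bare],
            per_annotation_confidence={},
        )
        with pytest.raises(ValueError, match="confidence"):
            combine_multi_class([t, other])

    def test_output_non_overlapping_and_subset(self, sent):
        rng = np.random.default_rng(0)
        for _ in range(200):
            models = []
            for _m in range(int(rng.integers(1, 4))):
                anns = []
                used = set()
                for _a in range(int(rng.integers(0, 4))):
                    s = int(rng.integers(0, 7))
                    e = min(7, s + int(rng.integers(0, 2)))
                    if any(x in used for x in range(s, e + 1)):
                        continue
                    used.update(range(s, e + 1))
                    anns.append(
                        (s, e, str(rng.choice(["protein", "DNA", "RNA"])),
                         round(float(rng.uniform(0.1, 1.0)), 3))
                    )
                models.append(tagged(sent, anns, float(rng.uniform(0.1, 1.0))))
            out = combine_multi_class(models)
            inputs = {
                (a.entity_type, a.token_start, a.token_end)
                for m in models
                for a in m.annotations
            }
            for a in out:
                assert (a.entity_type, a.token_start, a.token_end) in inputs
            spans = sorted((a.token_start, a.token_end) for a in out)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2  # mutually non-overlapping


def brute_force_multi(models) -> set[tuple[str, int, int]]:
    """Oracle: explicit transitive-closure clustering + per-cluster argmax."""
    items = []
    for m in models:
        for a in m.annotations:
            cs, ce = m.sentence.char_span(a)
            items.append((cs, ce, a.confidence, a))
    clusters: list[list] = []
    for it in items:
        hits = [
            c for c in clusters
            if any(it[0] < o[1] and o[0] < it[1] for o in c)
        ]
        merged = [it]
        for c in hits:
            merged.extend(c)
            clusters.remove(c)
        clusters.append(merged)
    out = set()
    for c in clusters:
        best = min(c, key=lambda m_: (-m_[2], m_[0], m_[1], m_[3].entity_type))
        a = best[3]
        out.add((a.entity_type, a.token_start, a.token_end))
    return out


def brute_force_same(models) -> set[tuple[int, int]]:
    overlap = False
    for i, m1 in enumerate(models):
        for m2 in models[i + 1 :]:
            for a in m1.annotations:
                for b in m2.annotations:
                    s1, e1 = m1.sentence.char_span(a)
                    s2, e2 = m2.sentence.char_span(b)
                    if s1 < e2 and s2 < e1:
                        overlap = True
    if overlap:
        best = min(
            models,
            key=lambda m: (
                -m.sentence_confidence,
                sorted((m.sentence.char_span(a), a.entity_type) for a in m.annotations),
            ),
        )
        return {(a.token_start, a.token_end) for a in best.annotations}
    return {
        (a.token_start, a.token_end) for m in models for a in m.annotations
    }


class TestOracleEquivalence:
    def test_exhaustive_small_ensembles(self, sent):
        """Both combiners match brute force on all inputs up to 4 models x 6 spans."""
        rng = np.random.default_rng(123)
        for trial in range(300):
            n_models = int(rng.integers(1, 5))
            models = []
            total = 0
            for _ in range(n_models):
                anns = []
                used = set()
                while total < 6 and rng.random() < 0.6:
                    s = int(rng.integers(0, 7))
                    e = min(7, s + int(rng.integers(0, 2)))
                    if any(x in used for x in range(s, e + 1)):
                        break
                    used.update(range(s, e + 1))
                    anns.append(
                        (s, e, str(rng.choice(["protein", "DNA"])),
                         round(float(rng.uniform(0.1, 1.0)), 2))
                    )
                    total += 1
                models.append(tagged(sent, anns, round(float(rng.uniform(0.1, 1.0)), 2)))
            multi = {
                (a.entity_type, a.token_start, a.token_end)
                for a in combine_multi_class(models)
            }
            assert multi == brute_force_multi(models)
            same = {
                (a.token_start, a.token_end) for a in combine_same_class(models)
            }
            assert same == brute_force_same(models)
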