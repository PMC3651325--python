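"""Confidence-based combination of annotation sets from multiple taggers.

Two regimes are supported:

* **same class** — models predicting one entity class (e.g. several
  order/direction variants of a gene-mention tagger).  If any two models'
  annotation sets overlap anywhere in the sentence, the whole sentence's
  annotations are taken from the single model with the highest
  sentence-level confidence; if no overlap exists the sets are unioned.
* **multi class** — models predicting different classes.  The choice is made
  per annotation: annotations are grouped into overlap clusters (transitive
  closure of character-span overlap) and within each cluster the annotation
  with the highest per-annotation confidence wins; an annotation no other
  model competes with is accepted as is.

Overlap is defined on character spans, not token indices, so models that
disagree on tokenization-sensitive boundaries still compete.  Ties are broken
deterministically (earlier span start, then lexicographically smaller entity
type), which makes both combiners invariant to the order models are given in.
"""

from __future__ import annotations

from typing import Sequence

from .corpus import Annotation, Sentence
from .engine import TaggedSentence

__all__ = ["combine_same_class", "combine_multi_class"]


def _char_spans(tagged: TaggedSentence) -> list[tuple[int, int, Annotation]]:
    sent = tagged.sentence
    return [(*sent.char_span(a), a) for a in tagged.annotations]


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _check_same_sentence(tagged: Sequence[TaggedSentence]) -> None:
    ids = {t.sentence.id for t in tagged}
    if len(ids) > 1:
        raise ValueError(f"tagged sentences from different sentences: {sorted(ids)}")


def combine_same_class(tagged: Sequence[TaggedSentence]) -> list[Annotation]:
    """Combine same-class model outputs for one sentence.

    Any overlap anywhere hands the whole sentence to the most confident
    model; otherwise the union of all predictions is returned.
    """
    if not tagged:
        raise ValueError("empty model list")
    _check_same_sentence(tagged)
    if len(tagged) == 1:
        return list(tagged[0].annotations)

    spans_per_model = [_char_spans(t) for t in tagged]
    overlap = any(
        _overlaps((s1, e1), (s2, e2))
        for i in range(len(tagged))
        for j in range(i + 1, len(tagged))
        for s1, e1, _ in spans_per_model[i]
        for s2, e2, _ in spans_per_model[j]
    )
    if overlap:
        # whole-sentence winner; tie-break keeps permutation invariance
        def key(t: TaggedSentence):
            sorted_spans = sorted(
                (t.sentence.char_span(a), a.entity_type) for a in t.annotations
            )
            return (-t.sentence_confidence, sorted_spans)

        winner = min(tagged, key=key)
        return list(winner.annotations)
    # disjoint everywhere: union, deduplicating identical (span, type)
    seen: set[tuple[int, int, str]] = set()
    out: list[Annotation] = []
    for spans in spans_per_model:
        for s, e, ann in spans:
            key_ = (s, e, ann.entity_type)
            if key_ not in seen:
                seen.add(key_)
                out.append(ann)
    return sorted(out)


def combine_multi_class(tagged: Sequence[TaggedSentence]) -> list[Annotation]:
    """Combine multi-class model outputs for one sentence, per annotation.

    Requires every annotation to carry a per-annotation confidence.
    """
    if not tagged:
        raise ValueError("empty model list")
    _check_same_sentence(tagged)
    items: list[tuple[int, int, float, Annotation]] = []
    for t in tagged:
        for ann in t.annotations:
            conf = t.per_annotation_confidence.get(ann, ann.confidence)
            if conf is None:
                raise ValueError(f"annotation {ann} has no confidence")
            s, e = t.sentence.char_span(ann)
            items.append((s, e, float(conf), ann))

    # overlap clusters: transitive closure over character-span overlap
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if _overlaps(items[i][:2], items[j][:2]):
                parent[find(i)] = find(j)

    clusters: dict[int, list[tuple[int, int, float, Annotation]]] = {}
    for i, item in enumerate(items):
        clusters.setdefault(find(i), []).append(item)

    out: list[Annotation] = []
    for members in clusters.values():
        # highest confidence wins; ties: earlier start, then earlier end,
        # then lexicographically smaller type
        best = min(members, key=lambda m: (-m[2], m[0], m[1], m[3].entity_type))
        out.append(best[3])
    return sorted(out)
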