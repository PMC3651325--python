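"""Exact-match entity evaluation: precision, recall and F-measure.

A prediction is a true positive only when its sentence, character span and
entity type all equal a gold annotation's (exact boundary matching).  The
matching key uses whitespace-normalized character spans — the span counted
over non-whitespace characters — so differently tokenized predictions
compare fairly.  Metrics follow

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2PR / (P + R),

with zero denominators yielding 0 by convention.  For multi-class corpora
both per-class scores and the micro-averaged overall score (pooled TP/FP/FN)
are reported.

An *alternative-annotation* mode gives credit when a prediction matches any
of the alternative spans human annotators accepted for a gold annotation;
each gold annotation is creditable at most once and each prediction counts
at most once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .corpus import Annotation, Corpus, Sentence, nonws_span

__all__ = [
    "MatchCounts",
    "prf",
    "exact_match_prf",
    "alternative_match_prf",
    "evaluation_report",
    "write_report",
]

SpanKey = tuple[str, int, int, str]  # sentence id, nonws start, nonws end, type


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1 from raw counts."""
    c = MatchCounts(tp, fp, fn)
    return c.precision, c.recall, c.f1


def _keys(corpus: Corpus) -> list[SpanKey]:
    out = []
    for sent in corpus:
        for ann in sent.annotations:
            cs, ce = sent.char_span(ann)
            s, e = nonws_span(sent.text, cs, ce)
            out.append((sent.id, s, e, ann.entity_type))
    return out


def _check_ids(gold: Corpus, pred: Corpus) -> None:
    gids = {s.id for s in gold}
    pids = {s.id for s in pred}
    if gids != pids:
        raise ValueError(
            f"gold and prediction sentence ids differ: "
            f"only-gold={sorted(gids - pids)[:5]} only-pred={sorted(pids - gids)[:5]}"
        )


def exact_match_prf(gold: Corpus, pred: Corpus) -> MatchCounts:
    """Exact-boundary, exact-type matching over two corpora."""
    _check_ids(gold, pred)
    gold_keys = _keys(gold)
    pred_keys = _keys(pred)
    gold_multiset: dict[SpanKey, int] = {}
    for k in gold_keys:
        gold_multiset[k] = gold_multiset.get(k, 0) + 1
    tp = 0
    for k in pred_keys:
        if gold_multiset.get(k, 0) > 0:
            gold_multiset[k] -= 1
            tp += 1
    return MatchCounts(tp=tp, fp=len(pred_keys) - tp, fn=len(gold_keys) - tp)


def alternative_match_prf(
    gold: Corpus,
    alternatives: Mapping[SpanKey, Sequence[SpanKey]],
    pred: Corpus,
) -> MatchCounts:
    """Exact matching with alternative-annotation credit.

    ``alternatives`` maps a gold annotation's span key to the extra span keys
    accepted for it.  A prediction matching the gold key or any alternative
    counts as the TP of that gold annotation; every gold annotation is
    credited at most once and every prediction consumed at most once.
    """
    _check_ids(gold, pred)
    gold_keys = _keys(gold)
    acceptable: list[set[SpanKey]] = [
        {k, *alternatives.get(k, ())} for k in gold_keys
    ]
    credited = [False] * len(gold_keys)
    tp = 0
    fp = 0
    for pk in sorted(_keys(pred)):
        hit = None
        for gi, acc in enumerate(acceptable):
            if not credited[gi] and pk in acc:
                hit = gi
                break
        if hit is None:
            fp += 1
        else:
            credited[hit] = True
            tp += 1
    return MatchCounts(tp=tp, fp=fp, fn=credited.count(False))


def read_alternatives(
    path: str | Path, gold: Corpus, entity_type: str = "PRGE"
) -> dict[SpanKey, list[SpanKey]]:
    """Read an offset-dialect file of alternative spans.

    Each line ``id|s e|text`` adds an acceptable span for every gold
    annotation of the same sentence it overlaps (non-whitespace offsets,
    inclusive end — the offset dialect's convention).
    """
    sents = {s.id: s for s in gold}
    gold_by_sent: dict[str, list[SpanKey]] = {}
    for k in _keys(gold):
        gold_by_sent.setdefault(k[0], []).append(k)
    out: dict[SpanKey, list[SpanKey]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        sid, span, _text = line.split("|", 2)
        s_str, e_str = span.split()
        s, e = int(s_str), int(e_str)
        if sid not in sents:
            raise ValueError(f"alternative for unknown sentence {sid}")
        alt_key = (sid, s, e, entity_type)
        for gk in gold_by_sent.get(sid, []):
            if gk[1] <= e and s <= gk[2]:  # overlaps the gold span
                out.setdefault(gk, []).append(alt_key)
    return out


def evaluation_report(gold: Corpus, pred: Corpus) -> pd.DataFrame:
    """Per-class and micro-averaged overall scores as a tidy table."""
    _check_ids(gold, pred)
    classes = sorted(
        {k[3] for k in _keys(gold)} | {k[3] for k in _keys(pred)}
    )
    rows = []
    total = MatchCounts(0, 0, 0)
    for cls in classes:
        g = _restrict(gold, cls)
        p = _restrict(pred, cls)
        counts = exact_match_prf(g, p)
        total = total + counts
        rows.append(_row(cls, counts))
    rows.append(_row("overall", total))
    return pd.DataFrame(
        rows, columns=["class", "TP", "FP", "FN", "precision", "recall", "f1"]
    )


def _restrict(corpus: Corpus, entity_type: str) -> Corpus:
    sents = []
    for s in corpus:
        sents.append(
            Sentence(
                id=s.id,
                text=s.text,
                tokens=s.tokens,
                annotations=[
                    a for a in s.annotations if a.entity_type == entity_type
                ],
                dependencies=s.dependencies,
                doc_id=s.doc_id,
            )
        )
    return Corpus(sents)


def _row(cls: str, c: MatchCounts) -> dict:
    return {
        "class": cls, "TP": c.tp, "FP": c.fp, "FN": c.fn,
        "precision": c.precision, "recall": c.recall, "f1": c.f1,
    }


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.4f")
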