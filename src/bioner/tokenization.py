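"""Sentence tokenization with exact offset tracking.

Biomedical gene and protein names are frequently glued to qualifiers with
``/``, ``-`` or ``.`` ("BRCA-1/2", "p53.1").  If such a compound stays one
token, a gold annotation covering only part of it ("BRCA-1") cannot be
expressed at the token level and the whole compound is learned as a negative
example.  The tokenizer here therefore always breaks words containing ``/``,
``-`` or ``.`` into multiple tokens, each separator becoming a standalone
token so that every sub-span ("BRCA-1" as well as "1/2") remains expressible
as a token range.

The split is applied uniformly — also inside decimals ("2.5" → "2", ".",
"5") — since annotations re-align by character offsets regardless and a
uniform rule keeps behaviour predictable.

A pluggable *base segmenter* hook (``text -> [(start, end), ...]``) lets an
external biomedical tokenizer supply the coarse segmentation; the refinement
pass is applied on top of whatever it returns.
"""

from __future__ import annotations

import re
from typing import Callable, Sequence

from .corpus import Annotation, Sentence, Token

__all__ = ["tokenize", "retokenize", "whitespace_segmenter"]

# word characters except underscore (unicode-aware); anything else is a symbol
_WORD_RUN = re.compile(r"[^\W_]+|\S", re.UNICODE)

BaseSegmenter = Callable[[str], list[tuple[int, int]]]


def whitespace_segmenter(text: str) -> list[tuple[int, int]]:
    """Default base segmentation: maximal runs of non-whitespace."""
    return [(m.start(), m.end()) for m in re.finditer(r"\S+", text)]


def _refine(text: str, start: int, end: int) -> list[tuple[int, int]]:
    """Split a base segment into word runs and standalone symbol tokens."""
    return [
        (start + m.start(), start + m.end())
        for m in _WORD_RUN.finditer(text[start:end])
    ]


def tokenize(text: str, base_segmenter: BaseSegmenter | None = None) -> list[Token]:
    """Tokenize a sentence into offset-faithful tokens.

    Base segmentation (whitespace by default, or the supplied hook) is refined
    so that every punctuation character — in particular ``/``, ``-`` and
    ``.`` — becomes its own token.
    """
    if not text.strip():
        raise ValueError("cannot tokenize empty or whitespace-only text")
    segmenter = base_segmenter or whitespace_segmenter
    tokens: list[Token] = []
    for s, e in segmenter(text):
        for rs, re_ in _refine(text, s, e):
            tokens.append(Token(text[rs:re_], rs, re_))
    return tokens


def retokenize(
    sentence: Sentence,
    char_annotations: Sequence[tuple[int, int, str]] | None = None,
) -> Sentence:
    """Apply the separator-splitting rule to an already-tokenized sentence.

    Existing token boundaries are preserved; each token is refined in place,
    so a token ``BRCA-1/2`` becomes ``BRCA``, ``-``, ``1``, ``/``, ``2``.
    The sentence's annotations are remapped onto the refined token ranges by
    character offset.  ``char_annotations`` may supply additional gold spans
    given directly as half-open character spans ``(start, end, entity_type)``
    — e.g. a span that was inside a single coarse token and only becomes
    representable after refinement.

    Raises ``ValueError`` for an annotation whose character span still
    crosses a token boundary after refinement.  Idempotent.
    """
    new_tokens: list[Token] = []
    old_to_new: list[int] = []  # old token index -> index of its first piece
    for tok in sentence.tokens:
        old_to_new.append(len(new_tokens))
        for rs, re_ in _refine(sentence.text, tok.start, tok.end):
            # linguistic attributes carry over only when the token is unsplit
            if (rs, re_) == (tok.start, tok.end):
                new_tokens.append(tok)
            else:
                new_tokens.append(Token(sentence.text[rs:re_], rs, re_))

    spans: list[tuple[int, int, str]] = [
        (*sentence.char_span(a), a.entity_type) for a in sentence.annotations
    ]
    spans.extend(char_annotations or [])

    new_sent = Sentence(
        id=sentence.id,
        text=sentence.text,
        tokens=new_tokens,
        # arcs follow the first piece of a split token
        dependencies=[
            (old_to_new[h], old_to_new[d], rel) for h, d, rel in sentence.dependencies
        ],
        doc_id=sentence.doc_id,
    )
    starts = {t.start: i for i, t in enumerate(new_tokens)}
    ends = {t.end: i for i, t in enumerate(new_tokens)}
    for cs, ce, etype in spans:
        if cs not in starts or ce not in ends or ends[ce] < starts[cs]:
            raise ValueError(
                f"sentence {sentence.id}: annotation span [{cs},{ce}) does not "
                f"align to token boundaries after retokenization"
            )
        new_sent.annotations.append(
            Annotation(etype, starts[cs], ends[ce], sentence_id=sentence.id)
        )
    return new_sent
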