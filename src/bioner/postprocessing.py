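"""Rule-based correction of tagger output.

Two corrections are applied after CRF decoding:

* **bracket parity** — an annotation whose covered text contains an odd
  total of round, square or curly brackets (counted per bracket type, so
  ``(]`` cannot slip through) is a clear model mistake and is removed;
* **abbreviation resolution** — parenthesized short forms are paired with a
  preceding long form by character-subsequence alignment, and annotations are
  propagated between the two forms: if one form is annotated the other gains
  an annotation of the same type, and a partially covered form has its
  annotation extended to the full form.

A long-form candidate must satisfy three constraints: (a) the first character
of the short form equals the first character of the long form's first word;
(b) the long form is longer than the short form; (c) the long form does not
contain the short form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .corpus import Annotation, Sentence

__all__ = [
    "AbbreviationPair",
    "filter_unbalanced",
    "adjust_unbalanced",
    "find_abbreviations",
    "propagate_abbreviations",
    "postprocess",
]

_BRACKET_TYPES = (("(", ")"), ("[", "]"), ("{", "}"))


@dataclass(frozen=True)
class AbbreviationPair:
    """A short form inside parentheses paired with its preceding long form.

    Spans are inclusive token ranges, disjoint by construction.
    """

    short_form: tuple[int, int]
    long_form: tuple[int, int]
    sentence_id: str | None = None


def filter_unbalanced(
    annotations: Sequence[Annotation], sentence: Sentence
) -> list[Annotation]:
    """Drop annotations whose covered text has an odd bracket count.

    Parity is checked separately for each bracket type (round, square,
    curly); never adds annotations.
    """
    kept = []
    for ann in annotations:
        text = sentence.annotation_text(ann)
        if all(
            (text.count(op) + text.count(cl)) % 2 == 0
            for op, cl in _BRACKET_TYPES
        ):
            kept.append(ann)
    return kept


def _balanced(text: str) -> bool:
    return all(
        (text.count(op) + text.count(cl)) % 2 == 0 for op, cl in _BRACKET_TYPES
    )


def adjust_unbalanced(
    annotations: Sequence[Annotation], sentence: Sentence
) -> list[Annotation]:
    """Alternative parity handling: move boundaries to the nearest bracket.

    Instead of removing a bracket-unbalanced annotation, its boundary is
    shifted token by token — extending to the following or preceding bracket,
    or shrinking away from one — until every bracket type balances; if no
    adjustment within the sentence balances, the annotation is removed.  Kept
    off by default: removal gives better results, this variant exists to
    reproduce the ablation.
    """
    n = len(sentence.tokens)
    out = []
    for ann in annotations:
        if _balanced(sentence.annotation_text(ann)):
            out.append(ann)
            continue
        fixed = None
        candidates = (
            [replace(ann, token_end=e) for e in range(ann.token_end + 1, n)]
            + [replace(ann, token_start=s) for s in range(ann.token_start - 1, -1, -1)]
            + [
                replace(ann, token_end=e)
                for e in range(ann.token_end - 1, ann.token_start - 1, -1)
            ]
            + [
                replace(ann, token_start=s)
                for s in range(ann.token_start + 1, ann.token_end + 1)
            ]
        )
        for cand in candidates:
            if _balanced(sentence.annotation_text(cand)):
                fixed = cand
                break
        if fixed is not None:
            out.append(fixed)
    return out


def _is_short_form_candidate(text: str, min_len: int, max_len: int) -> bool:
    return (
        min_len <= len(text) <= max_len
        and any(c.isalpha() for c in text)
        and text[0].isalnum()
    )


def _aligns(short: str, long: str) -> bool:
    """Greedy in-order character-subsequence alignment of short into long.

    The first character must anchor at the start of the long form; remaining
    characters (case-insensitive, alphanumeric only) are matched rightward.
    """
    sf = [c.lower() for c in short if c.isalnum()]
    lf = long.lower()
    if not sf or not lf or sf[0] != lf[0]:
        return False
    pos = 1
    for c in sf[1:]:
        nxt = lf.find(c, pos)
        if nxt < 0:
            return False
        pos = nxt + 1
    return True


def find_abbreviations(
    sentence: Sentence,
    min_short_len: int = 2,
    max_short_len: int = 10,
    max_short_tokens: int = 2,
) -> list[AbbreviationPair]:
    """Detect short/long abbreviation pairs in one tokenized sentence.

    A candidate short form is the token span inside a ``( … )`` pair; the
    long form is searched among the tokens immediately before the opening
    parenthesis, within a window of at most ``min(|SF| + 5, 2·|SF|)`` tokens
    (character length of the short form), preferring the shortest long form
    whose first word anchors the alignment and which satisfies constraints
    (a)–(c) above.
    """
    tokens = [t.text for t in sentence.tokens]
    pairs: list[AbbreviationPair] = []
    for i, tok in enumerate(tokens):
        if tok != "(":
            continue
        try:
            j = tokens.index(")", i + 1)
        except ValueError:
            continue
        sf_span = (i + 1, j - 1)
        if sf_span[1] < sf_span[0] or sf_span[1] - sf_span[0] + 1 > max_short_tokens:
            continue
        short = " ".join(tokens[sf_span[0] : sf_span[1] + 1])
        if not _is_short_form_candidate(short, min_short_len, max_short_len):
            continue
        window = min(len(short) + 5, 2 * len(short))
        found = None
        for s in range(i - 1, max(i - 1 - window, -1), -1):
            long = " ".join(tokens[s:i])
            if not tokens[s][0].isalnum():
                continue
            if short[0].lower() != tokens[s][0].lower():
                continue  # constraint (a)
            if not _aligns(short, long):
                continue
            if len(long) <= len(short):
                continue  # constraint (b)
            if short in tokens[s:i]:
                continue  # constraint (c)
            found = (s, i - 1)
            break  # shortest anchored long form wins
        if found is not None:
            pairs.append(AbbreviationPair(sf_span, found, sentence.id))
    return pairs


def _span_chars(sentence: Sentence, span: tuple[int, int]) -> tuple[int, int]:
    return sentence.tokens[span[0]].start, sentence.tokens[span[1]].end


def propagate_abbreviations(
    annotations: Sequence[Annotation],
    pairs: Sequence[AbbreviationPair],
    sentence: Sentence,
) -> list[Annotation]:
    """Propagate annotations between abbreviation forms; never removes any.

    For each pair: if exactly one form overlaps an annotation, the other form
    gains an annotation of the same type covering it in full; a form only
    partially covered has its annotation extended to the whole form.  When
    the two forms carry conflicting types, the pair is left unchanged with a
    warning.  Idempotent.
    """
    anns = list(annotations)
    for pair in pairs:
        spans = {"short": pair.short_form, "long": pair.long_form}
        hits: dict[str, list[int]] = {"short": [], "long": []}
        for which, span in spans.items():
            cs, ce = _span_chars(sentence, span)
            for k, ann in enumerate(anns):
                a_cs, a_ce = sentence.char_span(ann)
                if a_cs < ce and cs < a_ce:
                    hits[which].append(k)
        types = {
            which: {anns[k].entity_type for k in ks}
            for which, ks in hits.items()
            if ks
        }
        if len(types) == 2:
            if types["short"] != types["long"]:
                warnings.warn(
                    f"sentence {sentence.id}: conflicting types across "
                    f"abbreviation forms {types}; leaving unchanged"
                )
                continue
        # extend partial coverage to the full form
        for which, span in spans.items():
            for k in hits[which]:
                ann = anns[k]
                new_start = min(ann.token_start, span[0])
                new_end = max(ann.token_end, span[1])
                if (new_start, new_end) != (ann.token_start, ann.token_end):
                    anns[k] = replace(
                        ann, token_start=new_start, token_end=new_end
                    )
        # propagate to the untagged form
        if hits["short"] and not hits["long"]:
            etype = anns[hits["short"][0]].entity_type
            anns.append(
                Annotation(etype, *pair.long_form, sentence_id=sentence.id)
            )
        elif hits["long"] and not hits["short"]:
            etype = anns[hits["long"][0]].entity_type
            anns.append(
                Annotation(etype, *pair.short_form, sentence_id=sentence.id)
            )
    return anns


def postprocess(
    annotations: Sequence[Annotation],
    sentence: Sentence,
    parity_filter: bool = True,
    abbreviations: bool = True,
    adjust_brackets: bool = False,
) -> list[Annotation]:
    """Apply the default post-processing pipeline to one sentence's output."""
    anns = list(annotations)
    if parity_filter:
        anns = (
            adjust_unbalanced(anns, sentence)
            if adjust_brackets
            else filter_unbalanced(anns, sentence)
        )
    if abbreviations:
        pairs = find_abbreviations(sentence)
        anns = propagate_abbreviations(anns, pairs, sentence)
    return anns
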