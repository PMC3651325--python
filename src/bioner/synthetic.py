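"""Deterministic generator of annotated synthetic corpora.

The generator plants exactly the regularities the feature extractors target,
so every pipeline stage is testable at desk scale without external corpora:

* entity names composed as ``<CapitalizedStem><suffix>`` with an optional
  hyphen-digit qualifier ("Brakunase-2") — capitalisation, characteristic
  suffixes ("ase", "ome", "gen", …) and word shapes carry the signal, while
  the random stems make held-out names unseen at the token level;
* trigger words placed adjacent to entities (before or after with equal
  probability, keeping the corpus left-right symmetric) with a stated rate;
* abbreviation patterns ``long form ( SF )`` whose short form is the
  initials of the long form, satisfying the abbreviation recognizer's
  constraints by construction;
* occasional unbalanced-bracket noise tokens.

Sentences carry synthetic lemma / part-of-speech / chunk attributes so the
linguistic and conjunction features operate.  Everything is reproducible
from the seed.  ``corrupt_annotations`` derives a "prediction" with known
true/false positive and negative counts for evaluation tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Annotation, Corpus, Sentence, Token
from .tokenization import tokenize

__all__ = [
    "SyntheticParams",
    "generate_corpus",
    "generate_corpus_with_manifest",
    "corrupt_annotations",
    "write_manifest",
]

_FUNCTION_WORDS = ["the", "of", "in", "with", "by", "for", "a", "an"]
_VERBS = ["binds", "activates", "inhibits", "regulates", "induces", "suppresses"]
_NOUNS = [
    "cells", "levels", "analysis", "study", "results", "effects",
    "samples", "patients", "tissue", "response",
]
_TRIGGERS = ["activation", "stimulation", "expression", "phosphorylation",
             "transcription", "inhibition"]
_LONGFORM_WORDS = [
    "tumor", "necrosis", "factor", "growth", "binding", "protein",
    "nuclear", "receptor", "kinase", "interferon", "colony", "antigen",
]
_CONSONANTS = list("bcdfgklmnprstvz")
_VOWELS = list("aeiou")


@dataclass(frozen=True)
class SyntheticParams:
    """Generation rates and vocabularies (all rates are probabilities)."""

    entity_rate: float = 0.2          # per content slot
    trigger_rate: float = 0.5         # trigger adjacent to an entity
    abbreviation_rate: float = 0.15   # per sentence
    bracket_noise_rate: float = 0.05  # stray unbalanced bracket per sentence
    hyphen_digit_rate: float = 0.4    # entity carries a "-<digit>" qualifier
    suffixes: tuple[str, ...] = ("ase", "ome", "gen", "in", "ein", "or")
    min_slots: int = 6
    max_slots: int = 12

    def __post_init__(self) -> None:
        for name in ("entity_rate", "trigger_rate", "abbreviation_rate",
                     "bracket_noise_rate", "hyphen_digit_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.min_slots < 1 or self.max_slots < self.min_slots:
            raise ValueError("invalid slot range")


def _stem(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(2, 4))
    s = "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syll)
    )
    return s.capitalize()


def _type_suffixes(
    entity_types: Sequence[str], suffixes: Sequence[str]
) -> dict[str, list[str]]:
    """Partition the suffix vocabulary across entity types (round-robin)."""
    if len(suffixes) < len(entity_types):
        raise ValueError("need at least one suffix per entity type")
    return {
        t: [s for j, s in enumerate(suffixes) if j % len(entity_types) == i]
        for i, t in enumerate(entity_types)
    }


def _entity_name(
    rng: np.random.Generator, suffixes: Sequence[str], hyphen_digit_rate: float
) -> str:
    name = _stem(rng) + str(rng.choice(suffixes))
    if rng.random() < hyphen_digit_rate:
        name += f"-{int(rng.integers(1, 10))}"
    return name


def _abbreviation(rng: np.random.Generator) -> tuple[list[str], str]:
    n_words = int(rng.integers(2, 4))
    words = list(rng.choice(_LONGFORM_WORDS, size=n_words, replace=False))
    short = "".join(w[0] for w in words).upper()
    return words, short


def _word_attrs(word: str, role: str) -> tuple[str, str, str]:
    """Synthetic (lemma, POS, chunk) for one generated word."""
    if role == "function":
        pos = "DT" if word in ("the", "a", "an") else "IN"
        return word, pos, "B-PP"
    if role == "verb":
        lemma = word[:-1] if word.endswith("s") else word
        return lemma, "VBZ", "B-VP"
    if role in ("entity", "longform", "shortform"):
        return word.lower(), "NN", "B-NP"
    if role == "trigger":
        return word.lower(), "NN", "B-NP"
    if role == "bracket":
        return word, "-LRB-" if word in "([{" else "-RRB-", "O"
    return word.lower(), "NNS" if word.endswith("s") else "NN", "B-NP"


def generate_corpus_with_manifest(
    n_sentences: int,
    entity_types: Sequence[str] = ("PRGE",),
    seed: int = 0,
    params: SyntheticParams | None = None,
) -> tuple[Corpus, dict]:
    """Generate a corpus and a manifest of the planted ground truth."""
    if n_sentences < 1:
        raise ValueError("n_sentences must be >= 1")
    p = params or SyntheticParams()
    rng = np.random.default_rng(seed)
    suffix_map = _type_suffixes(entity_types, p.suffixes)

    sentences: list[Sentence] = []
    manifest: dict = {
        "seed": seed,
        "n_sentences": n_sentences,
        "entity_types": list(entity_types),
        "entities": [],
        "abbreviation_pairs": [],
    }
    for si in range(n_sentences):
        sid = f"s{si}"
        # words with (word, role, entity_group) bookkeeping
        words: list[tuple[str, str, int]] = []  # (text, role, entity id or -1)
        entity_info: dict[int, str] = {}  # entity id -> type
        eid = 0

        n_slots = int(rng.integers(p.min_slots, p.max_slots + 1))
        for _ in range(n_slots):
            r = rng.random()
            if r < p.entity_rate:
                etype = str(rng.choice(list(entity_types)))
                name = _entity_name(rng, suffix_map[etype], p.hyphen_digit_rate)
                trigger_before = rng.random() < 0.5
                has_trigger = rng.random() < p.trigger_rate
                if has_trigger and trigger_before:
                    words.append((str(rng.choice(_TRIGGERS)), "trigger", -1))
                words.append((name, "entity", eid))
                if has_trigger and not trigger_before:
                    words.append((str(rng.choice(_TRIGGERS)), "trigger", -1))
                entity_info[eid] = etype
                eid += 1
            elif r < p.entity_rate + 0.25:
                words.append((str(rng.choice(_VERBS)), "verb", -1))
            elif r < p.entity_rate + 0.5:
                words.append((str(rng.choice(_FUNCTION_WORDS)), "function", -1))
            elif rng.random() < 0.5:
                words.append((str(rng.choice(_NOUNS)), "noun", -1))
            else:
                # open-vocabulary filler: random lowercase stem, emulating the
                # long tail of ordinary words (no entity suffix, no capital)
                words.append((_stem(rng).lower(), "noun", -1))

        abbrev_span_words: tuple[int, int, int, str] | None = None
        if rng.random() < p.abbreviation_rate:
            lf_words, short = _abbreviation(rng)
            etype = str(rng.choice(list(entity_types)))
            insert_at = len(words)
            lf_start = insert_at
            for w in lf_words:
                words.append((w, "longform", eid))
            words.append(("(", "bracket", -1))
            sf_at = len(words)
            words.append((short, "shortform", eid + 1))
            words.append((")", "bracket", -1))
            entity_info[eid] = etype
            entity_info[eid + 1] = etype
            abbrev_span_words = (lf_start, sf_at, eid, short)
            eid += 2

        if rng.random() < p.bracket_noise_rate:
            # insert outside the abbreviation block so the planted pattern
            # stays contiguous; entity groups are single words, unaffected
            allowed = list(range(len(words) + 1))
            if abbrev_span_words is not None:
                lf_start, sf_at = abbrev_span_words[0], abbrev_span_words[1]
                allowed = [
                    q for q in allowed if q <= lf_start or q >= sf_at + 2
                ]
            pos = int(rng.choice(allowed))
            words.insert(pos, (str(rng.choice(["(", ")"])), "bracket", -1))

        words.append((".", "period", -1))

        # assemble text and char spans per word
        text_parts: list[str] = []
        offsets: list[tuple[int, int]] = []
        pos_c = 0
        for w, _, _ in words:
            if text_parts:
                pos_c += 1
            text_parts.append(w)
            offsets.append((pos_c, pos_c + len(w)))
            pos_c += len(w)
        text = " ".join(text_parts)

        tokens = tokenize(text)
        # word index for each token (tokens never straddle word boundaries)
        tok_word = []
        for t in tokens:
            wi = next(
                k for k, (s, e) in enumerate(offsets) if s <= t.start and t.end <= e
            )
            tok_word.append(wi)
        # attach synthetic linguistic attributes
        attrs = [_word_attrs(w, role) for w, role, _ in words]
        rich_tokens: list[Token] = []
        prev_word = -1
        for t, wi in zip(tokens, tok_word):
            lemma, pos_tag, chunk = attrs[wi]
            if t.text != words[wi][0]:  # a split piece of a compound word
                lemma = t.text.lower()
                pos_tag = "CD" if t.text.isdigit() else "HYPH" if t.text == "-" else pos_tag
            if wi == prev_word and chunk.startswith("B-"):
                chunk = "I-" + chunk[2:]
            rich_tokens.append(
                Token(t.text, t.start, t.end, lemma=lemma, pos=pos_tag, chunk=chunk)
            )
            prev_word = wi

        sent = Sentence(id=sid, text=text, tokens=rich_tokens)

        # gold annotations from entity groups
        group_tokens: dict[int, list[int]] = {}
        for ti, wi in enumerate(tok_word):
            g = words[wi][2]
            if g >= 0:
                group_tokens.setdefault(g, []).append(ti)
        for g in sorted(group_tokens):
            toks = group_tokens[g]
            ann = Annotation(
                entity_info[g], toks[0], toks[-1], sentence_id=sid
            )
            sent.annotations.append(ann)
            manifest["entities"].append(
                {"sentence": sid, "type": entity_info[g],
                 "token_start": toks[0], "token_end": toks[-1],
                 "text": sent.annotation_text(ann)}
            )
        if abbrev_span_words is not None:
            lf_g, sf_g = abbrev_span_words[2], abbrev_span_words[2] + 1
            manifest["abbreviation_pairs"].append(
                {
                    "sentence": sid,
                    "short_form": [group_tokens[sf_g][0], group_tokens[sf_g][-1]],
                    "long_form": [group_tokens[lf_g][0], group_tokens[lf_g][-1]],
                    "short_text": abbrev_span_words[3],
                }
            )
        sentences.append(sent)

    return Corpus(sentences), manifest


def generate_corpus(
    n_sentences: int,
    entity_types: Sequence[str] = ("PRGE",),
    seed: int = 0,
    params: SyntheticParams | None = None,
) -> Corpus:
    """Generate a synthetic annotated corpus (see module docstring)."""
    corpus, _ = generate_corpus_with_manifest(n_sentences, entity_types, seed, params)
    return corpus


# ---------------------------------------------------------------------------
# Controlled corruption for evaluation tests
# ---------------------------------------------------------------------------

_CORRUPTION_OPS = ("drop", "boundary_shift", "type_flip", "bracket_cut")


def corrupt_annotations(
    corpus: Corpus,
    seed: int = 0,
    ops: dict[str, float] | None = None,
) -> tuple[Corpus, dict]:
    """Derive a "prediction" corpus with known error counts.

    ``ops`` maps operation name to a rate in [0,1]; operations are tried in
    the order drop, boundary_shift, type_flip, bracket_cut, at most one per
    annotation.  Returns the prediction corpus and a bookkeeping dict with
    the exact expected TP/FP/FN counts under exact matching.
    """
    ops = dict(ops or {})
    unknown = set(ops) - set(_CORRUPTION_OPS)
    if unknown:
        raise ValueError(f"unknown corruption ops: {sorted(unknown)}")
    for name, rate in ops.items():
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"rate {name}={rate} outside [0,1]")
    rng = np.random.default_rng(seed)
    book = {"tp": 0, "fp": 0, "fn": 0,
            "per_op": {name: 0 for name in _CORRUPTION_OPS}}
    pred_sentences = []
    for sent in corpus:
        pred_anns: list[Annotation] = []
        for ann in sent.annotations:
            op = None
            for name in _CORRUPTION_OPS:
                if name in ops and rng.random() < ops[name]:
                    op = name
                    break
            if op == "drop":
                book["fn"] += 1
                book["per_op"]["drop"] += 1
                continue
            if op == "boundary_shift":
                if ann.token_end + 1 < len(sent.tokens):
                    new = replace(ann, token_end=ann.token_end + 1)
                elif ann.token_start > 0:
                    new = replace(ann, token_start=ann.token_start - 1)
                else:
                    new = None
                if new is not None:
                    pred_anns.append(new)
                    book["fp"] += 1
                    book["fn"] += 1
                    book["per_op"]["boundary_shift"] += 1
                    continue
            elif op == "type_flip":
                new_type = ann.entity_type + "_X"
                pred_anns.append(replace(ann, entity_type=new_type))
                book["fp"] += 1
                book["fn"] += 1
                book["per_op"]["type_flip"] += 1
                continue
            elif op == "bracket_cut":
                texts = [t.text for t in sent.tokens]
                new = None
                if ann.token_start > 0 and texts[ann.token_start - 1] in "([{":
                    new = replace(ann, token_start=ann.token_start - 1)
                elif ann.token_end + 1 < len(texts) and texts[ann.token_end + 1] in ")]}":
                    new = replace(ann, token_end=ann.token_end + 1)
                if new is not None:
                    pred_anns.append(new)
                    book["fp"] += 1
                    book["fn"] += 1
                    book["per_op"]["bracket_cut"] += 1
                    continue
            # untouched (or an op that could not apply): exact true positive
            pred_anns.append(ann)
            book["tp"] += 1
        pred_sentences.append(
            Sentence(
                id=sent.id, text=sent.text, tokens=sent.tokens,
                annotations=pred_anns, dependencies=sent.dependencies,
                doc_id=sent.doc_id,
            )
        )
    return Corpus(pred_sentences), book


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2), encoding="utf-8")
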