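"""Domain model for annotated sentences and corpus I/O.

The package works on single sentences carrying a token sequence and a set of
typed entity annotations over token ranges.  Two interchange dialects are
supported:

* the *offset* dialect: one file with ``id<whitespace>text`` sentences and one
  with ``id|s e|entity text`` annotations, where ``s``/``e`` index the
  **non-whitespace** characters of the sentence (inclusive end) — the
  convention used by the BioCreative II gene-mention corpus;
* the *IOB2* dialect: ``token<TAB>tag`` lines, a blank line between sentences
  and optional ``###MEDLINE:<id>`` document separators — the convention used
  by the JNLPBA shared-task corpus.

Internally all character offsets are 0-based half-open over the raw sentence
text; conversion between the two conventions happens only in the readers and
writers so the two can never mix silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "Token",
    "Annotation",
    "Sentence",
    "Corpus",
    "encode_bio",
    "decode_bio",
    "read_offset_corpus",
    "write_offset_corpus",
    "write_offset_annotations",
    "read_iob2_corpus",
    "write_iob2_corpus",
]


@dataclass(frozen=True)
class Token:
    """A text unit with character offsets into its source sentence.

    ``start``/``end`` are 0-based, half-open offsets into the raw sentence
    string.  Linguistic attributes (lemma, part-of-speech tag, BIO chunk tag)
    are optional and normally supplied by an external linguistic processor or
    by the synthetic corpus generator.
    """

    text: str
    start: int
    end: int
    lemma: str | None = None
    pos: str | None = None
    chunk: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"token span [{self.start},{self.end}) is empty")
        if len(self.text) != self.end - self.start:
            raise ValueError(
                f"token text {self.text!r} does not fit span [{self.start},{self.end})"
            )


@dataclass(frozen=True, order=True)
class Annotation:
    """A typed entity span over an inclusive token range.

    ``confidence`` is a posterior probability in (0, 1] attached by a tagger;
    gold annotations leave it ``None``.
    """

    entity_type: str
    token_start: int
    token_end: int  # inclusive
    confidence: float | None = field(default=None, compare=False)
    sentence_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.entity_type:
            raise ValueError("entity_type must be non-empty")
        if self.token_start < 0 or self.token_end < self.token_start:
            raise ValueError(
                f"invalid token range [{self.token_start},{self.token_end}]"
            )
        if self.confidence is not None and not (0.0 < self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside (0,1]")


@dataclass
class Sentence:
    id: str
    text: str
    tokens: list[Token]
    annotations: list[Annotation] = field(default_factory=list)
    #: dependency arcs as (head token index, dependent token index, relation label)
    dependencies: list[tuple[int, int, str]] = field(default_factory=list)
    #: document this sentence belongs to (IOB2 ``###MEDLINE:`` separators)
    doc_id: str | None = None

    def __post_init__(self) -> None:
        prev_end = -1
        for tok in self.tokens:
            if tok.start < prev_end:
                raise ValueError(f"sentence {self.id}: tokens overlap or are unsorted")
            if self.text[tok.start : tok.end] != tok.text:
                raise ValueError(
                    f"sentence {self.id}: token {tok.text!r} does not match "
                    f"text slice {self.text[tok.start:tok.end]!r}"
                )
            prev_end = tok.end
        for ann in self.annotations:
            if ann.token_end >= len(self.tokens):
                raise ValueError(
                    f"sentence {self.id}: annotation {ann} outside token range"
                )

    def __len__(self) -> int:
        return len(self.tokens)

    def char_span(self, ann: Annotation) -> tuple[int, int]:
        """Raw-text character span (half-open) covered by an annotation."""
        return self.tokens[ann.token_start].start, self.tokens[ann.token_end].end

    def annotation_text(self, ann: Annotation) -> str:
        s, e = self.char_span(ann)
        return self.text[s:e]


@dataclass
class Corpus:
    sentences: list[Sentence]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sentences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sentence ids in corpus")

    def __iter__(self) -> Iterator[Sentence]:
        return iter(self.sentences)

    def __len__(self) -> int:
        return len(self.sentences)

    @property
    def label_set(self) -> set[str]:
        return {a.entity_type for s in self.sentences for a in s.annotations}


# ---------------------------------------------------------------------------
# BIO tag encoding
# ---------------------------------------------------------------------------

def encode_bio(sentence: Sentence) -> list[str]:
    """Encode a sentence's annotations as one BIO tag per token.

    The first token of an entity is tagged ``B-<type>``, the following covered
    tokens ``I-<type>`` and everything else ``O``.  Raises ``ValueError`` when
    two annotations overlap (a BIO sequence cannot represent that).
    """
    tags = ["O"] * len(sentence)
    covered: dict[int, Annotation] = {}
    for ann in sorted(sentence.annotations):
        for i in range(ann.token_start, ann.token_end + 1):
            if i in covered:
                raise ValueError(
                    f"overlapping annotations: {covered[i]} and {ann} "
                    f"both cover token {i}"
                )
            covered[i] = ann
        tags[ann.token_start] = f"B-{ann.entity_type}"
        for i in range(ann.token_start + 1, ann.token_end + 1):
            tags[i] = f"I-{ann.entity_type}"
    return tags


def decode_bio(labels: Sequence[str], sentence_id: str | None = None) -> list[Annotation]:
    """Decode a BIO tag sequence into annotations, repairing ill-formed input.

    Repair convention: an ``I`` following ``O`` (or at sequence start) opens a
    new entity; an ``I`` whose type differs from the running entity closes it
    and opens a new one.  Tagger output is therefore always decodable.
    """
    anns: list[Annotation] = []
    cur_type: str | None = None
    cur_start = 0
    for i, tag in enumerate(labels):
        if tag == "O":
            prefix, etype = "O", None
        elif tag[:2] in ("B-", "I-") and len(tag) > 2:
            prefix, etype = tag[0], tag[2:]
        else:
            raise ValueError(f"malformed BIO tag {tag!r} at position {i}")
        if cur_type is not None and (
            prefix == "O" or prefix == "B" or etype != cur_type
        ):
            anns.append(Annotation(cur_type, cur_start, i - 1, sentence_id=sentence_id))
            cur_type = None
        if prefix in ("B", "I") and cur_type is None:
            cur_type, cur_start = etype, i
    if cur_type is not None:
        anns.append(
            Annotation(cur_type, cur_start, len(labels) - 1, sentence_id=sentence_id)
        )
    return anns


# ---------------------------------------------------------------------------
# Offset dialect
# ---------------------------------------------------------------------------

def _nonws_index_maps(text: str) -> list[int]:
    """Map non-whitespace character ordinal -> raw character offset."""
    return [i for i, c in enumerate(text) if not c.isspace()]


def nonws_span(text: str, start: int, end: int) -> tuple[int, int]:
    """Convert a raw half-open char span to inclusive non-whitespace indices."""
    count = 0
    first = last = -1
    for i, c in enumerate(text):
        if c.isspace():
            continue
        if start <= i < end:
            if first < 0:
                first = count
            last = count
        count += 1
    if first < 0:
        raise ValueError(f"span [{start},{end}) covers no non-whitespace character")
    return first, last


def _align_to_tokens(
    sentence: Sentence, char_start: int, char_end: int
) -> tuple[int, int]:
    """Find the token range exactly covering a half-open raw char span."""
    tok_start = tok_end = None
    for i, tok in enumerate(sentence.tokens):
        if tok.start == char_start:
            tok_start = i
        if tok.end == char_end:
            tok_end = i
    if tok_start is None or tok_end is None or tok_end < tok_start:
        boundaries = [(t.text, t.start, t.end) for t in sentence.tokens]
        raise ValueError(
            f"sentence {sentence.id}: span [{char_start},{char_end}) does not "
            f"align to token boundaries; tokens: {boundaries}"
        )
    return tok_start, tok_end


def read_offset_corpus(
    sentence_file: str | Path,
    annotation_file: str | Path | None = None,
    tokenizer=None,
    entity_type: str = "PRGE",
) -> Corpus:
    """Read an offset-dialect corpus.

    ``sentence_file`` holds ``id<whitespace>text`` lines; ``annotation_file``
    holds ``id|s e|entity text`` lines where ``s``/``e`` are inclusive indices
    over the sentence's non-whitespace characters.  Each annotation's text is
    cross-checked against the offset slice and must align to token boundaries.
    """
    from .tokenization import tokenize  # local import to avoid a cycle

    tokenizer = tokenizer or tokenize
    sentences: dict[str, Sentence] = {}
    for line in Path(sentence_file).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"malformed sentence line: {line!r}")
        sid, text = parts
        if sid in sentences:
            raise ValueError(f"duplicate sentence id {sid}")
        sentences[sid] = Sentence(id=sid, text=text, tokens=tokenizer(text))

    if annotation_file is not None:
        for lineno, line in enumerate(
            Path(annotation_file).read_text(encoding="utf-8").splitlines(), 1
        ):
            if not line.strip():
                continue
            try:
                sid, span, etext = line.split("|", 2)
                s_str, e_str = span.split()
                s, e = int(s_str), int(e_str)
            except ValueError as exc:
                raise ValueError(
                    f"{annotation_file}:{lineno}: malformed annotation line {line!r}"
                ) from exc
            if sid not in sentences:
                raise ValueError(f"{annotation_file}:{lineno}: unknown sentence id {sid}")
            sent = sentences[sid]
            nonws = _nonws_index_maps(sent.text)
            if e >= len(nonws) or s > e or s < 0:
                raise ValueError(
                    f"sentence {sid}: offsets {s} {e} outside sentence"
                )
            char_start, char_end = nonws[s], nonws[e] + 1
            if sent.text[char_start:char_end] != etext:
                raise ValueError(
                    f"sentence {sid}: annotation text {etext!r} does not match "
                    f"offset slice {sent.text[char_start:char_end]!r}"
                )
            ts, te = _align_to_tokens(sent, char_start, char_end)
            sent.annotations.append(Annotation(entity_type, ts, te, sentence_id=sid))
    return Corpus(list(sentences.values()))


def write_offset_corpus(
    corpus: Corpus, sentence_file: str | Path, annotation_file: str | Path
) -> None:
    """Write a corpus in the offset dialect (sentences + annotations)."""
    with open(sentence_file, "w", encoding="utf-8") as fh:
        for sent in corpus:
            fh.write(f"{sent.id} {sent.text}\n")
    write_offset_annotations(corpus, annotation_file)


def write_offset_annotations(corpus: Corpus, path: str | Path) -> None:
    """Write predicted or gold annotations in the offset dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for sent in corpus:
            for ann in sorted(sent.annotations):
                cs, ce = sent.char_span(ann)
                s, e = nonws_span(sent.text, cs, ce)
                fh.write(f"{sent.id}|{s} {e}|{sent.text[cs:ce]}\n")


# ---------------------------------------------------------------------------
# IOB2 dialect
# ---------------------------------------------------------------------------

_DOC_SEP = "###MEDLINE:"


def read_iob2_corpus(path: str | Path) -> Corpus:
    """Read a token-per-line IOB2 corpus (``token<TAB>tag`` lines)."""
    sentences: list[Sentence] = []
    cur_tokens: list[str] = []
    cur_tags: list[str] = []
    doc_id: str | None = None
    counter = 0

    def flush() -> None:
        nonlocal counter
        if not cur_tokens:
            return
        text = " ".join(cur_tokens)
        tokens: list[Token] = []
        pos = 0
        for t in cur_tokens:
            start = text.index(t, pos)
            tokens.append(Token(t, start, start + len(t)))
            pos = start + len(t)
        sid = f"{doc_id or 's'}-{counter}"
        counter += 1
        sent = Sentence(id=sid, text=text, tokens=tokens, doc_id=doc_id)
        sent.annotations = decode_bio(cur_tags, sentence_id=sid)
        sentences.append(sent)
        cur_tokens.clear()
        cur_tags.clear()

    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), 1
    ):
        if line.startswith(_DOC_SEP):
            flush()
            doc_id = line[len(_DOC_SEP):].strip()
            counter = 0
            continue
        if not line.strip():
            flush()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'token<TAB>tag', got {line!r}")
        token, tag = parts
        if not (tag == "O" or (tag[:2] in ("B-", "I-") and len(tag) > 2)):
            raise ValueError(f"{path}:{lineno}: malformed tag {tag!r}")
        cur_tokens.append(token)
        cur_tags.append(tag)
    flush()
    return Corpus(sentences)


def write_iob2_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the IOB2 dialect; inverse of :func:`read_iob2_corpus`.

    Canonical form: a ``###MEDLINE:<id>`` separator followed by a blank line
    whenever the document changes, each sentence as ``token<TAB>tag`` lines
    followed by a blank line, and a single trailing newline.
    """
    lines: list[str] = []
    prev_doc: str | None = None
    for sent in corpus:
        if sent.doc_id is not None and sent.doc_id != prev_doc:
            lines.append(f"{_DOC_SEP}{sent.doc_id}")
            lines.append("")
        prev_doc = sent.doc_id
        tags = encode_bio(sent)
        for tok, tag in zip(sent.tokens, tags):
            lines.append(f"{tok.text}\t{tag}")
        lines.append("")
    content = "\n".join(lines).rstrip("\n")
    with open(path, "w", encoding="utf-8") as fh:
        if content:
            fh.write(content + "\n")
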