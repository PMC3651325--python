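"""Per-token feature extraction for CRF sequence tagging.

Five feature families are implemented:

* **orthographic** — boolean word-formation patterns (capitalisation, digits,
  separators, Roman numerals, Greek letter words);
* **morphological** — prefixes/suffixes of configurable lengths, character
  n-grams, and three word-shape abstractions (digit-run collapse;
  per-character class map; class-run collapse);
* **linguistic** — the token itself plus lemma, part-of-speech tag and BIO
  chunk tag when available;
* **dependency** — lemmas of syntactic neighbours that plausibly signal an
  entity: governing verbs of subjects/objects, modified nouns, and modifiers;
* **local context** — windows (copying neighbour features with an ``@offset``
  marker) and conjunctions (a single feature concatenating attribute values
  of several relative positions, e.g. ``LEMMA=of@-1_&_LEMMA=hyperbilirubinemia@1``).

All extraction is a pure function of (sentence, config): identical input
yields an identical ordered feature-string sequence.  Feature strings never
contain whitespace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Sentence, Token

__all__ = [
    "FeatureVector",
    "FeatureConfig",
    "ORTHOGRAPHIC_PATTERNS",
    "orthographic_features",
    "affix_features",
    "char_ngram_features",
    "word_shape",
    "linguistic_features",
    "dependency_features",
    "window_features",
    "conjunction_features",
    "extract_features",
    "write_feature_file",
]

GREEK_LETTERS = (
    "alpha beta gamma delta epsilon zeta eta theta iota kappa lambda mu nu xi "
    "omicron pi rho sigma tau upsilon phi chi psi omega"
).split()

ROMAN_NUMERALS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")

#: canonical inventory of orthographic word-formation patterns
ORTHOGRAPHIC_PATTERNS = (
    "InitCap",
    "AllCaps",
    "AllLower",
    "MixedCase",
    "SingleChar",
    "AllDigits",
    "ContainsDigit",
    "ContainsHyphen",
    "ContainsSlash",
    "ContainsPeriod",
    "ContainsOtherSymbol",
    "RomanNumeral",
    "GreekLetter",
)


@dataclass
class FeatureVector:
    """The ordered, duplicate-free set of feature strings of one token."""

    token_index: int
    features: list[str] = field(default_factory=list)

    def add(self, feat: str) -> None:
        feat = re.sub(r"\s+", "_", feat)
        if feat not in self._seen:
            self._seen.add(feat)
            self.features.append(feat)

    def __post_init__(self) -> None:
        self._seen = set(self.features)

    def __iter__(self):
        return iter(self.features)

    def __contains__(self, feat: str) -> bool:
        return feat in self._seen


@dataclass(frozen=True)
class FeatureConfig:
    """Per-family toggles and parameters for feature extraction.

    Defaults enable every family except dependency features (which require an
    external parse) and use affix lengths and n-gram sizes of 2–4.
    """

    token: bool = True
    lemma: bool = True
    pos: bool = True
    chunk: bool = True
    orthographic: bool = True
    prefix_suffix: bool = True
    ngrams: bool = True
    shape_i: bool = True
    shape_ii: bool = True
    shape_iii: bool = True
    dependency: bool = False
    lexicon: bool = True
    trigger_words: bool = True
    conjunctions: bool = True
    windows: bool = False

    affix_lengths: tuple[int, ...] = (2, 3, 4)
    ngram_sizes: tuple[int, ...] = (2, 3, 4)
    orthographic_patterns: tuple[str, ...] = ORTHOGRAPHIC_PATTERNS
    #: conjunction window specs as (from, to) relative-offset pairs
    conjunction_windows: tuple[tuple[int, int], ...] = (
        (-3, -1),
        (-2, -1),
        (-1, 0),
        (-1, 1),
        (0, 1),
    )
    #: attribute streams fed to conjunctions, each producing its own features
    conjunction_sources: tuple[str, ...] = ("lemma", "pos")
    window_range: tuple[int, int] = (-1, 1)
    #: feature-name prefixes copied by window features
    window_sources: tuple[str, ...] = ("TOKEN",)

    def __post_init__(self) -> None:
        families = (
            self.token, self.lemma, self.pos, self.chunk, self.orthographic,
            self.prefix_suffix, self.ngrams, self.shape_i, self.shape_ii,
            self.shape_iii, self.dependency, self.lexicon, self.trigger_words,
            self.conjunctions, self.windows,
        )
        if not any(families):
            raise ValueError("at least one feature family must be enabled")
        for a, b in self.conjunction_windows:
            if a > b:
                raise ValueError(f"conjunction window ({a},{b}) has from > to")
        if self.window_range[0] > self.window_range[1]:
            raise ValueError("window_range has from > to")
        unknown = set(self.orthographic_patterns) - set(ORTHOGRAPHIC_PATTERNS)
        if unknown:
            raise ValueError(f"unknown orthographic patterns: {sorted(unknown)}")
        bad = {s for s in self.conjunction_sources if s not in ("token", "lemma", "pos")}
        if bad:
            raise ValueError(f"unknown conjunction sources: {sorted(bad)}")
        if any(k < 1 for k in self.affix_lengths):
            raise ValueError("affix lengths must be >= 1")
        if any(n < 2 for n in self.ngram_sizes):
            raise ValueError("n-gram sizes must be >= 2")

    @classmethod
    def token_only(cls) -> "FeatureConfig":
        """The minimal configuration: only the raw token string."""
        return cls(
            token=True, lemma=False, pos=False, chunk=False, orthographic=False,
            prefix_suffix=False, ngrams=False, shape_i=False, shape_ii=False,
            shape_iii=False, dependency=False, lexicon=False, trigger_words=False,
            conjunctions=False, windows=False,
        )


# ---------------------------------------------------------------------------
# Individual extractors
# ---------------------------------------------------------------------------

def orthographic_features(
    token: Token | str, patterns: Sequence[str] = ORTHOGRAPHIC_PATTERNS
) -> list[str]:
    """Boolean word-formation features, as ``ORT=<PatternName>`` strings."""
    text = token.text if isinstance(token, Token) else token
    if not text:
        raise ValueError("token text must be non-empty")
    has_upper = any(c.isupper() for c in text)
    has_lower = any(c.islower() for c in text)
    checks = {
        "InitCap": text[0].isupper(),
        "AllCaps": text.isalpha() and not has_lower,
        "AllLower": text.isalpha() and not has_upper,
        "MixedCase": has_upper and has_lower,
        "SingleChar": len(text) == 1,
        "AllDigits": text.isdigit(),
        "ContainsDigit": any(c.isdigit() for c in text),
        "ContainsHyphen": "-" in text,
        "ContainsSlash": "/" in text,
        "ContainsPeriod": "." in text,
        "ContainsOtherSymbol": any(
            not c.isalnum() and c not in "-/." for c in text
        ),
        "RomanNumeral": text in ROMAN_NUMERALS,
        "GreekLetter": text.lower() in GREEK_LETTERS,
    }
    return [f"ORT={name}" for name in patterns if checks[name]]


def affix_features(token: Token | str, lengths: Iterable[int]) -> list[str]:
    """``PREFIX=``/``SUFFIX=`` features for each length not exceeding the token."""
    text = token.text if isinstance(token, Token) else token
    out = []
    for k in lengths:
        if k < 1:
            raise ValueError("affix lengths must be >= 1")
        if k <= len(text):
            out.append(f"PREFIX={text[:k]}")
            out.append(f"SUFFIX={text[-k:]}")
    return out


def char_ngram_features(token: Token | str, sizes: Iterable[int]) -> list[str]:
    """All contiguous character n-grams of the given sizes (duplicates dropped)."""
    text = token.text if isinstance(token, Token) else token
    out: list[str] = []
    seen: set[str] = set()
    for n in sizes:
        if n < 2:
            raise ValueError("n-gram sizes must be >= 2")
        for i in range(len(text) - n + 1):
            feat = f"NGRAM={text[i:i + n]}"
            if feat not in seen:
                seen.add(feat)
                out.append(feat)
    return out


def word_shape(token: Token | str, shape_type: str) -> str:
    """Map a token to one of three word-shape abstractions.

    * Type ``I``   — each maximal digit run becomes ``*`` ("Abc1234" → "Abc*");
    * Type ``II``  — each character mapped to its class: uppercase → ``A``,
      lowercase → ``a``, digit → ``1``, symbol → ``#`` ("Abc:1234" → "Aaa#1111");
    * Type ``III`` — each maximal run of letters/digits/symbols collapses to a
      single class character ("Abc:1234" → "a#1").
    """
    text = token.text if isinstance(token, Token) else token
    if not text:
        raise ValueError("token text must be non-empty")
    if shape_type == "I":
        return re.sub(r"\d+", "*", text)
    if shape_type == "II":
        return "".join(
            "A" if c.isupper() else "a" if c.islower() else "1" if c.isdigit() else "#"
            for c in text
        )
    if shape_type == "III":
        out = []
        for c in text:
            cls = "a" if c.isalpha() else "1" if c.isdigit() else "#"
            if not out or out[-1] != cls:
                out.append(cls)
        return "".join(out)
    raise ValueError(f"unknown shape type {shape_type!r}")


def linguistic_features(token: Token, config: "FeatureConfig | None" = None) -> list[str]:
    """Token / lemma / POS / chunk features for the attributes present."""
    cfg = config or FeatureConfig()
    out = []
    if cfg.token:
        out.append(f"TOKEN={token.text}")
    if cfg.lemma and token.lemma is not None:
        out.append(f"LEMMA={token.lemma}")
    if cfg.pos and token.pos is not None:
        out.append(f"POS={token.pos}")
    if cfg.chunk and token.chunk is not None:
        out.append(f"CHUNK={token.chunk}")
    return out


def _arc_lemma(sentence: Sentence, idx: int) -> str:
    tok = sentence.tokens[idx]
    return tok.lemma if tok.lemma is not None else tok.text.lower()


def dependency_features(sentence: Sentence) -> list[list[str]]:
    """Entity-indicative dependency features for every token of a sentence.

    For each arc ``(head, dependent, relation)``:

    * a *subject* relation with a verbal head gives the dependent
      ``DEP_SUBJ_OF=<head lemma>``;
    * an *object* relation with a verbal head gives the dependent
      ``DEP_OBJ_OF=<head lemma>``;
    * a *modifier* relation with a nominal head gives the dependent
      ``DEP_MODIFIES=<head lemma>`` and the head ``DEP_MODIFIER=<dependent lemma>``.
    """
    feats: list[list[str]] = [[] for _ in sentence.tokens]
    n = len(sentence.tokens)
    for head, dep, rel in sentence.dependencies:
        if not (0 <= head < n and 0 <= dep < n):
            raise ValueError(
                f"sentence {sentence.id}: arc ({head},{dep},{rel}) out of range"
            )
        r = rel.lower()
        head_pos = sentence.tokens[head].pos or ""
        verbal = not head_pos or head_pos.startswith("V")
        nominal = not head_pos or head_pos.startswith("N")
        if "subj" in r and verbal:
            feats[dep].append(f"DEP_SUBJ_OF={_arc_lemma(sentence, head)}")
        elif "obj" in r and verbal:
            feats[dep].append(f"DEP_OBJ_OF={_arc_lemma(sentence, head)}")
        elif "mod" in r and nominal:
            feats[dep].append(f"DEP_MODIFIES={_arc_lemma(sentence, head)}")
            feats[head].append(f"DEP_MODIFIER={_arc_lemma(sentence, dep)}")
    return feats


def window_features(
    vectors: Sequence[FeatureVector],
    window: tuple[int, int],
    sources: Sequence[str],
) -> None:
    """Copy neighbour features onto each token with an ``@offset`` marker.

    For token *i* and each non-zero offset *d* in ``[from, to]``, every feature
    of token *i+d* whose name is in ``sources`` is added to token *i* as
    ``<feature>@<d>``.  Mutates ``vectors`` in place.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("window has from > to")
    n = len(vectors)
    originals = [list(v.features) for v in vectors]
    for i, vec in enumerate(vectors):
        for d in range(lo, hi + 1):
            if d == 0 or not (0 <= i + d < n):
                continue
            for feat in originals[i + d]:
                if any(feat.startswith(f"{s}=") for s in sources):
                    vec.add(f"{feat}@{d}")


_SOURCE_ATTR = {"token": "TOKEN", "lemma": "LEMMA", "pos": "POS"}


def _source_value(token: Token, source: str) -> str | None:
    if source == "token":
        return token.text
    if source == "lemma":
        return token.lemma
    if source == "pos":
        return token.pos
    raise ValueError(f"unknown conjunction source {source!r}")


def conjunction_features(
    sentence: Sentence,
    specs: Sequence[tuple[int, int]],
    sources: Sequence[str],
) -> list[list[str]]:
    """Conjunction features joining neighbour attribute values per token.

    For each token *i*, window spec ``(a, b)`` and source attribute, one
    feature is built joining ``<NAME>=<value>@<d>`` for every offset *d* in
    ``[a, b]`` with ``_&_`` in ascending *d*.  Offset ``0`` (the token's own
    value) participates only when it is an endpoint of the spec — the
    symmetric spec ``(-1, 1)`` conjoins only the two neighbours.  Positions
    falling outside the sentence, or whose attribute is missing, are skipped;
    a spec with no surviving position emits nothing.
    """
    n = len(sentence.tokens)
    feats: list[list[str]] = [[] for _ in range(n)]
    for i in range(n):
        for a, b in specs:
            if a > b:
                raise ValueError(f"conjunction spec ({a},{b}) has from > to")
            offsets = [
                d
                for d in range(a, b + 1)
                if (d != 0 or d in (a, b)) and 0 <= i + d < n
            ]
            for source in sources:
                name = _SOURCE_ATTR[source]
                parts = []
                for d in offsets:
                    value = _source_value(sentence.tokens[i + d], source)
                    if value is not None:
                        parts.append(f"{name}={value}@{d}")
                if parts:
                    feats[i].append("_&_".join(parts))
    return feats


# ---------------------------------------------------------------------------
# Full extraction
# ---------------------------------------------------------------------------

def extract_features(
    sentence: Sentence,
    config: FeatureConfig | None = None,
    lexicons: Sequence = (),
) -> list[FeatureVector]:
    """Extract the full configured feature set for every token of a sentence.

    ``lexicons`` are :class:`~bioner.lexicons.Lexicon` objects; entity-name
    lexicons contribute ``LEXICON=<name>`` via longest-match tagging and
    trigger lexicons contribute single-token ``TRIGGER=<name>`` features.
    """
    from .lexicons import match_lexicon, match_triggers  # avoid import cycle

    cfg = config or FeatureConfig()
    vectors = [FeatureVector(i) for i in range(len(sentence.tokens))]

    for i, tok in enumerate(sentence.tokens):
        vec = vectors[i]
        for f in linguistic_features(tok, cfg):
            vec.add(f)
        if cfg.orthographic:
            for f in orthographic_features(tok, cfg.orthographic_patterns):
                vec.add(f)
        if cfg.prefix_suffix:
            for f in affix_features(tok, cfg.affix_lengths):
                vec.add(f)
        if cfg.ngrams:
            for f in char_ngram_features(tok, cfg.ngram_sizes):
                vec.add(f)
        if cfg.shape_i:
            vec.add(f"SHAPE1={word_shape(tok, 'I')}")
        if cfg.shape_ii:
            vec.add(f"SHAPE2={word_shape(tok, 'II')}")
        if cfg.shape_iii:
            vec.add(f"SHAPE3={word_shape(tok, 'III')}")

    if cfg.dependency and sentence.dependencies:
        for vec, fs in zip(vectors, dependency_features(sentence)):
            for f in fs:
                vec.add(f)

    for lex in lexicons:
        is_trigger = getattr(lex, "trigger", False)
        if is_trigger and cfg.trigger_words:
            for i, fs in enumerate(match_triggers(sentence, lex)):
                for f in fs:
                    vectors[i].add(f)
        elif not is_trigger and cfg.lexicon:
            _, token_feats = match_lexicon(sentence, lex)
            for i, fs in enumerate(token_feats):
                for f in fs:
                    vectors[i].add(f)

    if cfg.conjunctions:
        conj = conjunction_features(
            sentence, cfg.conjunction_windows, cfg.conjunction_sources
        )
        for vec, fs in zip(vectors, conj):
            for f in fs:
                vec.add(f)

    if cfg.windows:
        window_features(vectors, cfg.window_range, cfg.window_sources)

    return vectors


def write_feature_file(
    sentences: Sequence[Sentence],
    vectors: Sequence[Sequence[FeatureVector]],
    labels: Sequence[Sequence[str]],
    path: str | Path,
) -> None:
    """Write a CRF-suite-style training file.

    One token per line: ``token<TAB>feat1<TAB>…<TAB>label``; a blank line
    between sentences.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for sent, vecs, tags in zip(sentences, vectors, labels):
            for tok, vec, tag in zip(sent.tokens, vecs, tags):
                fh.write("\t".join([tok.text, *vec.features, tag]) + "\n")
            fh.write("\n")
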