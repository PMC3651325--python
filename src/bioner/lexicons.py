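"""Dictionary matching with orthographic variant expansion.

Gene and protein names appear in text with small, systematic orthographic
variations ("BRCA 1", "BRCA-1", "BRCA1", "hTNF", "factor II" vs "factor 2").
A lexicon entry is therefore expanded into a bounded set of variants before
matching, and matching is greedy longest-match left-to-right over token
subsequences, with tokens joined either by single spaces or with no spaces
(so a hyphen-split "BRCA - 1" still matches the entry "BRCA-1").

Matched tokens receive ``LEXICON=<name>`` features; single-token trigger-word
lexicons (domain terms like "activation" whose presence hints at a nearby
entity) emit ``TRIGGER=<name>`` instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable

from .corpus import Sentence

__all__ = [
    "Lexicon",
    "generate_variants",
    "match_lexicon",
    "match_triggers",
    "load_lexicon",
    "load_sample_lexicon",
]

_ARABIC_TO_GREEK = {
    "1": "alpha", "2": "beta", "3": "gamma", "4": "delta", "5": "epsilon",
    "6": "zeta", "7": "eta", "8": "theta", "9": "iota",
}
_ROMAN_TO_ARABIC = {
    "I": "1", "II": "2", "III": "3", "IV": "4", "V": "5",
    "VI": "6", "VII": "7", "VIII": "8", "IX": "9", "X": "10",
}

#: an acronym for the h-/p-affixing rule: all capitals, length 2–5 (config-exposed)
ACRONYM_RE = re.compile(r"^[A-Z]{2,5}$")


@dataclass
class Lexicon:
    """A named dictionary of entity names or trigger words."""

    name: str
    entries: tuple[str, ...]
    case_sensitive: bool = False
    #: trigger lexicons match single tokens by lemma and emit TRIGGER= features
    trigger: bool = False

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"empty lexicon {self.name!r}")
        for e in self.entries:
            if not e or e != e.strip():
                raise ValueError(f"lexicon {self.name!r}: bad entry {e!r}")

    def __len__(self) -> int:
        return len(self.entries)


def generate_variants(name: str, acronym_re: re.Pattern = ACRONYM_RE) -> list[str]:
    """Expand an entity name into its orthographic variants.

    Each rule is applied once to the base name (no fixed-point iteration):

    1. spaces replaced by hyphens, and hyphens by spaces;
    2. spaces and hyphens removed;
    3. a hyphen inserted at every letter→digit boundary;
    4. standalone Roman numerals I–X replaced by Arabic numbers, and Arabic
       numbers 1–9 by Greek letter words;
    5. for all-capital acronyms, the prefix "h" (human) and the suffix "p"
       (protein) added.

    The base name is always included; the result is deduplicated, preserving
    generation order.
    """
    if not name:
        raise ValueError("name must be non-empty")
    variants = [name]

    def emit(v: str) -> None:
        if v and v != name and v not in variants:
            variants.append(v)

    # rule 1: swap space/hyphen separators
    emit(name.replace(" ", "-"))
    emit(name.replace("-", " "))
    # rule 2: remove separators
    emit(re.sub(r"[ -]", "", name))
    # rule 3: hyphen at letter->digit boundaries
    emit(re.sub(r"(?<=[A-Za-z])(?=[0-9])", "-", name))
    # rule 4: Roman -> Arabic, Arabic -> Greek, on standalone word tokens
    words = re.split(r"(\s+|-)", name)
    emit("".join(_ROMAN_TO_ARABIC.get(w, w) for w in words))
    emit("".join(_ARABIC_TO_GREEK.get(w, w) for w in words))
    # rule 5: h-prefix / p-suffix for acronyms
    if acronym_re.match(name):
        emit(f"h{name}")
        emit(f"{name}p")
    return variants


def _match_key(s: str, case_sensitive: bool) -> str:
    return s if case_sensitive else s.lower()


@dataclass
class _Index:
    """Pre-expanded variant index for matching."""

    exact: set[str]  # case-sensitive keys (short entries / case-sensitive lexicon)
    folded: set[str]  # lowercase keys
    max_chars: int

    @classmethod
    def build(cls, lexicon: Lexicon, short_len: int = 3) -> "_Index":
        exact: set[str] = set()
        folded: set[str] = set()
        max_chars = 0
        for entry in lexicon.entries:
            # entries at most `short_len` characters are acronym-like gene
            # symbols that collide with common words: match them exact-case
            sensitive = lexicon.case_sensitive or len(entry) <= short_len
            for v in generate_variants(entry):
                max_chars = max(max_chars, len(v))
                (exact if sensitive else folded).add(
                    v if sensitive else v.lower()
                )
        return cls(exact, folded, max_chars)

    def __contains__(self, s: str) -> bool:
        return s in self.exact or s.lower() in self.folded


def match_lexicon(
    sentence: Sentence, lexicon: Lexicon, _index: "_Index | None" = None
) -> tuple[list[tuple[int, int]], list[list[str]]]:
    """Greedy longest-match lexicon tagging over token subsequences.

    Candidate spans are tried longest-first, left to right; the tokens of a
    span are joined with single spaces, with no spaces, and with all
    space/hyphen separators stripped (pairing with the separator-removal
    variant rule, so "IL - 2 receptor" still finds "IL-2 receptor").
    Overlapping shorter matches are suppressed.  Returns the matched
    (inclusive) token spans and, per token, the ``LEXICON=<name>`` features.
    """
    index = _index if _index is not None else _Index.build(lexicon)
    n = len(sentence.tokens)
    texts = [t.text for t in sentence.tokens]
    spans: list[tuple[int, int]] = []
    feats: list[list[str]] = [[] for _ in range(n)]
    i = 0
    while i < n:
        matched_end = -1
        # longest span first; bounded by the longest variant's character count
        j = i
        for j_end in range(i, n):
            # the separator-stripped join is the shortest candidate form; once
            # it exceeds the longest variant no longer span can match
            stripped = re.sub(r"[ -]", "", "".join(texts[i : j_end + 1]))
            if len(stripped) > index.max_chars:
                break
            j = j_end
        for end in range(j, i - 1, -1):
            chunk = texts[i : end + 1]
            glued = "".join(chunk)
            if (
                " ".join(chunk) in index
                or glued in index
                or re.sub(r"[ -]", "", glued) in index
            ):
                matched_end = end
                break
        if matched_end >= 0:
            spans.append((i, matched_end))
            for k in range(i, matched_end + 1):
                feats[k].append(f"LEXICON={lexicon.name}")
            i = matched_end + 1
        else:
            i += 1
    return spans, feats


def match_triggers(sentence: Sentence, lexicon: Lexicon) -> list[list[str]]:
    """Single-token trigger matching by exact lemma (token text fallback)."""
    keys = {
        _match_key(e, lexicon.case_sensitive) for e in lexicon.entries
    }
    out: list[list[str]] = []
    for tok in sentence.tokens:
        value = tok.lemma if tok.lemma is not None else tok.text
        if _match_key(value, lexicon.case_sensitive) in keys:
            out.append([f"TRIGGER={lexicon.name}"])
        else:
            out.append([])
    return out


def load_lexicon(
    path: str | Path,
    name: str,
    filter: Callable[[str, str | None], bool] | None = None,
    case_sensitive: bool = False,
    trigger: bool = False,
) -> Lexicon:
    """Load a lexicon file: one name per line, optional TAB-separated source tag.

    ``filter`` receives ``(entry, source_tag)`` and keeps an entry when it
    returns true — e.g. restricting a large resource to human genes by tag.
    """
    entries: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        entry = parts[0].strip()
        source = parts[1].strip() if len(parts) > 1 else None
        if filter is not None and not filter(entry, source):
            continue
        if entry and entry not in seen:
            seen.add(entry)
            entries.append(entry)
    if not entries:
        raise ValueError(f"empty lexicon after filtering: {path}")
    return Lexicon(name, tuple(entries), case_sensitive=case_sensitive, trigger=trigger)


def load_sample_lexicon(which: str = "prge") -> Lexicon:
    """Load one of the bundled sample lexicons (``prge`` or ``trigger``)."""
    fname = {"prge": "prge_sample.txt", "trigger": "trigger_sample.txt"}[which]
    ref = resources.files("bioner.data").joinpath(fname)
    with resources.as_file(ref) as p:
        return load_lexicon(
            p,
            name="PRGE" if which == "prge" else "TRIGGER",
            trigger=(which == "trigger"),
        )
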