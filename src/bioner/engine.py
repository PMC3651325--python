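"""Training and application of CRF taggers over annotated corpora.

This layer wires feature extraction, BIO encoding and the linear-chain CRF
into configurable taggers:

* **direction** — *forward* processes tokens left to right; *backward*
  reverses the token sequence before feature extraction and training, so the
  transition structure is learned right-to-left (the last token of an entity
  in reading order carries ``B`` during processing).  Predictions are
  un-reversed and re-normalized to standard BIO afterwards.
* **order** — a second-order dependency (each label conditioned on the two
  previous labels) is emulated exactly on the first-order chain by expanding
  labels to (previous, current) pairs; predictions are projected back to the
  current component and BIO-repaired.

Each tagged sentence carries a sentence-level confidence (the posterior
probability of the Viterbi path) and a per-annotation confidence (the product
over the annotation's tokens of the posterior marginal of the predicted
label), both used by the model-combination stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Annotation, Corpus, Sentence, Token, decode_bio, encode_bio
from .crf import LinearChainCRF
from .features import FeatureConfig, extract_features

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "TaggedSentence",
    "train",
    "tag",
    "apply_direction",
    "reverse_sentence",
    "expand_order2",
    "project_order2",
    "save_model",
    "load_model",
]

_START = "O"  # virtual previous label at sentence start for order-2 pairs
_PAIR_SEP = "|"


@dataclass(frozen=True)
class ModelConfig:
    """Configuration a tagger is trained under."""

    entity_types: tuple[str, ...] = ("PRGE",)
    order: int = 1
    direction: str = "forward"
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    c2: float = 1.0
    max_iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError(f"order must be 1 or 2, got {self.order}")
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"direction must be forward or backward")
        if not self.entity_types:
            raise ValueError("entity_types must be non-empty")

    @property
    def label_alphabet(self) -> list[str]:
        labels = ["O"]
        for t in sorted(self.entity_types):
            labels += [f"B-{t}", f"I-{t}"]
        return labels


@dataclass
class TrainedModel:
    config: ModelConfig
    crf: LinearChainCRF
    lexicons: tuple = ()


@dataclass
class TaggedSentence:
    """A sentence with predicted BIO labels and confidence scores."""

    sentence: Sentence
    labels: list[str]
    sentence_confidence: float
    annotations: list[Annotation]
    per_annotation_confidence: dict[Annotation, float]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sentence.tokens):
            raise ValueError("label count != token count")
        if not (0.0 < self.sentence_confidence <= 1.0):
            raise ValueError("sentence confidence outside (0,1]")


# ---------------------------------------------------------------------------
# Direction handling
# ---------------------------------------------------------------------------

def reverse_sentence(sentence: Sentence) -> Sentence:
    """Reverse a sentence's token order, building a synthetic reversed text.

    Annotations and dependency arcs are remapped to the reversed indices; BIO
    re-encoding on the result puts ``B`` on the (reading-order) last token of
    each entity, which is the point of backward parsing.
    """
    n = len(sentence.tokens)
    rev = list(reversed(sentence.tokens))
    text = " ".join(t.text for t in rev)
    tokens: list[Token] = []
    pos = 0
    for t in rev:
        tokens.append(
            Token(t.text, pos, pos + len(t.text), lemma=t.lemma, pos=t.pos,
                  chunk=t.chunk)
        )
        pos += len(t.text) + 1
    anns = [
        Annotation(
            a.entity_type, n - 1 - a.token_end, n - 1 - a.token_start,
            confidence=a.confidence, sentence_id=a.sentence_id,
        )
        for a in sentence.annotations
    ]
    deps = [(n - 1 - h, n - 1 - d, rel) for h, d, rel in sentence.dependencies]
    return Sentence(
        id=sentence.id, text=text, tokens=tokens, annotations=anns,
        dependencies=deps, doc_id=sentence.doc_id,
    )


def apply_direction(labels: Sequence[str], direction: str) -> list[str]:
    """Re-express a BIO label sequence for the given processing direction.

    *forward* is the identity.  *backward* reverses the sequence and
    re-derives BIO so that ``B`` marks the first-processed token of each
    entity; applying it twice restores the original sequence.
    """
    if direction == "forward":
        return list(labels)
    if direction != "backward":
        raise ValueError(f"unknown direction {direction!r}")
    anns = decode_bio(list(labels))
    n = len(labels)
    out = ["O"] * n
    for a in anns:
        s, e = n - 1 - a.token_end, n - 1 - a.token_start
        out[s] = f"B-{a.entity_type}"
        for i in range(s + 1, e + 1):
            out[i] = f"I-{a.entity_type}"
    return out


# ---------------------------------------------------------------------------
# Order-2 emulation by label-pair expansion
# ---------------------------------------------------------------------------

def expand_order2(labels: Sequence[str]) -> list[str]:
    """Rewrite a label sequence to (previous, current) pair labels.

    The virtual previous label at sequence start is ``O`` (a sentence begins
    outside any entity), so an alphabet of L labels expands to exactly L×L
    pair labels.
    """
    prev = _START
    out = []
    for y in labels:
        out.append(f"{prev}{_PAIR_SEP}{y}")
        prev = y
    return out


def project_order2(pair_labels: Sequence[str]) -> list[str]:
    """Project pair labels back to their current component."""
    return [y.split(_PAIR_SEP, 1)[1] for y in pair_labels]


def pair_alphabet(labels: Sequence[str]) -> list[str]:
    return [f"{p}{_PAIR_SEP}{c}" for p in labels for c in labels]


# ---------------------------------------------------------------------------
# Training and tagging
# ---------------------------------------------------------------------------

def _prepare(
    sentence: Sentence, config: ModelConfig, lexicons: Sequence
) -> tuple[Sentence, list[list[str]]]:
    """Apply direction, then extract features; returns processing-order data."""
    proc = (
        reverse_sentence(sentence) if config.direction == "backward" else sentence
    )
    vectors = extract_features(proc, config.feature_config, lexicons)
    return proc, [list(v.features) for v in vectors]


def train(
    corpus: Corpus, config: ModelConfig, lexicons: Sequence = ()
) -> TrainedModel:
    """Train a CRF tagger on an annotated corpus under a configuration.

    Raises ``ValueError`` when the corpus contains an entity type absent from
    ``config.entity_types``.
    """
    if not len(corpus):
        raise ValueError("cannot train on an empty corpus")
    stray = corpus.label_set - set(config.entity_types)
    if stray:
        raise ValueError(
            f"corpus contains entity types {sorted(stray)} absent from "
            f"config.entity_types {sorted(config.entity_types)}"
        )
    sequences = []
    for sentence in corpus:
        proc, feats = _prepare(sentence, config, lexicons)
        labels = encode_bio(proc)
        if config.order == 2:
            labels = expand_order2(labels)
        sequences.append((feats, labels))
    crf = LinearChainCRF(
        c2=config.c2, max_iterations=config.max_iterations, seed=config.seed
    )
    crf.fit(sequences)
    return TrainedModel(config=config, crf=crf, lexicons=tuple(lexicons))


def _current_label_marginals(
    marginals: np.ndarray, crf_labels: list[str], order: int
) -> tuple[np.ndarray, list[str]]:
    """Collapse pair-label marginals to current-component label marginals."""
    if order == 1:
        return marginals, crf_labels
    currents = sorted({y.split(_PAIR_SEP, 1)[1] for y in crf_labels})
    idx = {c: k for k, c in enumerate(currents)}
    out = np.zeros((marginals.shape[0], len(currents)))
    for j, y in enumerate(crf_labels):
        out[:, idx[y.split(_PAIR_SEP, 1)[1]]] += marginals[:, j]
    return out, currents


def tag(
    model: TrainedModel, sentence: Sentence, lexicons: Sequence | None = None
) -> TaggedSentence:
    """Tag one sentence with a trained model.

    Returns reading-order BIO labels, annotations decoded from them (with the
    BIO repair convention), the Viterbi path's posterior probability as the
    sentence confidence, and per-annotation confidences as products of
    per-token posterior marginals of the predicted labels.
    """
    config = model.config
    lexs = model.lexicons if lexicons is None else lexicons
    proc, feats = _prepare(sentence, config, lexs)
    raw_labels, path_prob, marginals = model.crf.predict(feats)

    proc_labels = project_order2(raw_labels) if config.order == 2 else raw_labels
    marg, marg_labels = _current_label_marginals(
        marginals, model.crf.labels, config.order
    )
    label_pos = {y: k for k, y in enumerate(marg_labels)}
    # per-token marginal of the predicted (current) label, processing order
    tok_marg_proc = [
        float(marg[t, label_pos[y]]) for t, y in enumerate(proc_labels)
    ]

    if config.direction == "backward":
        labels = apply_direction(proc_labels, "backward")
        tok_marg = list(reversed(tok_marg_proc))
    else:
        labels = list(proc_labels)
        tok_marg = tok_marg_proc

    annotations = []
    per_ann: dict[Annotation, float] = {}
    for ann in decode_bio(labels, sentence_id=sentence.id):
        conf = float(
            np.prod(tok_marg[ann.token_start : ann.token_end + 1])
        )
        conf = min(max(conf, np.finfo(float).tiny), 1.0)
        ann = replace(ann, confidence=conf)
        annotations.append(ann)
        per_ann[ann] = conf
    return TaggedSentence(
        sentence=sentence,
        labels=labels,
        sentence_confidence=path_prob,
        annotations=annotations,
        per_annotation_confidence=per_ann,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _config_dict(config: ModelConfig) -> dict:
    d = asdict(config)
    d["feature_config"] = asdict(config.feature_config)
    return d


def config_hash(config: ModelConfig) -> str:
    return hashlib.sha256(
        json.dumps(_config_dict(config), sort_keys=True, default=list).encode()
    ).hexdigest()[:16]


def save_model(model: TrainedModel, directory: str | Path) -> Path:
    """Serialize a model: weight arrays plus a JSON sidecar of its config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model.crf.save(directory / "weights.npz")
    sidecar = {
        "format_version": 1,
        "config": _config_dict(model.config),
        "config_hash": config_hash(model.config),
        "n_features": len(model.crf.feature_index),
        "labels": model.crf.labels,
    }
    (directory / "model.json").write_text(
        json.dumps(sidecar, indent=2, default=list), encoding="utf-8"
    )
    return directory


def load_model(directory: str | Path, lexicons: Sequence = ()) -> TrainedModel:
    """Load a serialized model, validating its JSON sidecar."""
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text(encoding="utf-8"))
    if sidecar.get("format_version") != 1:
        raise ValueError(f"unsupported model format in {directory}")
    cd = dict(sidecar["config"])
    fc = cd.pop("feature_config")
    fc = {
        k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
        if isinstance(v, list) else v
        for k, v in fc.items()
    }
    config = ModelConfig(
        feature_config=FeatureConfig(**fc),
        **{**cd, "entity_types": tuple(cd["entity_types"])},
    )
    if config_hash(config) != sidecar["config_hash"]:
        raise ValueError(f"config hash mismatch in {directory}")
    crf = LinearChainCRF.load(directory / "weights.npz")
    return TrainedModel(config=config, crf=crf, lexicons=tuple(lexicons))
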