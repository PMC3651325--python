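"""Shared fixtures: tiny hand-built sentences and session-scoped trained models."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from bioner.corpus import Annotation, Corpus, Sentence
from bioner.engine import ModelConfig, tag, train
from bioner.features import FeatureConfig
from bioner.synthetic import generate_corpus
from bioner.tokenization import tokenize

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

TRAIN_SEED, TEST_SEED = 7, 8
N_TRAIN, N_TEST = 200, 50
MAX_ITER = 150


def make_sentence(text: str, sid: str = "s0", annotations=()) -> Sentence:
    """Tokenize text and attach annotations given as (tok_start, tok_end, type)."""
    sent = Sentence(id=sid, text=text, tokens=tokenize(text))
    for ts, te, etype in annotations:
        sent.annotations.append(Annotation(etype, ts, te, sentence_id=sid))
    return sent


@pytest.fixture(scope="session")
def train_corpus() -> Corpus:
    return generate_corpus(N_TRAIN, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def heldout_corpus() -> Corpus:
    return generate_corpus(N_TEST, seed=TEST_SEED)


def _fit(train_c: Corpus, **kwargs) -> object:
    config = ModelConfig(max_iterations=MAX_ITER, **kwargs)
    return train(train_c, config)


@pytest.fixture(scope="session")
def forward_model(train_corpus):
    return _fit(train_corpus)


@pytest.fixture(scope="session")
def token_only_model(train_corpus):
    return _fit(train_corpus, feature_config=FeatureConfig.token_only())


@pytest.fixture(scope="session")
def backward_model(train_corpus):
    return _fit(train_corpus, direction="backward")


@pytest.fixture(scope="session")
def order2_model(train_corpus):
    return _fit(train_corpus, order=2)


def heldout_f1(model, heldout: Corpus) -> float:
    from bioner.evaluation import exact_match_prf

    preds = [
        Sentence(id=s.id, text=s.text, tokens=s.tokens,
                 annotations=tag(model, s).annotations)
        for s in heldout
    ]
    return exact_match_prf(heldout, Corpus(preds)).f1
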