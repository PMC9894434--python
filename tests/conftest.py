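"""Shared fixtures: hand-built dependency trees and tiny corpora."""

from __future__ import annotations

import numpy as np
import pytest

from veracue.corpus_io import Lexicon, ParsedSentence, StatementRecord, Token


def make_sentence(heads, surfaces=None, lemmas=None, upos=None, xpos=None, deprels=None, misc=None):
    """Build a ParsedSentence from parallel per-token attribute lists."""
    n = len(heads)
    surfaces = surfaces or [f"w{i}" for i in range(1, n + 1)]
    lemmas = lemmas or [s.lower() for s in surfaces]
    upos = upos or ["X"] * n
    xpos = xpos or ["subst"] * n
    deprels = deprels or ["root" if h == 0 else "dep" for h in heads]
    misc = misc or [{}] * n
    tokens = [
        Token(
            index=i + 1,
            surface=surfaces[i],
            lemma=lemmas[i],
            upos=upos[i],
            xpos=xpos[i],
            head=heads[i],
            deprel=deprels[i],
            misc=misc[i],
        )
        for i in range(n)
    ]
    return ParsedSentence(tokens=tokens)


def make_statement(sentences, statement_id="st1", subject_id="s1", veracity="truth",
                   modality="written", raw_text=None):
    if raw_text is None:
        raw_text = "\n".join(" ".join(t.surface for t in s.tokens) for s in sentences)
    return StatementRecord(
        statement_id=statement_id,
        subject_id=subject_id,
        topic="1",
        veracity=veracity,
        modality=modality,
        sentences=sentences,
        raw_text=raw_text,
    )


def chain_sentence(k):
    """Chain rooted at token 1; token i attaches to i-1."""
    return make_sentence([0] + list(range(1, k)))


def star_sentence(k):
    """Star rooted at token 1; every other token attaches to the root."""
    return make_sentence([0] + [1] * (k - 1))


def random_tree_heads(n, rng):
    """Uniform random valid heads: each token attaches to any earlier token."""
    heads = [0]
    for i in range(2, n + 1):
        heads.append(int(rng.integers(1, i)))
    return heads


@pytest.fixture
def worked_example():
    """The six-token example sentence with its published dependency tree."""
    return make_sentence(
        heads=[2, 3, 0, 6, 6, 3],
        surfaces=["My", "neighbour", "has", "a", "black", "cat"],
        upos=["DET", "NOUN", "VERB", "DET", "ADJ", "NOUN"],
        xpos=["adj", "subst", "fin", "adj", "adj", "subst"],
        deprels=["det", "nsubj", "root", "det", "amod", "obj"],
    )


@pytest.fixture
def worked_statement(worked_example):
    return make_statement([worked_example])


@pytest.fixture
def lcm_lexicon():
    return Lexicon(
        family="lcm",
        entries={
            "biegać": "DAV",
            "rzucać": "DAV",
            "pomagać": "IAV",
            "oszukiwać": "IAV",
            "kochać": "SV",
            "myśleć": "SV",
            "dobry": "ADJ",
            "czarny": "ADJ",
        },
    )


@pytest.fixture
def sentiment_lexicon():
    return Lexicon(
        family="sentiment",
        entries={"piękny": "positive", "miły": "positive", "okropny": "negative"},
    )


@pytest.fixture
def negation_lexicon():
    return Lexicon(family="negation", entries={"nie": "member", "nigdy": "member"})


@pytest.fixture
def overgen_lexicon():
    return Lexicon(family="overgen", entries={"zawsze": "member", "wszyscy": "member"})


@pytest.fixture
def all_lexicons(lcm_lexicon, sentiment_lexicon, negation_lexicon, overgen_lexicon):
    return {
        "lcm": lcm_lexicon,
        "sentiment": sentiment_lexicon,
        "negation": negation_lexicon,
        "overgen": overgen_lexicon,
    }


@pytest.fixture(scope="session")
def small_corpus():
    """A 30-subject null corpus shared across tests (deterministic)."""
    from veracue import synthetic_data as sd

    corpus, lexicons, truth = sd.generate_corpus(30, sd.null_effects(), seed=11)
    return corpus, lexicons, truth


@pytest.fixture(scope="session")
def small_table(small_corpus):
    from veracue import lexicon_features as lf

    corpus, lexicons, _ = small_corpus
    return lf.extract_table(corpus, lexicons)
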