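"""Synthetic dependency-parsed corpora with a known ground truth.

The generator emulates the study design the analysis stage expects:
``n_subjects`` subjects each contribute four statements in a 2x2
within-subject layout — truth/lie crossed with written/transcribed, the
spoken pair on one topic and the written pair on another. Every cue
family the pipeline measures has a controllable generating parameter:

* statement shape: sentence count and tokens-per-sentence (Poisson with
  log-scale condition shifts),
* syntax: a tree-shape parameter interpolating star-like (flat, MHD -> 1)
  to chain-like (deep, MDD -> 1, MHD -> n/2) dependency trees,
* vocabulary difficulty: the probability that a filler word is complex
  (>= 3 syllables), driving the Fog index,
* lexicon categories: per-token emission probabilities for LCM classes,
  positive/negative sentiment, negations, over-generalizations, and the
  pronoun/infinitive POS families (logit-scale condition shifts).

Condition effects and per-subject random intercepts act on the latent
scale (logit for probabilities, log for lengths) before the inverse link,
matching the random-intercept model the analysis stage fits. Zero shifts
define a null corpus. Lemmas are synthetic CV-syllable strings with exact
known syllable counts, and all category inventories are mutually
disjoint, so every planted count is recoverable exactly. Everything is
deterministic given the seed; a :class:`GroundTruth` record sufficient to
recompute expected per-condition feature means is emitted beside the
corpus.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.special import expit, logit

from .corpus_io import (
    Corpus,
    Lexicon,
    ManifestEntry,
    ParsedSentence,
    StatementRecord,
    Token,
    write_conllu,
    write_lexicon,
    write_manifest,
)

#: Token-emission families, in canonical sampling order.
EMISSION_FAMILIES = (
    "dav",
    "iav",
    "sv",
    "adj",
    "pos_sentiment",
    "neg_sentiment",
    "negation",
    "overgen",
    "ppron12",
    "ppron3",
    "inf",
)

#: Scalar latent families (links: log for lengths, logit for the rest).
SCALAR_FAMILIES = ("n_sentences", "sentence_length", "tree_shape", "p_complex")

_DEFAULT_LEXICON_SIZES: Mapping[str, Mapping[str, int]] = {
    "lcm": {"DAV": 40, "IAV": 40, "SV": 40, "ADJ": 40},
    "sentiment": {"positive": 60, "negative": 60},
    "negation": {"member": 15},
    "overgen": {"member": 15},
}

_CONSONANTS = "bdfgklmnprstwz"
_VOWELS = "aeouy"  # plain nuclei only: one CV pair == one syllable

# Filler (upos, xpos-class, deprel, weight): covers the default detailed-POS
# battery beyond the families controlled directly.
_FILLER_TAGS = (
    ("NOUN", "subst", "obj", 0.26),
    ("NOUN", "depr", "obj", 0.005),
    ("NUM", "num", "nummod", 0.02),
    ("ADJ", "adj", "amod", 0.05),
    ("ADJ", "adja", "amod", 0.01),
    ("ADV", "adv", "advmod", 0.06),
    ("PRON", "siebie", "obj", 0.015),
    ("VERB", "fin", "conj", 0.07),
    ("AUX", "bedzie", "aux", 0.01),
    ("AUX", "aglt", "aux", 0.02),
    ("VERB", "praet", "conj", 0.07),
    ("VERB", "impt", "conj", 0.01),
    ("VERB", "imps", "conj", 0.01),
    ("VERB", "pcon", "advcl", 0.01),
    ("VERB", "pant", "advcl", 0.005),
    ("NOUN", "ger", "obj", 0.02),
    ("ADJ", "pact", "amod", 0.01),
    ("ADJ", "ppas", "amod", 0.02),
    ("VERB", "winien", "conj", 0.005),
    ("VERB", "pred", "conj", 0.01),
    ("ADP", "prep", "case", 0.09),
    ("CCONJ", "conj", "cc", 0.05),
    ("SCONJ", "comp", "mark", 0.02),
    ("PART", "qub", "discourse", 0.04),
    ("INTJ", "interj", "discourse", 0.005),
)


class EffectOverflowError(ValueError):
    """Condition shifts pushed a probability family out of range."""


@dataclass(frozen=True)
class FamilyEffect:
    """Baseline (natural scale) plus latent-scale condition shifts."""

    baseline: float
    veracity: float = 0.0
    modality: float = 0.0
    interaction: float = 0.0

    def latent(self, link, v: float, m: float, u: float = 0.0) -> float:
        return (
            link(self.baseline)
            + self.veracity * v
            + self.modality * m
            + self.interaction * v * m
            + u
        )


def _default_emissions() -> dict[str, FamilyEffect]:
    return {
        "dav": FamilyEffect(0.035),
        "iav": FamilyEffect(0.03),
        "sv": FamilyEffect(0.03),
        "adj": FamilyEffect(0.02),
        "pos_sentiment": FamilyEffect(0.04),
        "neg_sentiment": FamilyEffect(0.04),
        "negation": FamilyEffect(0.02),
        "overgen": FamilyEffect(0.012),
        "ppron12": FamilyEffect(0.03),
        "ppron3": FamilyEffect(0.02),
        "inf": FamilyEffect(0.03),
    }


@dataclass(frozen=True)
class EffectSpec:
    """Generating parameters for one synthetic study.

    Baselines are on the natural scale (counts, probabilities); condition
    shifts and the subject-intercept standard deviation act on the latent
    (log / logit) scale. All-zero shifts define the null corpus.
    """

    n_sentences: FamilyEffect = FamilyEffect(7.0)
    sentence_length: FamilyEffect = FamilyEffect(12.0)
    tree_shape: FamilyEffect = FamilyEffect(0.5)
    p_complex: FamilyEffect = FamilyEffect(0.25)
    emissions: Mapping[str, FamilyEffect] = field(default_factory=_default_emissions)
    sigma_subject: float = 0.3

    def __post_init__(self) -> None:
        unknown = set(self.emissions) - set(EMISSION_FAMILIES)
        if unknown:
            raise ValueError(f"unknown emission families {sorted(unknown)}")

    @property
    def family_names(self) -> tuple[str, ...]:
        return SCALAR_FAMILIES + tuple(self.emissions)

    def to_dict(self) -> dict:
        return {
            "n_sentences": dataclasses.asdict(self.n_sentences),
            "sentence_length": dataclasses.asdict(self.sentence_length),
            "tree_shape": dataclasses.asdict(self.tree_shape),
            "p_complex": dataclasses.asdict(self.p_complex),
            "emissions": {k: dataclasses.asdict(v) for k, v in self.emissions.items()},
            "sigma_subject": self.sigma_subject,
        }


def null_effects(**overrides) -> EffectSpec:
    """Baseline study with zero condition effects everywhere."""
    return EffectSpec(**overrides)


def paper_like_effects() -> EffectSpec:
    """Moderate effects emulating the direction and rough latent size of
    the deception cues the analysis stage is meant to detect.

    Lies are shorter, lexically simpler, less abstract, more positive and
    less negative, with more infinitives; transcribed speech is longer and
    syntactically deeper than writing.
    """
    em = _default_emissions()
    em.update(
        {
            "dav": FamilyEffect(0.035, modality=0.09),
            "sv": FamilyEffect(0.03, modality=0.13),
            "adj": FamilyEffect(0.02, veracity=-0.10),
            "pos_sentiment": FamilyEffect(0.04, veracity=0.12, modality=-0.25),
            "neg_sentiment": FamilyEffect(0.04, veracity=-0.10, modality=-0.25),
            "ppron12": FamilyEffect(0.03, modality=0.10),
            "ppron3": FamilyEffect(0.02, modality=-0.15),
            "inf": FamilyEffect(0.03, veracity=0.15),
        }
    )
    return EffectSpec(
        n_sentences=FamilyEffect(7.0, veracity=-0.09, modality=0.30),
        sentence_length=FamilyEffect(12.0, veracity=-0.05, modality=0.20),
        tree_shape=FamilyEffect(0.5, modality=0.24),
        p_complex=FamilyEffect(0.25, veracity=-0.12, modality=0.18),
        emissions=em,
        sigma_subject=0.3,
    )


def strong_effects() -> EffectSpec:
    """Large planted veracity effects for classifier stress-testing."""
    em = _default_emissions()
    em.update(
        {
            "dav": FamilyEffect(0.035, veracity=0.6),
            "iav": FamilyEffect(0.03, veracity=-0.6),
            "sv": FamilyEffect(0.03, veracity=-0.6),
            "adj": FamilyEffect(0.02, veracity=-0.8),
            "pos_sentiment": FamilyEffect(0.04, veracity=0.9),
            "neg_sentiment": FamilyEffect(0.04, veracity=-0.9),
            "negation": FamilyEffect(0.02, veracity=0.9),
            "overgen": FamilyEffect(0.012, veracity=0.9),
            "ppron12": FamilyEffect(0.03, veracity=-0.8),
            "ppron3": FamilyEffect(0.02, veracity=0.8),
            "inf": FamilyEffect(0.03, veracity=0.9),
        }
    )
    return EffectSpec(
        n_sentences=FamilyEffect(7.0, veracity=-0.30),
        sentence_length=FamilyEffect(12.0, veracity=-0.20),
        tree_shape=FamilyEffect(0.5, veracity=-0.60),
        p_complex=FamilyEffect(0.25, veracity=-0.80),
        emissions=em,
        sigma_subject=0.3,
    )


PRESETS = {
    "null": null_effects,
    "paper_like": paper_like_effects,
    "strong": strong_effects,
}


@dataclass
class GroundTruth:
    """The realized generating process, serialized beside the corpus."""

    seed: int
    n_subjects: int
    effects: EffectSpec
    subject_intercepts: dict[str, dict[str, float]]

    def expected_value(self, family: str, veracity: str, modality: str) -> float:
        """Population-level (zero-intercept) expected parameter per cell."""
        v = -0.5 if veracity == "truth" else 0.5
        m = -0.5 if modality == "written" else 0.5
        if family in ("n_sentences", "sentence_length"):
            fe = getattr(self.effects, family)
            return math.exp(fe.latent(math.log, v, m))
        if family in ("tree_shape", "p_complex"):
            fe = getattr(self.effects, family)
            return float(expit(fe.latent(logit, v, m)))
        fe = self.effects.emissions[family]
        return float(expit(fe.latent(logit, v, m)))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "effects": self.effects.to_dict(),
            "subject_intercepts": self.subject_intercepts,
        }
        Path(path).write_text(
            json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# Vocabulary


@dataclass
class SyntheticVocabulary:
    """Disjoint lemma inventories: category lexicons plus fillers."""

    lexicons: dict[str, Lexicon]
    simple_fillers: list[str]  # 1-2 syllables
    complex_fillers: list[str]  # 3-4 syllables (>= 3: FOG-complex)


def _new_lemma(rng: np.random.Generator, n_syllables: int, used: set[str]) -> str:
    while True:
        lemma = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syllables)
        )
        if lemma not in used:
            used.add(lemma)
            return lemma


def _generate_vocabulary(
    rng: np.random.Generator,
    sizes: Mapping[str, Mapping[str, int]] | None = None,
    n_simple: int = 150,
    n_complex: int = 100,
) -> SyntheticVocabulary:
    sizes = sizes or _DEFAULT_LEXICON_SIZES
    used: set[str] = set()
    lexicons: dict[str, Lexicon] = {}
    for family in ("lcm", "sentiment", "negation", "overgen"):
        if family not in sizes:
            continue
        entries: dict[str, str] = {}
        for category, count in sizes[family].items():
            if count < 1:
                raise ValueError(f"{family}/{category}: size must be >= 1")
            for _ in range(count):
                entries[_new_lemma(rng, 2, used)] = category
        lexicons[family] = Lexicon(family=family, entries=entries)
    # 2 syllables keeps simple fillers below the FOG complexity threshold
    # while leaving a large enough CV-combination space for uniqueness.
    simple = [_new_lemma(rng, 2, used) for _ in range(n_simple)]
    complex_ = [_new_lemma(rng, int(rng.integers(3, 5)), used) for _ in range(n_complex)]
    return SyntheticVocabulary(
        lexicons=lexicons, simple_fillers=simple, complex_fillers=complex_
    )


def generate_lexicons(
    sizes: Mapping[str, Mapping[str, int]] | None = None, seed: int = 0
) -> dict[str, Lexicon]:
    """Deterministic disjoint synthetic lexicons, one per cue family.

    ``sizes`` maps family -> category -> lemma count; categories must
    belong to the family (the Lexicon constructor enforces this).
    """
    vocab_seq, _ = np.random.SeedSequence(seed).spawn(2)
    vocab = _generate_vocabulary(np.random.default_rng(vocab_seq), sizes)
    return vocab.lexicons


# ---------------------------------------------------------------------------
# Trees and statements


def _sample_heads(n_tokens: int, shape: float, rng: np.random.Generator) -> list[int]:
    """Heads for a valid tree rooted at token 1.

    Each token i >= 2 attaches to its predecessor with probability
    ``shape`` (chain-like) and to the root otherwise (star-like); head
    indices always precede dependents, so the result is acyclic.
    """
    heads = [0] * n_tokens
    for i in range(1, n_tokens):  # 0-based position, token index i+1
        if i == 1 or rng.random() >= shape:
            heads[i] = 1
        else:
            heads[i] = i  # previous token's 1-based index
    return heads


def generate_tree(
    n_tokens: int, shape: float, rng: np.random.Generator
) -> ParsedSentence:
    """A valid random tree skeleton with placeholder tokens.

    ``shape = 0`` yields a star (every token attached to the root, MHD =
    1); ``shape = 1`` yields a chain rooted at one end (MDD = 1, MHD =
    n/2); intermediate values interpolate the expected depth.
    """
    if n_tokens < 2:
        raise ValueError("a tree needs at least 2 tokens")
    if not 0.0 <= shape <= 1.0:
        raise ValueError("shape must lie in [0, 1]")
    heads = _sample_heads(n_tokens, shape, rng)
    tokens = [
        Token(
            index=i + 1,
            surface=f"w{i + 1}",
            lemma=f"w{i + 1}",
            upos="X",
            xpos="subst",
            head=heads[i],
            deprel="root" if heads[i] == 0 else "dep",
        )
        for i in range(n_tokens)
    ]
    sent = ParsedSentence(tokens=tokens)
    sent.validate()
    return sent


_FILLER_WEIGHTS = np.array([w for *_, w in _FILLER_TAGS])
_FILLER_WEIGHTS = _FILLER_WEIGHTS / _FILLER_WEIGHTS.sum()


def _emission_probs(
    effects: EffectSpec, v: float, m: float, intercepts: Mapping[str, float]
) -> np.ndarray:
    probs = np.array(
        [
            expit(fe.latent(logit, v, m, intercepts.get(name, 0.0)))
            for name, fe in effects.emissions.items()
        ]
    )
    if probs.sum() >= 0.95:
        raise EffectOverflowError(
            "token-emission probabilities sum to "
            f"{probs.sum():.3f} after condition shifts; no room for filler tokens"
        )
    return probs


def _filler_token(
    index: int,
    head: int,
    p_complex: float,
    vocab: SyntheticVocabulary,
    rng: np.random.Generator,
) -> Token:
    upos, xcls, deprel, _ = _FILLER_TAGS[
        int(rng.choice(len(_FILLER_TAGS), p=_FILLER_WEIGHTS))
    ]
    pool = vocab.complex_fillers if rng.random() < p_complex else vocab.simple_fillers
    lemma = pool[int(rng.integers(len(pool)))]
    return Token(
        index=index,
        surface=lemma,
        lemma=lemma,
        upos=upos,
        xpos=f"{xcls}:sg" if xcls in ("subst", "adj", "ppas", "pact") else xcls,
        head=head,
        deprel=deprel,
    )


def _category_token(
    family: str,
    index: int,
    head: int,
    vocab: SyntheticVocabulary,
    rng: np.random.Generator,
) -> Token:
    def pick(lemmas: list[str]) -> str:
        return lemmas[int(rng.integers(len(lemmas)))]

    if family in ("dav", "iav", "sv"):
        lemma = pick(sorted(vocab.lexicons["lcm"].lemmas(family.upper())))
        return Token(index, lemma, lemma, "VERB", "fin:sg", head, "conj")
    if family == "adj":
        lemma = pick(sorted(vocab.lexicons["lcm"].lemmas("ADJ")))
        # head is forced to the subject noun by the caller
        return Token(index, lemma, lemma, "ADJ", "adj:sg", head, "amod")
    if family in ("pos_sentiment", "neg_sentiment"):
        cat = "positive" if family == "pos_sentiment" else "negative"
        lemma = pick(sorted(vocab.lexicons["sentiment"].lemmas(cat)))
        return Token(index, lemma, lemma, "ADV", "adv", head, "advmod")
    if family == "negation":
        lemma = pick(sorted(vocab.lexicons["negation"].lemmas("member")))
        return Token(index, lemma, lemma, "PART", "qub", head, "advmod")
    if family == "overgen":
        lemma = pick(sorted(vocab.lexicons["overgen"].lemmas("member")))
        return Token(index, lemma, lemma, "ADV", "adv", head, "advmod")
    if family == "ppron12":
        lemma = pick(vocab.simple_fillers)
        return Token(index, lemma, lemma, "PRON", "ppron12:sg:nom", head, "obj")
    if family == "ppron3":
        lemma = pick(vocab.simple_fillers)
        return Token(index, lemma, lemma, "PRON", "ppron3:sg:nom", head, "obj")
    if family == "inf":
        lemma = pick(vocab.simple_fillers)
        return Token(index, lemma, lemma, "VERB", "inf", head, "xcomp")
    raise ValueError(f"unknown emission family {family!r}")


def generate_statement(
    statement_id: str,
    subject_id: str,
    topic: str,
    veracity: str,
    modality: str,
    intercepts: Mapping[str, float],
    effects: EffectSpec,
    vocab: SyntheticVocabulary,
    rng: np.random.Generator,
) -> StatementRecord:
    """Sample one statement under its condition and subject intercepts.

    Token 1 of each sentence is a verb root, token 2 a subject noun
    (deprel nsubj); remaining tokens draw an emission family or a filler
    tag. LCM-adjective tokens are attached amod to the subject noun so
    they pass the subject-modifier filter; all other attachments follow
    the sampled tree. The raw text is the space-joined surface forms, one
    line per sentence.
    """
    v = -0.5 if veracity == "truth" else 0.5
    m = -0.5 if modality == "written" else 0.5

    mean_sent = math.exp(
        effects.n_sentences.latent(math.log, v, m, intercepts.get("n_sentences", 0.0))
    )
    mean_len = math.exp(
        effects.sentence_length.latent(
            math.log, v, m, intercepts.get("sentence_length", 0.0)
        )
    )
    shape = float(
        expit(effects.tree_shape.latent(logit, v, m, intercepts.get("tree_shape", 0.0)))
    )
    p_complex = float(
        expit(effects.p_complex.latent(logit, v, m, intercepts.get("p_complex", 0.0)))
    )
    probs = _emission_probs(effects, v, m, intercepts)
    fam_names = list(effects.emissions)
    p_full = np.append(probs, 1.0 - probs.sum())  # last slot = filler

    n_sent = max(1, int(rng.poisson(mean_sent)))
    sentences = []
    for _ in range(n_sent):
        n_tok = max(2, int(rng.poisson(mean_len)))
        heads = _sample_heads(n_tok, shape, rng)
        tokens: list[Token] = []
        root_lemma = vocab.simple_fillers[int(rng.integers(len(vocab.simple_fillers)))]
        tokens.append(Token(1, root_lemma, root_lemma, "VERB", "fin:sg", 0, "root"))
        subj_lemma = vocab.simple_fillers[int(rng.integers(len(vocab.simple_fillers)))]
        tokens.append(Token(2, subj_lemma, subj_lemma, "NOUN", "subst:sg:nom", 1, "nsubj"))
        for i in range(3, n_tok + 1):
            choice = int(rng.choice(len(p_full), p=p_full))
            head = heads[i - 1]
            if choice == len(fam_names):
                tokens.append(_filler_token(i, head, p_complex, vocab, rng))
            else:
                family = fam_names[choice]
                if family == "adj":
                    head = 2  # attach to the subject noun: qualifying adjective
                tokens.append(_category_token(family, i, head, vocab, rng))
        sentences.append(ParsedSentence(tokens=tokens))
    raw_text = "\n".join(" ".join(t.surface for t in s.tokens) for s in sentences)
    return StatementRecord(
        statement_id=statement_id,
        subject_id=subject_id,
        topic=topic,
        veracity=veracity,
        modality=modality,
        sentences=sentences,
        raw_text=raw_text,
    )


# ---------------------------------------------------------------------------
# Corpus


def generate_corpus(
    n_subjects: int,
    effects: EffectSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    lexicon_sizes: Mapping[str, Mapping[str, int]] | None = None,
) -> tuple[Corpus, dict[str, Lexicon], GroundTruth]:
    """Generate a full 2x2 within-subject corpus (4 statements/subject).

    Returns the in-memory corpus, its lexicons and the ground truth; with
    ``out_dir`` also writes one CoNLL-U + text file per statement, the
    manifest CSV, lexicon TSVs and ``ground_truth.json`` — byte-identical
    across runs with the same seed.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    effects = effects if effects is not None else null_effects()
    vocab_seq, corpus_seq = np.random.SeedSequence(seed).spawn(2)
    vocab = _generate_vocabulary(np.random.default_rng(vocab_seq), lexicon_sizes)
    rng = np.random.default_rng(corpus_seq)

    families = SCALAR_FAMILIES + tuple(effects.emissions)
    statements: list[StatementRecord] = []
    intercept_record: dict[str, dict[str, float]] = {}
    width = max(4, len(str(n_subjects)))
    for s in range(1, n_subjects + 1):
        subject_id = f"subj{s:0{width}d}"
        u = {
            fam: float(rng.normal(0.0, effects.sigma_subject)) for fam in families
        }
        intercept_record[subject_id] = u
        topics = rng.choice(np.arange(1, 14), size=2, replace=False)
        # spoken pair on one topic, written pair on the other
        cells = (
            ("truth", "written", str(int(topics[0]))),
            ("lie", "written", str(int(topics[0]))),
            ("truth", "transcribed", str(int(topics[1]))),
            ("lie", "transcribed", str(int(topics[1]))),
        )
        for veracity, modality, topic in cells:
            sid = f"{subject_id}_{veracity[0]}{modality[0]}"
            statements.append(
                generate_statement(
                    sid, subject_id, topic, veracity, modality, u, effects, vocab, rng
                )
            )
    corpus = Corpus(statements=statements)
    corpus.validate()
    truth = GroundTruth(
        seed=seed,
        n_subjects=n_subjects,
        effects=effects,
        subject_intercepts=intercept_record,
    )
    if out_dir is not None:
        _write_corpus(corpus, vocab, truth, Path(out_dir))
    return corpus, vocab.lexicons, truth


def _write_corpus(
    corpus: Corpus,
    vocab: SyntheticVocabulary,
    truth: GroundTruth,
    out_dir: Path,
) -> None:
    stm_dir = out_dir / "statements"
    lex_dir = out_dir / "lexicons"
    stm_dir.mkdir(parents=True, exist_ok=True)
    lex_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for st in corpus:
        conllu_rel = f"statements/{st.statement_id}.conllu"
        text_rel = f"statements/{st.statement_id}.txt"
        write_conllu(st.sentences, out_dir / conllu_rel)
        (out_dir / text_rel).write_text(st.raw_text or "", encoding="utf-8")
        entries.append(
            ManifestEntry(
                statement_id=st.statement_id,
                subject_id=st.subject_id,
                topic=st.topic,
                veracity=st.veracity,
                modality=st.modality,
                text_file=text_rel,
                conllu_file=conllu_rel,
            )
        )
    write_manifest(entries, out_dir / "manifest.csv")
    for family, lex in vocab.lexicons.items():
        write_lexicon(lex, lex_dir / f"{family}.tsv")
    truth.to_json(out_dir / "ground_truth.json")
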