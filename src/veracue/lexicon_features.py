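"""Per-statement cue features: LCM abstraction, sentiment, word lists,
detailed part-of-speech counts and length.

The Linguistic Category Model (LCM) grades lexical abstraction from
descriptive action verbs (DAV, most concrete) through interpretative
action verbs (IAV) and state verbs (SV) to adjectives (ADJ, most
abstract); the general score is the weighted sum DAV + 2*IAV + 3*SV +
4*ADJ. Verb tokens are matched to classes by lower-cased lemma; adjective
tokens count only when the dependency parse shows them modifying a
subject noun (amod attachment to a token bearing a subject relation).

Sentiment, negation and over-generalization features are lemma-match
counts against the corresponding lexicons. Detailed POS features count
tokens by the class segment of their XPOS tag (NKJP/Morfeusz style, e.g.
``ppron3:sg:nom`` -> ``ppron3``). All counts are stored unnormalized;
per-token normalization happens in the statistics and classification
stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .complexity import statement_complexity
from .corpus_io import Corpus, Lexicon, ParsedSentence, StatementRecord, Token

#: Default detailed-POS battery: 28 NKJP/Morfeusz tag classes.
DEFAULT_POS_TAGS = (
    "subst",
    "depr",
    "num",
    "adj",
    "adja",
    "adv",
    "ppron12",
    "ppron3",
    "siebie",
    "fin",
    "bedzie",
    "aglt",
    "praet",
    "impt",
    "imps",
    "inf",
    "pcon",
    "pant",
    "ger",
    "pact",
    "ppas",
    "winien",
    "pred",
    "prep",
    "conj",
    "comp",
    "qub",
    "interj",
)

#: Features kept on their native scale (everything else is a token count
#: normalized per token downstream).
BASE_FEATURES = ("n_sentences", "n_tokens", "n_characters", "mdd", "mhd", "fog")

METADATA_COLUMNS = ("statement_id", "subject_id", "topic", "veracity", "modality")


@dataclass(frozen=True)
class FeatureConfig:
    """Configuration of the feature battery.

    The default battery has 43 variables: 3 length + 3 complexity + 5 LCM
    + 2 sentiment + 1 negation + 1 over-generalization + 28 detailed-POS
    counts. ``ne_count`` is appended only when MISC carries NE annotations
    (``include_ne="auto"``).
    """

    pos_tags: tuple[str, ...] = DEFAULT_POS_TAGS
    subject_deprels: frozenset[str] = frozenset({"nsubj"})
    amod_deprels: frozenset[str] = frozenset({"amod"})
    adj_requires_lexicon: bool = True
    include_ne: str = "auto"  # "auto" | "always" | "never"
    aggregate: str = "sentence_mean"
    exclude_punct_edges: bool = False
    fog_min_words: int = 100


@dataclass(frozen=True)
class LcmCounts:
    dav: int
    iav: int
    sv: int
    adj: int

    def general_score(self) -> int:
        return lcm_general_score(self)


def feature_names(config: FeatureConfig = FeatureConfig()) -> tuple[str, ...]:
    """Canonical ordered battery (without the optional ne_count column)."""
    return (
        BASE_FEATURES
        + ("dav", "iav", "sv", "adj", "lcm_general")
        + ("pos_sentiment", "neg_sentiment", "negations", "overgen")
        + tuple(f"pos_{t}" for t in config.pos_tags)
    )


def count_feature_names(config: FeatureConfig = FeatureConfig()) -> tuple[str, ...]:
    """Features that are token counts, to be normalized per token."""
    return tuple(n for n in feature_names(config) if n not in BASE_FEATURES)


def adjective_qualifies(token: Token, sentence: ParsedSentence, config: FeatureConfig = FeatureConfig()) -> bool:
    """True iff an adjective token modifies a subject noun.

    The token must attach via an adjectival-modifier relation (amod by
    default) and its head must itself bear a subject relation (nsubj by
    default; scheme variants are configurable). Predicative adjectives
    (root/cop constructions) do not qualify.
    """
    if token.upos != "ADJ":
        return False
    if token.deprel not in config.amod_deprels:
        return False
    if token.head == 0:
        return False
    head = sentence.token(token.head)
    return head.deprel in config.subject_deprels


def lcm_counts(
    statement: StatementRecord,
    lcm_lexicon: Lexicon,
    config: FeatureConfig = FeatureConfig(),
) -> LcmCounts:
    """Count LCM category tokens over the whole statement.

    Verb classes (DAV/IAV/SV) match by lemma; the ADJ class additionally
    requires the subject-modifier syntactic test, and (by default) lemma
    membership in the lexicon's ADJ category.
    """
    if lcm_lexicon.family != "lcm":
        raise ValueError(f"expected an lcm lexicon, got {lcm_lexicon.family!r}")
    dav = iav = sv = adj = 0
    for sent in statement.sentences:
        for tok in sent.tokens:
            cat = lcm_lexicon.category(tok.lemma)
            if cat == "DAV":
                dav += 1
            elif cat == "IAV":
                iav += 1
            elif cat == "SV":
                sv += 1
            elif cat == "ADJ" or (not config.adj_requires_lexicon and tok.upos == "ADJ"):
                if adjective_qualifies(tok, sent, config):
                    adj += 1
    return LcmCounts(dav=dav, iav=iav, sv=sv, adj=adj)


def lcm_general_score(counts: LcmCounts) -> int:
    """Weighted abstraction score DAV + 2*IAV + 3*SV + 4*ADJ."""
    return counts.dav + 2 * counts.iav + 3 * counts.sv + 4 * counts.adj


def sentiment_counts(statement: StatementRecord, sentiment_lexicon: Lexicon) -> tuple[int, int]:
    """(positive, negative) lemma-match token counts."""
    if sentiment_lexicon.family != "sentiment":
        raise ValueError(
            f"expected a sentiment lexicon, got {sentiment_lexicon.family!r}"
        )
    pos = neg = 0
    for sent in statement.sentences:
        for tok in sent.tokens:
            cat = sentiment_lexicon.category(tok.lemma)
            if cat == "positive":
                pos += 1
            elif cat == "negative":
                neg += 1
    return pos, neg


def wordlist_count(statement: StatementRecord, lexicon: Lexicon) -> int:
    """Token count of lemmas present in a membership word list."""
    if lexicon.family not in ("negation", "overgen"):
        raise ValueError(
            f"expected a negation/overgen lexicon, got {lexicon.family!r}"
        )
    count = 0
    for sent in statement.sentences:
        for tok in sent.tokens:
            if lexicon.category(tok.lemma) is not None:
                count += 1
    return count


def pos_counts(
    statement: StatementRecord, config: FeatureConfig = FeatureConfig()
) -> dict[str, int]:
    """Counts of tokens per tracked detailed-POS tag class.

    A token is counted under the first ':'-separated segment of its XPOS
    tag; untracked classes are ignored.
    """
    counts = {tag: 0 for tag in config.pos_tags}
    for sent in statement.sentences:
        for tok in sent.tokens:
            cls = tok.xpos_class
            if cls in counts:
                counts[cls] += 1
    return counts


def ne_count(statement: StatementRecord) -> int:
    """Tokens carrying any NE annotation in MISC (NE=<label>)."""
    return sum(
        1
        for sent in statement.sentences
        for tok in sent.tokens
        if "NE" in tok.misc
    )


def length_features(statement: StatementRecord) -> tuple[int, int, float]:
    """(n_sentences, n_tokens, n_characters).

    Characters are the non-whitespace characters of the raw text; NaN when
    raw text is unavailable (never silently zero).
    """
    n_sentences = len(statement.sentences)
    n_tokens = sum(len(s) for s in statement.sentences)
    if statement.raw_text is None:
        n_characters: float = math.nan
    else:
        n_characters = float(sum(1 for ch in statement.raw_text if not ch.isspace()))
    return n_sentences, n_tokens, n_characters


def extract_features(
    statement: StatementRecord,
    lexicons: Mapping[str, Lexicon],
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Assemble the full per-statement feature vector.

    ``lexicons`` maps family name -> Lexicon; families absent from the
    mapping leave their columns out of the vector (downstream stages that
    need them will fail loudly rather than read silent zeros). Undefined
    components (e.g. FOG on an empty statement) propagate as NaN.
    """
    out: dict[str, float] = {}
    n_sentences, n_tokens, n_characters = length_features(statement)
    out["n_sentences"] = float(n_sentences)
    out["n_tokens"] = float(n_tokens)
    out["n_characters"] = n_characters

    scores = statement_complexity(
        statement,
        aggregate=config.aggregate,
        exclude_punct_edges=config.exclude_punct_edges,
        fog_min_words=config.fog_min_words,
    )
    out["mdd"] = scores.mdd
    out["mhd"] = scores.mhd
    out["fog"] = scores.fog

    if "lcm" in lexicons:
        counts = lcm_counts(statement, lexicons["lcm"], config)
        out["dav"] = float(counts.dav)
        out["iav"] = float(counts.iav)
        out["sv"] = float(counts.sv)
        out["adj"] = float(counts.adj)
        out["lcm_general"] = float(lcm_general_score(counts))
    if "sentiment" in lexicons:
        pos, neg = sentiment_counts(statement, lexicons["sentiment"])
        out["pos_sentiment"] = float(pos)
        out["neg_sentiment"] = float(neg)
    if "negation" in lexicons:
        out["negations"] = float(wordlist_count(statement, lexicons["negation"]))
    if "overgen" in lexicons:
        out["overgen"] = float(wordlist_count(statement, lexicons["overgen"]))

    for tag, cnt in pos_counts(statement, config).items():
        out[f"pos_{tag}"] = float(cnt)

    if config.include_ne == "always":
        out["ne_count"] = float(ne_count(statement))
    elif config.include_ne == "auto":
        cnt = ne_count(statement)
        if cnt > 0:
            out["ne_count"] = float(cnt)
    return out


def extract_table(
    corpus: Corpus,
    lexicons: Mapping[str, Lexicon],
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """One row per statement: design metadata followed by the battery.

    Column order is fixed and identical across rows; the optional
    ``ne_count`` column appears iff any statement carries NE annotations
    (under ``include_ne="auto"``).
    """
    rows = []
    for st in corpus:
        row: dict[str, object] = {
            "statement_id": st.statement_id,
            "subject_id": st.subject_id,
            "topic": st.topic,
            "veracity": st.veracity,
            "modality": st.modality,
        }
        row.update(extract_features(st, lexicons, config))
        rows.append(row)
    df = pd.DataFrame(rows)
    ordered = [c for c in METADATA_COLUMNS if c in df.columns]
    ordered += [n for n in feature_names(config) if n in df.columns]
    if "ne_count" in df.columns:
        if config.include_ne == "auto":
            df["ne_count"] = df["ne_count"].fillna(0.0)
        ordered.append("ne_count")
    return df[ordered]
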