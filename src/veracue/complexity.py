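"""Syntactic and lexical complexity measures.

Three per-statement measures of how demanding a statement is to produce
and comprehend:

* **Mean dependency distance (MDD)** — the mean absolute surface-position
  distance between each dependent token and its head,
  ``MDD = (1/n) * sum_i |DD_i|`` over the ``n = len - 1`` dependency pairs
  of a sentence. A proxy for the working-memory load of the syntax.
* **Mean hierarchical distance (MHD)** — the mean number of dependency
  edges on the path from each non-root token up to the root,
  ``MHD = (1/n) * sum_i HD_i``; the vertical-depth analogue of MDD.
* **Gunning Fog index (FOG)** — the readability score
  ``0.4 * (words/sentences + 100 * complex_words/words)`` where a complex
  word carries three or more syllables; interpreted as years of schooling
  needed to follow the text.

MDD and MHD are undefined (NaN) for single-token sentences; statement
values average the per-sentence values over sentences with at least two
tokens. The syllable counter is a pluggable vowel-nucleus heuristic with a
Polish default vowel set (a maximal run of vowel letters is one nucleus,
so glides like "ia"/"ie" merge into the following vowel).
"""

from __future__ import annotations

import logging
import math
from typing import Callable, NamedTuple

from .corpus_io import ParsedSentence, StatementRecord

logger = logging.getLogger(__name__)

#: Vowel letters for the default (Polish) syllable heuristic.
POLISH_VOWELS = "aeiouyąęó"


class ComplexityScores(NamedTuple):
    mdd: float
    mhd: float
    fog: float


def edge_distances(sentence: ParsedSentence, exclude_punct: bool = False) -> list[int]:
    """Absolute surface distances |index(dependent) - index(head)|.

    One value per non-root token, in token order. With ``exclude_punct``,
    edges whose dependent is a PUNCT token are dropped. Single-token
    sentences yield an empty list.
    """
    out = []
    for tok in sentence.tokens:
        if tok.head == 0:
            continue
        if exclude_punct and tok.upos == "PUNCT":
            continue
        out.append(abs(tok.index - tok.head))
    return out


def token_depths(sentence: ParsedSentence, exclude_punct: bool = False) -> list[int]:
    """Root-path edge counts (hierarchical distances) per non-root token."""
    heads = {t.index: t.head for t in sentence.tokens}
    out = []
    for tok in sentence.tokens:
        if tok.head == 0:
            continue
        if exclude_punct and tok.upos == "PUNCT":
            continue
        depth, cur = 0, tok.index
        while heads[cur] != 0:  # each hop is one edge; stop at the root token
            cur = heads[cur]
            depth += 1
        out.append(depth)
    return out


def mdd_sentence(sentence: ParsedSentence, exclude_punct: bool = False) -> float:
    """Mean dependency distance of one sentence; NaN if fewer than 2 tokens."""
    dists = edge_distances(sentence, exclude_punct=exclude_punct)
    if not dists:
        return math.nan
    return sum(dists) / len(dists)


def mhd_sentence(sentence: ParsedSentence, exclude_punct: bool = False) -> float:
    """Mean hierarchical distance of one sentence; NaN if fewer than 2 tokens."""
    depths = token_depths(sentence, exclude_punct=exclude_punct)
    if not depths:
        return math.nan
    return sum(depths) / len(depths)


def count_syllables(word: str, vowels: str = POLISH_VOWELS) -> int:
    """Count syllable nuclei as maximal runs of vowel letters.

    Returns 0 for empty or vowel-less input. Case-insensitive. This is a
    heuristic adequate for Polish-like orthographies where vowel clusters
    within a word are rare and glide sequences ("ia", "ie") form a single
    nucleus.
    """
    count = 0
    prev_vowel = False
    for ch in word.lower():
        is_vowel = ch in vowels
        if is_vowel and not prev_vowel:
            count += 1
        prev_vowel = is_vowel
    return count


def fog_statement(
    statement: StatementRecord,
    syllable_counter: Callable[[str], int] = count_syllables,
    complex_threshold: int = 3,
    min_words: int = 100,
) -> float:
    """Gunning Fog index over the whole statement.

    Words are non-PUNCT tokens pooled over all sentences; sentence count is
    the number of parsed sentences. Statements shorter than ``min_words``
    are still scored (the index's classic framing assumes a 100-word
    passage) but logged at warning level. Returns NaN when there are no
    words.
    """
    n_sentences = len(statement.sentences)
    if n_sentences == 0:
        return math.nan
    words = 0
    complex_words = 0
    for sent in statement.sentences:
        for tok in sent.tokens:
            if tok.upos == "PUNCT":
                continue
            words += 1
            if syllable_counter(tok.surface) >= complex_threshold:
                complex_words += 1
    if words == 0:
        return math.nan
    if words < min_words:
        logger.warning(
            "statement %s: FOG computed on %d words (< %d); index designed "
            "for longer passages",
            statement.statement_id,
            words,
            min_words,
        )
    return 0.4 * (words / n_sentences + 100.0 * complex_words / words)


def statement_complexity(
    statement: StatementRecord,
    aggregate: str = "sentence_mean",
    exclude_punct_edges: bool = False,
    fog_min_words: int = 100,
) -> ComplexityScores:
    """MDD, MHD and FOG for one statement.

    ``aggregate="sentence_mean"`` (default) averages per-sentence MDD/MHD
    over sentences with >= 2 tokens, treating sentences as exchangeable;
    ``aggregate="edge_pooled"`` pools all edges/depths across sentences
    before averaging. NaN propagates when no sentence is eligible.
    """
    if aggregate not in ("sentence_mean", "edge_pooled"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    if aggregate == "sentence_mean":
        mdds = [
            m
            for s in statement.sentences
            if not math.isnan(m := mdd_sentence(s, exclude_punct=exclude_punct_edges))
        ]
        mhds = [
            m
            for s in statement.sentences
            if not math.isnan(m := mhd_sentence(s, exclude_punct=exclude_punct_edges))
        ]
        mdd = sum(mdds) / len(mdds) if mdds else math.nan
        mhd = sum(mhds) / len(mhds) if mhds else math.nan
    else:
        all_d: list[int] = []
        all_h: list[int] = []
        for s in statement.sentences:
            all_d.extend(edge_distances(s, exclude_punct=exclude_punct_edges))
            all_h.extend(token_depths(s, exclude_punct=exclude_punct_edges))
        mdd = sum(all_d) / len(all_d) if all_d else math.nan
        mhd = sum(all_h) / len(all_h) if all_h else math.nan
    fog = fog_statement(statement, min_words=fog_min_words)
    return ComplexityScores(mdd=mdd, mhd=mhd, fog=fog)
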