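"""Interchange formats for the deception-cue pipeline.

The pipeline is parser-agnostic: statements arrive as CoNLL-U dependency
parses (any conformant parser), a CSV manifest carrying the study design
(subject, topic, veracity, modality), raw text files for character counts,
and TSV category lexicons (LCM verb classes, sentiment polarity, negation
and over-generalization word lists).

Token indices are 1-based and ``head == 0`` marks the root, exactly as
CoNLL-U defines; all downstream distance math uses these conventions.
Multiword-token ranges and empty nodes are skipped on read: they have no
single surface position for distance computations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

VERACITY_LEVELS = ("truth", "lie")
MODALITY_LEVELS = ("written", "transcribed")

#: Allowed categories per lexicon family.
LEXICON_FAMILIES: Mapping[str, frozenset[str]] = {
    "lcm": frozenset({"DAV", "IAV", "SV", "ADJ"}),
    "sentiment": frozenset({"positive", "negative"}),
    "negation": frozenset({"member"}),
    "overgen": frozenset({"member"}),
}

MANIFEST_COLUMNS = (
    "statement_id",
    "subject_id",
    "topic",
    "veracity",
    "modality",
    "text_file",
    "conllu_file",
)


class ConlluParseError(ValueError):
    """Malformed CoNLL-U input (names the offending line)."""


class TreeValidationError(ValueError):
    """A sentence whose head pointers do not form a single-rooted tree."""


class ManifestError(ValueError):
    """Malformed or inconsistent corpus manifest."""


class LexiconError(ValueError):
    """Malformed lexicon file or category/family mismatch."""


@dataclass(frozen=True)
class Token:
    """One syntactic word of a dependency-parsed sentence."""

    index: int
    surface: str
    lemma: str
    upos: str
    xpos: str
    head: int
    deprel: str
    misc: Mapping[str, str] = field(default_factory=dict)

    @property
    def xpos_class(self) -> str:
        """Detailed tag class: the segment of XPOS before the first ':'.

        NKJP/Morfeusz tags pack inflection into colon-separated segments
        (``ppron3:sg:nom`` -> class ``ppron3``).
        """
        return self.xpos.split(":", 1)[0] if self.xpos else ""


@dataclass
class ParsedSentence:
    """An ordered dependency tree over 1-based token indices."""

    tokens: list[Token]

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def token(self, index: int) -> Token:
        """Token by its 1-based index."""
        return self.tokens[index - 1]

    @property
    def root_index(self) -> int:
        for tok in self.tokens:
            if tok.head == 0:
                return tok.index
        raise TreeValidationError("sentence has no root token")

    def validate(self, label: str = "sentence") -> None:
        """Check the ParsedSentence invariants; raise TreeValidationError.

        Indices must be contiguous 1..n, head pointers in range and not
        self-referential, exactly one root, and head links acyclic.
        """
        n = len(self.tokens)
        if n == 0:
            raise TreeValidationError(f"{label}: empty sentence")
        for pos, tok in enumerate(self.tokens, start=1):
            if tok.index != pos:
                raise TreeValidationError(
                    f"{label}: token indices not contiguous at position {pos} "
                    f"(found {tok.index})"
                )
            if not 0 <= tok.head <= n:
                raise TreeValidationError(
                    f"{label}: token {pos} head {tok.head} out of range 0..{n}"
                )
            if tok.head == tok.index:
                raise TreeValidationError(f"{label}: token {pos} is its own head")
        roots = [t.index for t in self.tokens if t.head == 0]
        if len(roots) != 1:
            raise TreeValidationError(
                f"{label}: expected exactly one root, found {len(roots)} "
                f"(indices {roots})"
            )
        # Cycle check: every token must reach the root in <= n steps.
        heads = {t.index: t.head for t in self.tokens}
        for tok in self.tokens:
            cur, steps = tok.index, 0
            while cur != 0:
                cur = heads[cur]
                steps += 1
                if steps > n:
                    raise TreeValidationError(
                        f"{label}: cycle reachable from token {tok.index}"
                    )

    def to_conllu(self) -> str:
        """Serialize as a CoNLL-U sentence block (no trailing blank line)."""
        lines = []
        for tok in self.tokens:
            misc = (
                "|".join(f"{k}={v}" for k, v in tok.misc.items())
                if tok.misc
                else "_"
            )
            lines.append(
                "\t".join(
                    [
                        str(tok.index),
                        tok.surface or "_",
                        tok.lemma or "_",
                        tok.upos or "_",
                        tok.xpos or "_",
                        "_",
                        str(tok.head),
                        tok.deprel or "_",
                        "_",
                        misc,
                    ]
                )
            )
        return "\n".join(lines)


@dataclass
class StatementRecord:
    """One statement: study metadata plus its parsed sentences and raw text."""

    statement_id: str
    subject_id: str
    topic: str
    veracity: str
    modality: str
    sentences: list[ParsedSentence] = field(default_factory=list)
    raw_text: str | None = None

    def validate(self) -> None:
        if self.veracity not in VERACITY_LEVELS:
            raise ManifestError(
                f"statement {self.statement_id}: veracity {self.veracity!r} "
                f"not in {VERACITY_LEVELS}"
            )
        if self.modality not in MODALITY_LEVELS:
            raise ManifestError(
                f"statement {self.statement_id}: modality {self.modality!r} "
                f"not in {MODALITY_LEVELS}"
            )
        if not self.sentences:
            raise ManifestError(f"statement {self.statement_id}: no sentences")
        for i, sent in enumerate(self.sentences, start=1):
            sent.validate(label=f"statement {self.statement_id} sentence {i}")


@dataclass
class Corpus:
    statements: list[StatementRecord]

    def __len__(self) -> int:
        return len(self.statements)

    def __iter__(self):
        return iter(self.statements)

    def validate(self) -> None:
        seen: set[str] = set()
        for st in self.statements:
            if st.statement_id in seen:
                raise ManifestError(f"duplicate statement_id {st.statement_id}")
            seen.add(st.statement_id)
            st.validate()


@dataclass(frozen=True)
class ManifestEntry:
    """One manifest row: statement metadata plus its data file paths."""

    statement_id: str
    subject_id: str
    topic: str
    veracity: str
    modality: str
    text_file: str
    conllu_file: str


@dataclass
class Lexicon:
    """Lemma -> category map for one cue family (lower-cased lemmas)."""

    family: str
    entries: dict[str, str]

    def __post_init__(self) -> None:
        if self.family not in LEXICON_FAMILIES:
            raise LexiconError(f"unknown lexicon family {self.family!r}")
        allowed = LEXICON_FAMILIES[self.family]
        for lemma, cat in self.entries.items():
            if not lemma:
                raise LexiconError(f"{self.family}: empty lemma")
            if lemma != lemma.lower():
                raise LexiconError(f"{self.family}: lemma {lemma!r} not lower-cased")
            if cat not in allowed:
                raise LexiconError(
                    f"{self.family}: category {cat!r} for lemma {lemma!r} "
                    f"not in {sorted(allowed)}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def category(self, lemma: str) -> str | None:
        return self.entries.get(lemma.lower())

    def lemmas(self, category: str) -> set[str]:
        return {l for l, c in self.entries.items() if c == category}


# ---------------------------------------------------------------------------
# CoNLL-U


def _parse_conllu_line(fields: list[str], lineno: int) -> Token:
    try:
        index = int(fields[0])
        head = int(fields[6])
    except ValueError as exc:
        raise ConlluParseError(
            f"line {lineno}: non-integer ID or HEAD field: {exc}"
        ) from None
    misc: dict[str, str] = {}
    if fields[9] != "_":
        for item in fields[9].split("|"):
            if "=" in item:
                k, v = item.split("=", 1)
                misc[k] = v
    return Token(
        index=index,
        surface=fields[1],
        lemma=fields[2],
        upos=fields[3],
        xpos=fields[4],
        head=head,
        deprel=fields[7],
        misc=misc,
    )


def read_conllu(path: str | Path) -> list[ParsedSentence]:
    """Read a CoNLL-U file into validated :class:`ParsedSentence` objects.

    Comment lines, multiword-token ranges (``1-2``) and empty nodes
    (``1.1``) are skipped. Every returned sentence satisfies the tree
    invariants; violations raise :class:`TreeValidationError` naming the
    sentence, malformed lines raise :class:`ConlluParseError` naming the
    line number.
    """
    path = Path(path)
    sentences: list[ParsedSentence] = []
    current: list[Token] = []

    def _flush() -> None:
        if current:
            sent = ParsedSentence(tokens=list(current))
            sent.validate(label=f"{path.name} sentence {len(sentences) + 1}")
            sentences.append(sent)
            current.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                _flush()
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ConlluParseError(
                    f"{path.name} line {lineno}: expected 10 tab-separated "
                    f"columns, found {len(fields)}"
                )
            token_id = fields[0]
            if "-" in token_id or "." in token_id:
                continue  # multiword range / empty node: no surface position
            current.append(_parse_conllu_line(fields, lineno))
    _flush()
    return sentences


def write_conllu(sentences: Iterable[ParsedSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            fh.write(sent.to_conllu())
            fh.write("\n\n")


# ---------------------------------------------------------------------------
# Manifest and corpus assembly


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read and validate the corpus manifest CSV.

    Rejects missing columns, duplicate statement ids and veracity/modality
    values outside the closed vocabularies.
    """
    path = Path(path)
    entries: list[ManifestEntry] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in MANIFEST_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ManifestError(f"{path.name}: missing manifest columns {missing}")
        for rownum, row in enumerate(reader, start=2):
            sid = row["statement_id"].strip()
            if not sid:
                raise ManifestError(f"{path.name} row {rownum}: empty statement_id")
            if sid in seen:
                raise ManifestError(
                    f"{path.name} row {rownum}: duplicate statement_id {sid!r}"
                )
            seen.add(sid)
            veracity = row["veracity"].strip()
            modality = row["modality"].strip()
            if veracity not in VERACITY_LEVELS:
                raise ManifestError(
                    f"{path.name} row {rownum} ({sid}): veracity {veracity!r} "
                    f"not in {VERACITY_LEVELS}"
                )
            if modality not in MODALITY_LEVELS:
                raise ManifestError(
                    f"{path.name} row {rownum} ({sid}): modality {modality!r} "
                    f"not in {MODALITY_LEVELS}"
                )
            entries.append(
                ManifestEntry(
                    statement_id=sid,
                    subject_id=row["subject_id"].strip(),
                    topic=row["topic"].strip(),
                    veracity=veracity,
                    modality=modality,
                    text_file=row["text_file"].strip(),
                    conllu_file=row["conllu_file"].strip(),
                )
            )
    return entries


def load_corpus(manifest_path: str | Path, base_dir: str | Path | None = None) -> Corpus:
    """Assemble a full :class:`Corpus` from a manifest and its data files.

    Paths in the manifest are resolved relative to ``base_dir`` (default:
    the manifest's directory). All missing files are reported together.
    """
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    entries = read_manifest(manifest_path)
    missing = []
    for e in entries:
        for rel in (e.text_file, e.conllu_file):
            if not (base / rel).is_file():
                missing.append(str(base / rel))
    if missing:
        raise ManifestError("missing corpus files: " + ", ".join(sorted(set(missing))))
    statements = []
    for e in entries:
        sentences = read_conllu(base / e.conllu_file)
        raw_text = (base / e.text_file).read_text(encoding="utf-8")
        st = StatementRecord(
            statement_id=e.statement_id,
            subject_id=e.subject_id,
            topic=e.topic,
            veracity=e.veracity,
            modality=e.modality,
            sentences=sentences,
            raw_text=raw_text,
        )
        statements.append(st)
    corpus = Corpus(statements=statements)
    corpus.validate()
    return corpus


def write_manifest(entries: Sequence[ManifestEntry], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for e in entries:
            writer.writerow(
                [
                    e.statement_id,
                    e.subject_id,
                    e.topic,
                    e.veracity,
                    e.modality,
                    e.text_file,
                    e.conllu_file,
                ]
            )


# ---------------------------------------------------------------------------
# Lexicons


def read_lexicon(path: str | Path, family: str) -> Lexicon:
    """Read a two-column TSV lexicon (``lemma<TAB>category``).

    Lemmas are lower-cased on read. Duplicate lemmas with conflicting
    categories and categories outside the family's set are errors.
    """
    path = Path(path)
    if family not in LEXICON_FAMILIES:
        raise LexiconError(f"unknown lexicon family {family!r}")
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LexiconError(
                    f"{path.name} line {lineno}: expected 'lemma<TAB>category'"
                )
            lemma = parts[0].strip().lower()
            cat = parts[1].strip()
            if lemma in entries and entries[lemma] != cat:
                raise LexiconError(
                    f"{path.name} line {lineno}: lemma {lemma!r} already mapped "
                    f"to {entries[lemma]!r}, conflicting {cat!r}"
                )
            entries[lemma] = cat
    return Lexicon(family=family, entries=entries)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lemma in sorted(lexicon.entries):
            fh.write(f"{lemma}\t{lexicon.entries[lemma]}\n")


# ---------------------------------------------------------------------------
# Feature tables


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as TSV (missing values as empty fields)."""
    if table.empty:
        raise ValueError("refusing to write an empty feature table")
    table.to_csv(path, sep="\t", index=False, na_rep="")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read back a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"statement_id": str, "subject_id": str, "topic": str})
    return df
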