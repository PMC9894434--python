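"""corpus_io: CoNLL-U parsing, tree validation, manifest and lexicon I/O."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from veracue import corpus_io as cio
from .conftest import make_sentence, random_tree_heads

WORKED_CONLLU = """\
# text = My neighbour has a black cat
1\tMy\tmy\tDET\tadj\t_\t2\tdet\t_\t_
2\tneighbour\tneighbour\tNOUN\tsubst\t_\t3\tnsubj\t_\t_
3\thas\thave\tVERB\tfin\t_\t0\troot\t_\t_
4\ta\ta\tDET\tadj\t_\t6\tdet\t_\t_
5\tblack\tblack\tADJ\tadj\t_\t6\tamod\t_\t_
6\tcat\tcat\tNOUN\tsubst\t_\t3\tobj\t_\tNE=ANIMAL
"""


class TestReadConllu:
    def test_worked_example_tree(self, tmp_path):
        path = tmp_path / "ex.conllu"
        path.write_text(WORKED_CONLLU)
        sents = cio.read_conllu(path)
        assert len(sents) == 1
        sent = sents[0]
        assert len(sent) == 6
        assert sent.root_index == 3
        assert [t.head for t in sent.tokens] == [2, 3, 0, 6, 6, 3]
        assert sent.token(6).misc == {"NE": "ANIMAL"}

    def test_single_token_sentence(self, tmp_path):
        path = tmp_path / "one.conllu"
        path.write_text("1\tTak\ttak\tPART\tqub\t_\t0\troot\t_\t_\n")
        sents = cio.read_conllu(path)
        assert len(sents) == 1 and len(sents[0]) == 1

    def test_multiword_ranges_and_empty_nodes_skipped(self, tmp_path):
        text = (
            "1-2\tdel\t_\t_\t_\t_\t_\t_\t_\t_\n"
            "1\tde\tde\tADP\tprep\t_\t2\tcase\t_\t_\n"
            "2\tel\tel\tDET\tadj\t_\t0\troot\t_\t_\n"
            "2.1\tnull\t_\t_\t_\t_\t_\t_\t_\t_\n"
        )
        path = tmp_path / "mw.conllu"
        path.write_text(text)
        (sent,) = cio.read_conllu(path)
        assert [t.index for t in sent.tokens] == [1, 2]

    def test_cycle_rejected(self, tmp_path):
        text = (
            "1\ta\ta\tX\tx\t_\t0\troot\t_\t_\n"
            "2\tb\tb\tX\tx\t_\t3\tdep\t_\t_\n"
            "3\tc\tc\tX\tx\t_\t2\tdep\t_\t_\n"
        )
        path = tmp_path / "cyc.conllu"
        path.write_text(text)
        with pytest.raises(cio.TreeValidationError, match="cycle"):
            cio.read_conllu(path)

    def test_multi_root_rejected(self, tmp_path):
        text = (
            "1\ta\ta\tX\tx\t_\t0\troot\t_\t_\n"
            "2\tb\tb\tX\tx\t_\t0\troot\t_\t_\n"
        )
        path = tmp_path / "mr.conllu"
        path.write_text(text)
        with pytest.raises(cio.TreeValidationError, match="root"):
            cio.read_conllu(path)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.conllu"
        path.write_text("1\tonly\tthree\n")
        with pytest.raises(cio.ConlluParseError, match="line 1"):
            cio.read_conllu(path)

    def test_roundtrip_preserves_structure(self, tmp_path, worked_example):
        out = tmp_path / "rt.conllu"
        cio.write_conllu([worked_example], out)
        (back,) = cio.read_conllu(out)
        for a, b in zip(worked_example.tokens, back.tokens):
            assert (a.index, a.head, a.deprel, a.lemma) == (
                b.index,
                b.head,
                b.deprel,
                b.lemma,
            )


class TestTreeValidation:
    def test_corrupted_trees_all_rejected(self):
        """Redirecting one head to create a cycle or a second root is
        always caught, across 1,000 random corruptions."""
        rng = np.random.default_rng(1234)
        rejected = 0
        trials = 1000
        for _ in range(trials):
            n = int(rng.integers(3, 15))
            heads = random_tree_heads(n, rng)
            heads_bad = list(heads)
            if rng.random() < 0.5:
                # second root: some non-root token's head set to 0
                idx = int(rng.integers(1, n))
                heads_bad[idx] = 0
            else:
                # cycle: root's head redirected onto one of its descendants
                heads_bad[0] = int(rng.integers(2, n + 1))
            sent = make_sentence(heads_bad)
            try:
                sent.validate()
            except cio.TreeValidationError:
                rejected += 1
        assert rejected == trials

    def test_self_head_rejected(self):
        with pytest.raises(cio.TreeValidationError, match="own head"):
            make_sentence([0, 2]).validate()

    def test_noncontiguous_indices_rejected(self):
        sent = make_sentence([0, 1])
        object.__setattr__(sent.tokens[1], "index", 5)
        with pytest.raises(cio.TreeValidationError, match="contiguous"):
            sent.validate()


class TestManifest:
    def _write(self, tmp_path, rows):
        header = ",".join(cio.MANIFEST_COLUMNS)
        path = tmp_path / "manifest.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_four_statement_design(self, tmp_path):
        rows = [
            f"s1_{v[0]}{m[0]},subj1,3,{v},{m},s1.txt,s1.conllu"
            for v in ("truth", "lie")
            for m in ("written", "transcribed")
        ]
        entries = cio.read_manifest(self._write(tmp_path, rows))
        assert len(entries) == 4
        assert {e.subject_id for e in entries} == {"subj1"}
        assert {(e.veracity, e.modality) for e in entries} == {
            (v, m) for v in ("truth", "lie") for m in ("written", "transcribed")
        }

    def test_header_only_is_empty(self, tmp_path):
        assert cio.read_manifest(self._write(tmp_path, [])) == []

    def test_unknown_veracity_rejected(self, tmp_path):
        path = self._write(tmp_path, ["x,subj1,1,maybe,written,a.txt,a.conllu"])
        with pytest.raises(cio.ManifestError, match="maybe"):
            cio.read_manifest(path)

    def test_duplicate_statement_id_rejected(self, tmp_path):
        rows = [
            "x,subj1,1,truth,written,a.txt,a.conllu",
            "x,subj2,1,lie,written,b.txt,b.conllu",
        ]
        with pytest.raises(cio.ManifestError, match="duplicate"):
            cio.read_manifest(self._write(tmp_path, rows))

    def test_load_corpus_reports_missing_files(self, tmp_path):
        path = self._write(tmp_path, ["x,subj1,1,truth,written,a.txt,a.conllu"])
        with pytest.raises(cio.ManifestError, match="missing corpus files"):
            cio.load_corpus(path)


class TestLexicon:
    def test_category_family_mismatch(self, tmp_path):
        path = tmp_path / "lex.tsv"
        path.write_text("kot\tDAV\n")
        with pytest.raises(cio.LexiconError):
            cio.read_lexicon(path, "sentiment")

    def test_one_row_per_lcm_category(self, tmp_path):
        path = tmp_path / "lcm.tsv"
        path.write_text("biegac\tDAV\npomagac\tIAV\nkochac\tSV\ndobry\tADJ\n")
        lex = cio.read_lexicon(path, "lcm")
        assert len(lex) == 4
        assert lex.category("Biegac".lower()) == "DAV"

    def test_sentiment_fixture_count(self, tmp_path):
        rows = [f"pos{i}\tpositive" for i in range(10)]
        rows += [f"neg{i}\tnegative" for i in range(10)]
        path = tmp_path / "sent.tsv"
        path.write_text("\n".join(rows) + "\n")
        lex = cio.read_lexicon(path, "sentiment")
        assert len(lex) == 20
        assert len(lex.lemmas("positive")) == 10

    def test_conflicting_duplicate_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("slowo\tpositive\nslowo\tnegative\n")
        with pytest.raises(cio.LexiconError, match="conflict"):
            cio.read_lexicon(path, "sentiment")

    def test_lemmas_lowercased_on_read(self, tmp_path):
        path = tmp_path / "up.tsv"
        path.write_text("Nigdy\tmember\n")
        lex = cio.read_lexicon(path, "negation")
        assert lex.category("NIGDY") == "member"


class TestFeatureTable:
    def test_roundtrip_identity_with_nan(self, tmp_path):
        table = pd.DataFrame(
            {
                "statement_id": ["a", "b"],
                "subject_id": ["s1", "s1"],
                "n_tokens": [10.0, 12.0],
                "fog": [4.0, math.nan],
            }
        )
        path = tmp_path / "feat.tsv"
        cio.write_feature_table(table, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 3  # header + 2 rows
        back = cio.read_feature_table(path)
        assert back["fog"].isna().tolist() == [False, True]
        pd.testing.assert_frame_equal(back, table)

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            cio.write_feature_table(pd.DataFrame(), tmp_path / "x.tsv")
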