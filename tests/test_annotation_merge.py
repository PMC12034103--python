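"""Annotation token normalization, frequency tables, and two-source merging."""

import pytest

from loopclust.annotations import (
    AnnotationError,
    AnnotationRecord,
    PatternFrequencyTable,
    merge_annotations,
    normalize_pair_token,
    normalize_records,
    normalize_stack_token,
    read_annotation_file,
)


class TestTokenNormalization:
    @pytest.mark.parametrize(
        "raw, canonical",
        [
            ("cWW", "cWW"),
            ("cW-W", "cWW"),
            ("tS/H", "tSH"),
            ("CWH", "cWH"),
            ("thh", "tHH"),
            (" cSS ", "cSS"),
        ],
    )
    def test_pair_spellings(self, raw, canonical):
        assert normalize_pair_token(raw) == canonical

    @pytest.mark.parametrize("raw", ["qWW", "cWX", "cW", "cWWW", "", "pair"])
    def test_bad_pair_token(self, raw):
        with pytest.raises(AnnotationError, match=repr(raw)):
            normalize_pair_token(raw)

    @pytest.mark.parametrize(
        "raw, canonical",
        [
            ("upward", "upward"), ("up", "upward"), ("s35", "upward"),
            ("down", "downward"), ("s53", "downward"),
            ("in", "inward"), ("s33", "inward"),
            ("OUT", "outward"), ("s55", "outward"),
        ],
    )
    def test_stack_spellings(self, raw, canonical):
        assert normalize_stack_token(raw) == canonical

    def test_bad_stack_token(self):
        with pytest.raises(AnnotationError, match="sideways"):
            normalize_stack_token("sideways")


def _rec(ci="A", ri=1, cj="A", rj=10, kind="pair", token="cWW",
         source="FR3D", bi="G", bj="C", sid="1AAA"):
    return AnnotationRecord(
        structure_id=sid, chain_i=ci, res_i=ri, chain_j=cj, res_j=rj,
        kind=kind, class_token=token, source=source, base_i=bi, base_j=bj,
    )


class TestAnnotationRecord:
    def test_non_canonical_token_rejected(self):
        with pytest.raises(AnnotationError):
            _rec(token="cW-W")

    def test_unknown_kind_rejected(self):
        with pytest.raises(AnnotationError):
            _rec(kind="hbond", token="cWW")

    def test_partner_key_is_order_free(self):
        a = _rec(ri=1, rj=10, token="tWH")
        b = _rec(ri=10, rj=1, token="tHW")
        assert a.partner_key == b.partner_key

    def test_canonical_reorients_pair(self):
        rec = _rec(ri=10, rj=1, token="tWH", bi="G", bj="A")
        canon = rec.canonical()
        assert (canon.res_i, canon.res_j) == (1, 10)
        assert canon.class_token == "tHW"
        assert (canon.base_i, canon.base_j) == ("A", "G")
        # already-canonical records are returned unchanged
        assert canon.canonical() is canon

    def test_canonical_reorients_stack(self):
        rec = _rec(ri=5, rj=4, kind="stack", token="upward")
        canon = rec.canonical()
        assert (canon.res_i, canon.res_j) == (4, 5)
        assert canon.class_token == "downward"


class TestNormalizeRecords:
    def test_reads_both_kinds(self):
        rows = [
            ["1AAA", "A", "1", "G", "A", "10", "C", "pair", "cW-W"],
            ["1AAA", "A", "2", "A", "A", "3", "G", "stack", "s35"],
        ]
        recs = normalize_records(rows, "DSSR")
        assert recs[0].class_token == "cWW"
        assert recs[0].base_i == "G"
        assert recs[1].kind == "stack"
        assert recs[1].class_token == "upward"
        assert all(r.source == "DSSR" for r in recs)

    def test_wrong_width_names_row(self):
        with pytest.raises(AnnotationError, match="row 2"):
            normalize_records(
                [["1AAA", "A", "1", "G", "A", "10", "C", "pair", "cWW"],
                 ["1AAA", "A", "1"]],
                "FR3D",
            )

    def test_unknown_source_rejected(self):
        with pytest.raises(AnnotationError, match="RNAVIEW"):
            normalize_records([], "RNAVIEW")

    def test_file_reader_skips_comments(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "# comment line\n"
            "1AAA\tA\t1\tG\tA\t10\tC\tpair\tcWW\n"
            "\n"
            "1AAA\tA\t2\tA\tA\t3\tG\tstack\tup\n"
        )
        recs = read_annotation_file(path, "FR3D")
        assert len(recs) == 2


class TestFrequencyTable:
    def test_transpose_lookup(self):
        t = PatternFrequencyTable()
        t.add("G", "A", "tHS", 3)
        assert t.count("G", "A", "tHS") == 3
        assert t.count("A", "G", "tSH") == 3  # physically the same pattern
        t.add("A", "G", "tSH", 2)
        assert t.count("G", "A", "tHS") == 5

    def test_stack_tokens_have_no_transpose(self):
        t = PatternFrequencyTable()
        t.add("G", "A", "upward", 4)
        assert t.count("G", "A", "upward") == 4
        assert t.count("A", "G", "upward") == 0

    def test_tsv_round_trip(self, tmp_path):
        t = PatternFrequencyTable()
        t.add("G", "C", "cWW", 120)
        t.add("A", "G", "tSH", 7)
        path = tmp_path / "freq.tsv"
        t.to_tsv(path)
        back = PatternFrequencyTable.from_tsv(path)
        assert back.counts == t.counts


class TestMerge:
    def test_true_duplicates_collapse_with_preferred_provenance(self):
        a = [_rec(source="FR3D")]
        b = [_rec(ri=10, rj=1, bi="C", bj="G", source="DSSR")]  # same pair, flipped
        merged, log = merge_annotations(a, b)
        assert len(merged) == 1
        assert merged[0].source == "FR3D"
        assert log == []

    def test_class_conflict_resolved_by_frequency(self):
        freq = PatternFrequencyTable()
        freq.add("G", "C", "cWW", 100)
        freq.add("G", "C", "tHS", 5)
        a = [_rec(token="tHS", source="FR3D")]
        b = [_rec(token="cWW", source="DSSR")]
        merged, log = merge_annotations(a, b, freq)
        assert [r.class_token for r in merged] == ["cWW"]
        assert len(log) == 1
        assert log[0]["dropped"].class_token == "tHS"
        assert log[0]["reason"] == "same-pair class conflict"

    def test_class_conflict_tie_prefers_fr3d(self):
        a = [_rec(token="tHS", source="FR3D")]
        b = [_rec(token="cWW", source="DSSR")]
        merged, _ = merge_annotations(a, b)
        assert [r.class_token for r in merged] == ["tHS"]

    def test_edge_slot_conflict(self):
        # Both pairs claim the Watson-Crick edge of A:1; the rarer loses.
        freq = PatternFrequencyTable()
        freq.add("G", "C", "cWW", 50)
        a = [_rec(ri=1, rj=10, token="cWW")]
        b = [_rec(ri=1, rj=20, token="cWS", source="DSSR", bj="A")]
        merged, log = merge_annotations(a, b, freq)
        assert len(merged) == 1
        assert merged[0].res_j == 10
        assert log[0]["reason"] == "edge already claimed"

    def test_different_edges_coexist(self):
        # cWW on one partner and tHS on another use different edges of A:1.
        a = [_rec(ri=1, rj=10, token="cWW")]
        b = [_rec(ri=1, rj=20, token="tHS", source="DSSR", bj="A")]
        merged, log = merge_annotations(a, b)
        assert len(merged) == 2
        assert log == []

    def test_stacks_pass_through(self):
        a = [_rec(kind="stack", token="upward")]
        b = [_rec(ri=10, rj=1, kind="stack", token="downward", source="DSSR")]
        merged, log = merge_annotations(a, b)
        assert len(merged) == 1  # same physical stack, deduplicated
        assert log == []

    def test_merge_is_deterministic_and_sorted(self):
        recs = [
            _rec(ri=5, rj=30, token="tWW"),
            _rec(ri=1, rj=10, token="cWW"),
            _rec(ri=2, rj=3, kind="stack", token="upward"),
        ]
        m1, _ = merge_annotations(recs, [])
        m2, _ = merge_annotations(list(reversed(recs)), [])
        assert m1 == m2
        keys = [(r.kind, r.res_i, r.res_j) for r in m1]
        assert keys == sorted(keys)
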