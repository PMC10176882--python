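"""Best-hit selection, cutoff filtering, annotation transfer, name priority."""

import logging
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_hit
from morfkit.hits import (
    DEFAULT_BIT_SCORE_CUTOFF,
    AnnotationRecord,
    HitTableError,
    MorphologAssignment,
    TransferConfig,
    aggregate_and_filter,
    assignment_row,
    collapse_to_genes,
    compose_display_name,
    read_assignment_table,
    read_foldseek_hits,
    select_best_per_db,
    transfer_annotations,
    write_assignment_table,
)


class TestReadHits:
    def test_parses_twelve_column_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\tP12345\t0.118\t150\t100\t3\t1\t150\t5\t154\t1e-30\t250.0\n"
        )
        (hit,) = read_foldseek_hits(path, database="afdb")
        assert hit.query_id == "q1"
        assert hit.target_id == "P12345"
        assert hit.seq_identity == pytest.approx(0.118)
        assert hit.bit_score == 250.0
        assert (hit.q_start, hit.q_end, hit.t_start, hit.t_end) == (1, 150, 5, 154)

    def test_empty_file_and_extra_columns(self, tmp_path):
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        assert read_foldseek_hits(empty, "afdb") == []
        extra = tmp_path / "extra.tsv"
        extra.write_text(
            "q1\tt1\t0.2\t100\t50\t2\t1\t100\t1\t100\t1e-10\t90.0\textra\tcols\n"
        )
        (hit,) = read_foldseek_hits(extra, "afdb")
        assert hit.bit_score == 90.0

    @pytest.mark.parametrize(
        "line, fragment",
        [
            ("q1\tt1\t0.2\t100\t50\t2\t1\t100\t1\t100\t1e-10\tabc", "line 2"),
            ("q1\tt1\t0.2\t100", "line 2"),
        ],
    )
    def test_malformed_row_names_line_number(self, tmp_path, line, fragment):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "q0\tt0\t0.2\t100\t50\t2\t1\t100\t1\t100\t1e-10\t90.0\n" + line + "\n"
        )
        with pytest.raises(HitTableError, match=fragment):
            read_foldseek_hits(path, "afdb")

    def test_input_order_preserved(self, tmp_path):
        path = tmp_path / "hits.tsv"
        rows = [
            f"q1\tt{i}\t0.2\t100\t50\t2\t1\t100\t1\t100\t1e-10\t{100 - i}.0"
            for i in range(5)
        ]
        path.write_text("\n".join(rows) + "\n")
        hits = read_foldseek_hits(path, "pdb")
        assert [h.target_id for h in hits] == [f"t{i}" for i in range(5)]


class TestSelectBest:
    def test_picks_maximum_bit_score(self):
        hits = [make_hit(bits=b, target=f"t{b}") for b in (100.0, 250.0, 30.0)]
        best = select_best_per_db(hits)
        assert best[("q1", "afdb")].bit_score == 250.0

    def test_tie_broken_by_evalue_then_target(self):
        a = make_hit(bits=100.0, evalue=1e-5, target="tA")
        b = make_hit(bits=100.0, evalue=1e-9, target="tB")
        for order in ([a, b], [b, a]):
            assert select_best_per_db(order)[("q1", "afdb")] is b
        c = make_hit(bits=100.0, evalue=1e-9, target="tC")
        for order in ([b, c], [c, b]):
            assert select_best_per_db(order)[("q1", "afdb")] is b

    def test_single_hit_and_empty(self):
        only = make_hit()
        assert select_best_per_db([only]) == {("q1", "afdb"): only}
        assert select_best_per_db([]) == {}

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5),  # query
                st.sampled_from(["afdb", "pdb"]),
                st.integers(0, 400),  # bit score (ints so ties occur)
                st.integers(0, 30),  # e-value grade
                st.integers(0, 20),  # target id
            ),
            max_size=200,
        )
    )
    def test_matches_brute_force_scan(self, rows):
        hits = [
            make_hit(
                query=f"q{q}",
                database=db,
                bits=float(bits),
                evalue=10.0**-e,
                target=f"t{t:02d}",
            )
            for q, db, bits, e, t in rows
        ]
        best = select_best_per_db(hits)
        groups = {}
        for h in hits:
            groups.setdefault((h.query_id, h.database), []).append(h)
        assert set(best) == set(groups)
        for key, group in groups.items():
            expected = sorted(
                group, key=lambda h: (-h.bit_score, h.e_value, h.target_id)
            )[0]
            assert best[key] == expected


class TestAggregateAndFilter:
    def _assignments(self, bits_by_db):
        hits = [
            make_hit(database=db, bits=bits, target=f"t_{db}")
            for db, bits in bits_by_db.items()
        ]
        return aggregate_and_filter(select_best_per_db(hits))

    def test_boundary_is_strict(self):
        # 148.0 < e^5 = 148.4131... ; the cutoff itself would also fail
        (asg,) = self._assignments({"afdb": 148.0})
        assert not asg.passes_cutoff
        (asg,) = self._assignments({"afdb": DEFAULT_BIT_SCORE_CUTOFF})
        assert not asg.passes_cutoff
        (asg,) = self._assignments({"afdb": 200.0})
        assert asg.passes_cutoff

    def test_overall_best_across_databases(self):
        (asg,) = self._assignments({"afdb": 180.0, "pdb": 220.0, "swissprot": 90.0})
        assert asg.overall_best.database == "pdb"
        assert set(asg.best_hit_per_db) == {"afdb", "pdb", "swissprot"}
        assert asg.best_hit_per_db["swissprot"].bit_score == 90.0

    def test_no_hits_yields_empty_list(self):
        assert aggregate_and_filter({}) == []

    def test_filtering_monotone_in_cutoff(self):
        hits = [
            make_hit(query=f"q{i}", bits=float(50 + 10 * i), target=f"t{i}")
            for i in range(30)
        ]
        best = select_best_per_db(hits)
        passing = [
            sum(
                a.passes_cutoff
                for a in aggregate_and_filter(
                    best, TransferConfig(bit_score_cutoff=c)
                )
            )
            for c in (60.0, 120.0, 200.0, 400.0)
        ]
        assert passing == sorted(passing, reverse=True)

    def test_permutation_invariant(self):
        hits = [
            make_hit(query=f"q{i % 4}", database=db, bits=float(b), target=f"t{b}")
            for i, (db, b) in enumerate(
                [("afdb", 100), ("pdb", 300), ("afdb", 200), ("pdb", 150)] * 3
            )
        ]
        forward = aggregate_and_filter(select_best_per_db(hits))
        backward = aggregate_and_filter(select_best_per_db(hits[::-1]))
        assert forward == backward


class TestTransfer:
    def test_transfers_morpholog_name(self):
        # e.g. a chicken FGF4 best hit naming an unannotated sponge query
        hits = [make_hit(query="sq1", target="P48804", bits=300.0)]
        assignments = aggregate_and_filter(select_best_per_db(hits))
        record = AnnotationRecord(protein_id="P48804", preferred_name="FGF4")
        (asg,) = transfer_annotations(assignments, {"P48804": record})
        assert asg.transferred.preferred_name == "FGF4"
        assert asg.transferred.source == "structure"
        assert asg.transferred.protein_id == "sq1"

    def test_failing_query_gets_nothing(self):
        hits = [make_hit(query="sq1", target="P48804", bits=100.0)]
        assignments = aggregate_and_filter(select_best_per_db(hits))
        (asg,) = transfer_annotations(
            assignments, {"P48804": AnnotationRecord(protein_id="P48804")}
        )
        assert asg.transferred is None

    def test_missing_target_annotation_warns(self, caplog):
        hits = [make_hit(query="sq1", target="Pmissing", bits=300.0)]
        assignments = aggregate_and_filter(select_best_per_db(hits))
        with caplog.at_level(logging.WARNING):
            (asg,) = transfer_annotations(assignments, {})
        assert asg.transferred is None
        assert "Pmissing" in caplog.text


class TestCollapseToGenes:
    def test_best_isoform_wins(self):
        assignments = aggregate_and_filter(
            select_best_per_db(
                [
                    make_hit(query="i1", bits=150.0, target="tA"),
                    make_hit(query="i2", bits=160.0, target="tB"),
                ]
            )
        )
        by_gene = collapse_to_genes(assignments, {"i1": "g", "i2": "g"})
        assert by_gene["g"].overall_best.bit_score == 160.0

    def test_single_isoform_unchanged(self):
        assignments = aggregate_and_filter(
            select_best_per_db([make_hit(query="i1", bits=150.0)])
        )
        by_gene = collapse_to_genes(assignments, {"i1": "g"})
        assert by_gene["g"] == assignments[0]

    def test_all_hitless_isoforms_keep_hitless_record(self):
        hitless = [
            MorphologAssignment(query_id="i1"),
            MorphologAssignment(query_id="i2"),
        ]
        by_gene = collapse_to_genes(hitless, {"i1": "g", "i2": "g"})
        assert by_gene["g"].overall_best is None
        assert not by_gene["g"].passes_cutoff

    def test_unmapped_isoform_is_listed(self):
        with pytest.raises(KeyError, match="i2"):
            collapse_to_genes(
                [MorphologAssignment(query_id="i1"), MorphologAssignment(query_id="i2")],
                {"i1": "g"},
            )


class TestDisplayName:
    LEGACY = AnnotationRecord("p", preferred_name="LegName", source="legacy")
    SEQ = AnnotationRecord("p", preferred_name="SeqName", description="seq desc")
    MORF = AnnotationRecord(
        "p", preferred_name="MorfName", description="morf desc", source="structure"
    )
    MORF_DESC_ONLY = AnnotationRecord("p", description="morf desc", source="structure")

    @pytest.mark.parametrize(
        "legacy, seq, morf, expected",
        [
            (LEGACY, SEQ, MORF, ("LegName", "legacy")),
            (None, SEQ, MORF, ("SeqName", "seq_name")),
            (None, AnnotationRecord("p", description="seq desc"), MORF,
             ("seq desc", "seq_description")),
            (None, None, MORF, ("MorfName", "morf_name")),
            (None, None, MORF_DESC_ONLY, ("morf desc", "morf_description")),
            (None, None, None, ("unannotated", "none")),
        ],
    )
    def test_priority_order(self, legacy, seq, morf, expected):
        assert compose_display_name(legacy, seq, morf) == expected


def test_assignment_table_round_trips(tmp_path):
    hits = [
        make_hit(query="q1", bits=300.0, target="tA"),
        make_hit(query="q2", bits=90.0, target="tB"),
    ]
    assignments = transfer_annotations(
        aggregate_and_filter(select_best_per_db(hits)),
        {"tA": AnnotationRecord("tA", preferred_name="NAME", description="desc")},
    )
    rows = [assignment_row(a) for a in assignments]
    path = tmp_path / "assignments.tsv"
    write_assignment_table(rows, path)
    assert read_assignment_table(path) == rows
    # writing the re-read rows reproduces the file byte for byte
    path2 = tmp_path / "again.tsv"
    write_assignment_table(read_assignment_table(path), path2)
    assert path.read_bytes() == path2.read_bytes()
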