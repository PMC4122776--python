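import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import repquant as rq
from repquant.counting import ReadSubfamilyMap, count_reads

SAM_TEXT = (
    "@HD\tVN:1.6\n"
    "@SQ\tSN:chr1\tLN:10000\n"
    + "".join(
        f"u{i}\t0\tchr1\t{101 + 40 * i}\t255\t30M\t*\t0\t0\t{'A' * 30}\t*\n"
        for i in range(8)
    )
    + "x0\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTACGTACGTACGTACGTACGTAC\t*\n"
    + "x1\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTACGTACGTACGTACGTACGTAC\t*\n"
)

FASTQ_TEXT = "".join(
    f"@m{i}\n{'ACGT' * 8}\n+\n{'I' * 32}\n" for i in range(5)
)


def _map_from(sets):
    rmap = ReadSubfamilyMap()
    for i, s in enumerate(sets):
        rmap.add(f"r{i}", 0, s)
    return rmap


class TestCountingStrategies:
    def test_worked_example(self):
        # 10 reads {A}; 4 reads {A,B}; 1 read {B,C}
        rmap = _map_from([{"A"}] * 10 + [{"A", "B"}] * 4 + [{"B", "C"}])
        df = count_reads(rmap, ["A", "B", "C"])
        assert df["total"].tolist() == [14, 5, 1]
        assert df["unique"].tolist() == [10, 0, 0]
        assert df["fractional_unrounded"].tolist() == [12.0, 2.5, 0.5]
        # nearest integer, ties to even
        assert df["fractional"].tolist() == [12, 2, 0]

    def test_empty_map_all_zero(self):
        df = count_reads(ReadSubfamilyMap(), ["A", "B"])
        assert (df[["total", "unique", "fractional"]] == 0).all().all()

    def test_singleton_sets_make_strategies_coincide(self):
        rmap = _map_from([{"A"}] * 5 + [{"B"}] * 3)
        df = count_reads(rmap)
        assert (df["total"] == df["unique"]).all()
        assert (df["total"] == df["fractional_unrounded"]).all()

    @given(
        st.lists(
            st.sets(st.sampled_from("ABCDE"), min_size=1, max_size=4),
            max_size=60,
        )
    )
    def test_conservation_and_ordering(self, sets):
        df = count_reads(_map_from(sets), list("ABCDE"))
        # each read distributes total mass exactly 1
        assert df["fractional_unrounded"].sum() == pytest.approx(len(sets), abs=1e-9)
        assert (df["unique"] <= df["fractional_unrounded"] + 1e-12).all()
        assert (df["fractional_unrounded"] <= df["total"] + 1e-12).all()


class TestUniqueReadAssignment:
    instances = [
        rq.RepeatInstance("chr1", 120, 300, "+", "L1PA2", "L1", "LINE", 0),
        rq.RepeatInstance("chr1", 90, 110, "+", "AluY", "Alu", "SINE", 1),
        rq.RepeatInstance("chr1", 140, 400, "+", "L1PA3", "L1", "LINE", 2),
    ]

    def _assign(self, start, end):
        ua = rq.UniqueAlignment("r", 0, "chr1", start, end)
        rmap = rq.assign_unique_reads([ua], self.instances)
        return rmap[("r", 0)] if len(rmap) else None

    def test_single_overlap(self):
        # [100,150) overlaps L1PA2 [120,300) and AluY [90,110) and L1PA3 [140,400)
        assert self._assign(200, 250) == {"L1PA2", "L1PA3"}
        assert self._assign(300, 350) == {"L1PA3"}

    def test_no_overlap_unassigned(self):
        assert self._assign(0, 50) is None

    def test_two_subfamily_overlap(self):
        assert self._assign(95, 145) == {"AluY", "L1PA2", "L1PA3"}
        # spec's minimal two-subfamily case, away from L1PA2
        inst = [self.instances[1], self.instances[2]]
        ua = rq.UniqueAlignment("r", 0, "chr1", 95, 145)
        assert rq.assign_unique_reads([ua], inst)[("r", 0)] == {"AluY", "L1PA3"}

    def test_one_bp_overlap_counts(self):
        # [119,121) overlaps L1PA2 [120,300) by exactly 1 bp
        assert self._assign(119, 121) == {"L1PA2"}
        # [299,301): last bp of L1PA2 plus inside L1PA3
        assert self._assign(299, 301) == {"L1PA2", "L1PA3"}
        # [110,120) touches neither AluY (ends at 110) nor L1PA2 (starts 120)
        assert self._assign(110, 120) is None


class TestPartition:
    def test_sam_fastq_partition(self, tmp_path):
        sam = tmp_path / "u.sam"
        fq = tmp_path / "m.fastq"
        sam.write_text(SAM_TEXT)
        fq.write_text(FASTQ_TEXT)
        part = rq.partition_alignments(sam, fq)
        assert len(part.unique) == 8
        assert len(part.multimap) == 5
        assert part.n_unmapped == 2

    def test_empty_multimap_is_all_unique(self, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text(SAM_TEXT)
        part = rq.partition_alignments(sam, None)
        assert len(part.unique) == 8 and part.multimap == []

    def test_read_in_both_inputs_rejected(self, tmp_path):
        sam = tmp_path / "u.sam"
        fq = tmp_path / "m.fastq"
        sam.write_text(SAM_TEXT)
        fq.write_text("@u0\n" + "ACGT" * 8 + "\n+\n" + "I" * 32 + "\n")
        with pytest.raises(ValueError, match="both"):
            rq.partition_alignments(sam, fq)

    def test_matcher_partition_matches_placement_counts(
        self, oracle_toy, oracle_reads
    ):
        index = rq.KmerIndex(dict(oracle_toy.genome), 2)
        part = rq.partition_with_matcher(oracle_reads, index, 2)
        oracle = rq.brute_force_align(
            {rid: seq for rid, _m, seq in oracle_reads}, dict(oracle_toy.genome), 2
        )
        n_unique = sum(1 for v in oracle.values() if len(v) == 1)
        n_multi = sum(1 for v in oracle.values() if len(v) > 1)
        assert len(part.unique) == n_unique
        assert len(part.multimap) == n_multi
        assert part.n_unmapped == len(oracle_reads) - n_unique - n_multi


class TestMultimapAssignment:
    def test_within_pseudogenome_hits_collapse(self):
        # read matches 2 loci of A's pseudogenome and 1 locus of B's
        core = "ACGGTTCAGGCATTACCGG"
        pgs = {
            "A": core + "N" * 30 + core,
            "B": "TTTT" + core + "GGGG",
            "C": "GCGCGCGCATATATATGCGCAT",
        }
        index = rq.KmerIndex(pgs, 0)
        rmap, dropped = rq.map_multireads(
            [rq.MultimapRead("r", 0, core)], index
        )
        assert rmap[("r", 0)] == {"A", "B"}
        assert dropped == 0

    def test_nowhere_aligning_read_dropped(self):
        index = rq.KmerIndex({"A": "ACGTACGTACGTACGTACGT"}, 0)
        rmap, dropped = rq.map_multireads(
            [rq.MultimapRead("r", 0, "GGGGCCCCAAAATTTTGGCC")], index
        )
        assert len(rmap) == 0 and dropped == 1


class TestAggregateAndCpm:
    def _table(self):
        counts = pd.DataFrame(
            {"s1": [5, 7, 3]},
            index=pd.Index(["L1PA2", "L1PA3", "AluY"], name="subfamily"),
        )
        hierarchy = rq.RepeatHierarchy(
            {"L1PA2": ("L1", "LINE"), "L1PA3": ("L1", "LINE"), "AluY": ("Alu", "SINE")}
        )
        table = rq.CountTable("total", counts, pd.Series({"s1": 2_000_000}))
        return table, hierarchy

    def test_family_aggregation(self):
        table, hierarchy = self._table()
        fam = rq.aggregate(table, "family", hierarchy)
        assert fam.counts.loc["L1", "s1"] == 12
        assert fam.counts.loc["Alu", "s1"] == 3  # singleton family: identity

    def test_class_aggregation_worked_example(self):
        # total counts A=14, B=5, C=1 with A,B in class X and C in class Y
        counts = pd.DataFrame({"s": [14, 5, 1]}, index=["A", "B", "C"])
        h = rq.RepeatHierarchy({"A": ("fA", "X"), "B": ("fB", "X"), "C": ("fC", "Y")})
        table = rq.CountTable("total", counts, pd.Series({"s": 100}))
        cls = rq.aggregate(table, "class", h)
        assert cls.counts["s"].to_dict() == {"X": 19, "Y": 1}

    def test_aggregate_missing_subfamily_errors(self):
        table, _ = self._table()
        bad = rq.RepeatHierarchy({"L1PA2": ("L1", "LINE")})
        with pytest.raises(KeyError):
            rq.aggregate(table, "family", bad)

    def test_cpm_formula(self):
        table, _ = self._table()
        c = rq.cpm(table)
        assert c.loc["L1PA2", "s1"] == pytest.approx(5 * 1e6 / 2_000_000)
        counts0 = table.counts.copy()
        counts0.loc["L1PA2", "s1"] = 0
        t0 = rq.CountTable("total", counts0, table.library_sizes)
        assert rq.cpm(t0).loc["L1PA2", "s1"] == 0.0

    def test_cpm_column_sum_identity(self, oracle_toy, oracle_reads):
        from repquant.pseudogenome import build_pseudogenome_set, pseudogenome_sequences

        gidx = rq.KmerIndex(dict(oracle_toy.genome), 2)
        pgidx = rq.KmerIndex(
            pseudogenome_sequences(
                build_pseudogenome_set(oracle_toy.instances, oracle_toy.genome)
            ),
            2,
        )
        part = rq.partition_with_matcher(oracle_reads, gidx, 2)
        res = rq.quantify_sample(
            part, oracle_toy.instances, pgidx, oracle_toy.hierarchy.subfamilies, 2
        )
        table = rq.CountTable(
            "fractional",
            res.counts[["fractional_unrounded"]].rename(
                columns={"fractional_unrounded": "s"}
            ),
            pd.Series({"s": res.library_size}),
        )
        col_sum = rq.cpm(table)["s"].sum()
        assert col_sum == pytest.approx(1e6 * len(res.read_map) / res.library_size)

    def test_zero_library_size_rejected(self):
        table, _ = self._table()
        table.library_sizes["s1"] = 0
        with pytest.raises(ValueError):
            rq.cpm(table)


class TestOverlapFraction:
    instances = [rq.RepeatInstance("chr1", 100, 300, "+", "AluY", "Alu", "SINE", 0)]

    def test_fractional_overlap_threshold(self):
        # read [90,140): 40/50 bp inside the instance
        ua = rq.UniqueAlignment("r", 0, "chr1", 90, 140)
        assert rq.assign_unique_reads([ua], self.instances, 0.5)[("r", 0)] == {"AluY"}
        rmap = rq.assign_unique_reads([ua], self.instances, 0.9)
        assert len(rmap) == 0

    def test_default_is_one_bp(self):
        ua = rq.UniqueAlignment("r", 0, "chr1", 99, 101)
        assert rq.assign_unique_reads([ua], self.instances)[("r", 0)] == {"AluY"}
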