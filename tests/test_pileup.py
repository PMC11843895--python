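import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import g4methyl as gm
from g4methyl.pileup import (
    ModProbTriple,
    ReadModCalls,
    accuracy_track,
    classify_call,
    global_modification_levels,
    pileup,
    read_bedmethyl,
    read_call_table,
    site_accuracy,
    write_bedmethyl,
    write_call_table,
)
from g4methyl.sequence import AmpliconSequence, find_cpg_sites


def triple(p_c, p_m, p_h=None):
    if p_h is None:
        p_h = 1.0 - p_c - p_m
    return ModProbTriple(p_c, p_m, p_h)


@st.composite
def prob_triples(draw):
    a = draw(st.floats(0.01, 10.0))
    b = draw(st.floats(0.01, 10.0))
    c = draw(st.floats(0.01, 10.0))
    total = a + b + c
    return ModProbTriple(a / total, b / total, 1.0 - a / total - b / total)


class TestModProbTriple:
    def test_valid(self):
        t = triple(0.2, 0.7, 0.1)
        assert t.as_tuple() == (0.2, 0.7, 0.1)

    def test_bad_sum(self):
        with pytest.raises(ValueError, match="sum"):
            ModProbTriple(0.5, 0.6, 0.2)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ModProbTriple(1.2, -0.1, -0.1)


class TestClassifyCall:
    def test_certain_canonical(self):
        assert classify_call(triple(1.0, 0.0, 0.0), 0.65).state == "canonical"

    def test_confident_5mc(self):
        assert classify_call(triple(0.2, 0.7, 0.1), 0.65).state == "5mC"

    def test_low_confidence_filtered(self):
        call = classify_call(triple(0.4, 0.35, 0.25), 0.65)
        assert call.state == "filtered"
        assert call.max_prob == 0.4

    def test_tie_break_canonical_over_5mc(self):
        # exact tie resolves canonical > 5mC > 5hmC
        call = classify_call(ModProbTriple(0.5, 0.5, 0.0), 0.5001)
        assert call.state == "filtered"  # 0.5 < 0.5001
        call = classify_call(ModProbTriple(0.5, 0.5, 0.0), 0.4)
        assert call.state == "canonical"

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            classify_call(triple(1.0, 0.0, 0.0), 1.0 / 3.0)
        with pytest.raises(ValueError):
            classify_call(triple(1.0, 0.0, 0.0), 1.1)

    @given(prob_triples(), st.floats(0.34, 0.99), st.floats(0.34, 0.99))
    def test_monotone_in_threshold(self, t, th1, th2):
        lo, hi = sorted([th1, th2])
        if classify_call(t, lo).state == "filtered":
            assert classify_call(t, hi).state == "filtered"


class TestCallTable:
    def test_single_row(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("read_id\tstrand\tsite_pos\tp_c\tp_m\tp_h\nr1\t+\t12\t1.0\t0.0\t0.0\n")
        reads = read_call_table(p)
        assert len(reads) == 1
        assert reads[0].read_id == "r1" and reads[0].strand == "+"
        assert reads[0].calls[12].p_c == 1.0

    def test_bad_sum_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("read_id\tstrand\tsite_pos\tp_c\tp_m\tp_h\nr1\t+\t12\t0.5\t0.6\t0.2\n")
        with pytest.raises(ValueError, match="sum"):
            read_call_table(p)

    def test_header_only(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("read_id\tstrand\tsite_pos\tp_c\tp_m\tp_h\n")
        assert read_call_table(p) == []

    def test_unknown_strand(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("read_id\tstrand\tsite_pos\tp_c\tp_m\tp_h\nr1\t*\t12\t1\t0\t0\n")
        with pytest.raises(ValueError, match="strand"):
            read_call_table(p)

    def test_comments_skipped(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(
            "# generated\nread_id\tstrand\tsite_pos\tp_c\tp_m\tp_h\n"
            "r1\t-\t3\t0.1\t0.8\t0.1\n"
        )
        assert len(read_call_table(p)) == 1

    def test_round_trip(self, tmp_path):
        reads = [
            ReadModCalls("r1", "+", {1: triple(0.2, 0.7, 0.1), 5: triple(1.0, 0.0, 0.0)}),
            ReadModCalls("r2", "-", {1: triple(1 / 3, 1 / 3, 1 / 3)}),
        ]
        p = tmp_path / "c.tsv"
        write_call_table(reads, p)
        back = read_call_table(p)
        assert [r.read_id for r in back] == ["r1", "r2"]
        for orig, rt in zip(reads, back):
            assert orig.strand == rt.strand
            for pos in orig.calls:
                for a, b in zip(orig.calls[pos].as_tuple(), rt.calls[pos].as_tuple()):
                    assert a == pytest.approx(b, abs=1e-8)


class TestPileup:
    REF = AmpliconSequence("ref", "ACGTACGTTTCGA")  # CpG sites at 1, 5, 10

    def make_reads(self, per_site):
        reads = []
        for i, (strand, pos, t) in enumerate(per_site):
            reads.append(ReadModCalls(f"r{i}", strand, {pos: t}))
        return reads

    def test_all_canonical(self):
        idx = find_cpg_sites(self.REF)
        reads = self.make_reads([("+", 1, triple(1.0, 0.0, 0.0))] * 10)
        pile = pileup(reads, idx, 0.65)
        row = pile.row(1, "+")
        assert row.n_canonical == 10 and row.frac_5mC == 0.0

    def test_mixed_fraction(self):
        idx = find_cpg_sites(self.REF)
        reads = self.make_reads(
            [("+", 1, triple(0.1, 0.9, 0.0))] * 4 + [("+", 1, triple(0.9, 0.1, 0.0))] * 6
        )
        pile = pileup(reads, idx, 0.65)
        assert pile.row(1, "+").frac_5mC == pytest.approx(0.4)

    def test_conservation_with_filtered(self):
        idx = find_cpg_sites(self.REF)
        reads = self.make_reads(
            [("-", 5, triple(0.5, 0.3, 0.2))] * 3 + [("-", 5, triple(0.9, 0.05, 0.05))] * 4
        )
        pile = pileup(reads, idx, 0.65)
        row = pile.row(5, "-")
        assert row.n_filtered == 3
        assert row.n_canonical + row.n_5mC + row.n_5hmC + row.n_filtered == row.coverage_total

    def test_unknown_site_rejected(self):
        idx = find_cpg_sites(self.REF)
        reads = self.make_reads([("+", 2, triple(1.0, 0.0, 0.0))])
        with pytest.raises(KeyError):
            pileup(reads, idx, 0.65)

    def test_brute_force_tally_oracle(self):
        # random small instances vs an independent per-read tally
        rng = np.random.default_rng(42)
        idx = find_cpg_sites(self.REF)
        sites = list(idx.positions)
        for _ in range(20):
            reads = []
            expected = {}
            for i in range(int(rng.integers(1, 21))):
                strand = "+" if rng.random() < 0.5 else "-"
                calls = {}
                for pos in sites:
                    if rng.random() < 0.7:
                        raw = rng.dirichlet([1.0, 1.0, 1.0])
                        t = ModProbTriple(
                            float(raw[0]), float(raw[1]), 1.0 - float(raw[0]) - float(raw[1])
                        )
                        calls[pos] = t
                        key = (pos, strand)
                        cell = expected.setdefault(
                            key, {"canonical": 0, "5mC": 0, "5hmC": 0, "filtered": 0}
                        )
                        probs = t.as_tuple()
                        best = max(range(3), key=lambda k: (probs[k], -k))
                        state = ("canonical", "5mC", "5hmC")[best]
                        if probs[best] < 0.65:
                            state = "filtered"
                        cell[state] += 1
                if calls:
                    reads.append(ReadModCalls(f"r{i}", strand, calls))
            if not reads:
                continue
            pile = pileup(reads, idx, 0.65)
            assert set(pile.rows) == set(expected)
            for key, cell in expected.items():
                row = pile.rows[key]
                assert row.n_canonical == cell["canonical"]
                assert row.n_5mC == cell["5mC"]
                assert row.n_5hmC == cell["5hmC"]
                assert row.n_filtered == cell["filtered"]
                assert row.coverage_total == sum(cell.values())


class TestSiteAccuracy:
    def reads_at(self, triples, site=1, strand="+"):
        return [ReadModCalls(f"r{i}", strand, {site: t}) for i, t in enumerate(triples)]

    def test_certain_canonical_is_100(self):
        reads = self.reads_at([triple(1.0, 0.0, 0.0)] * 5)
        assert site_accuracy(reads, 1, "+") == pytest.approx(100.0)

    def test_uniform_is_0(self):
        reads = self.reads_at([ModProbTriple(1 / 3, 1 / 3, 1 / 3)] * 7)
        assert site_accuracy(reads, 1, "+") == pytest.approx(0.0, abs=1e-9)

    def test_linear_midpoint(self):
        reads = self.reads_at([triple(2 / 3, 1 / 6, 1 / 6)] * 3)
        assert site_accuracy(reads, 1, "+") == pytest.approx(50.0)

    def test_negative_not_clamped(self):
        reads = self.reads_at([triple(0.0, 0.5, 0.5)] * 2)
        assert site_accuracy(reads, 1, "+") == pytest.approx(-50.0)

    def test_zero_coverage_error(self):
        reads = self.reads_at([triple(1.0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="coverage"):
            site_accuracy(reads, 1, "-")

    def test_permutation_invariant(self):
        ts = [triple(0.9, 0.05, 0.05), triple(0.5, 0.25, 0.25), triple(0.2, 0.4, 0.4)]
        fwd = site_accuracy(self.reads_at(ts), 1, "+")
        rev = site_accuracy(self.reads_at(ts[::-1]), 1, "+")
        assert fwd == pytest.approx(rev)

    @given(st.lists(prob_triples(), min_size=1, max_size=10))
    @settings(max_examples=50)
    def test_affine_in_mean_pc(self, triples):
        reads = self.reads_at(triples)
        mean_pc = sum(t.p_c for t in triples) / len(triples)
        expected = 100.0 * (mean_pc - 1 / 3) / (2 / 3)
        assert site_accuracy(reads, 1, "+") == pytest.approx(expected)


class TestGlobalLevels:
    def test_all_canonical(self):
        idx = find_cpg_sites(TestPileup.REF)
        reads = [ReadModCalls("r", "+", {1: triple(1.0, 0.0, 0.0)})]
        pile = pileup(reads, idx, 0.65)
        assert global_modification_levels(pile) == (0.0, 0.0)

    def test_all_5mc(self):
        idx = find_cpg_sites(TestPileup.REF)
        reads = [ReadModCalls("r", "+", {1: triple(0.0, 1.0, 0.0)})]
        pile = pileup(reads, idx, 0.65)
        assert global_modification_levels(pile) == (1.0, 0.0)

    def test_half_half(self):
        idx = find_cpg_sites(TestPileup.REF)
        reads = [
            ReadModCalls(f"m{i}", "+", {1: triple(0.0, 1.0, 0.0)}) for i in range(50)
        ] + [
            ReadModCalls(f"c{i}", "+", {1: triple(1.0, 0.0, 0.0)}) for i in range(50)
        ]
        pile = pileup(reads, idx, 0.65)
        assert global_modification_levels(pile) == (0.5, 0.0)

    def test_no_retained_calls(self):
        idx = find_cpg_sites(TestPileup.REF)
        reads = [ReadModCalls("r", "+", {1: ModProbTriple(1 / 3, 1 / 3, 1 / 3)})]
        pile = pileup(reads, idx, 0.65)
        with pytest.raises(ValueError, match="retained"):
            global_modification_levels(pile)


class TestBedMethyl:
    def test_empty_pileup(self, tmp_path):
        idx = find_cpg_sites(TestPileup.REF)
        pile = pileup([], idx, 0.65, "ref")
        path = tmp_path / "out.tsv"
        write_bedmethyl(pile, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1  # header only

    def test_round_trip_counts(self, tmp_path, amplicon, cpg_index):
        truth, noise = gm.preset_truth("dnmt3a")
        labels = {p: "non-PQS" for p in cpg_index.positions}
        reads = gm.simulate_reads(amplicon, cpg_index, labels, truth, noise, 20, seed=3)
        pile = pileup(reads, cpg_index, 0.65, amplicon.id)
        path = tmp_path / "out.tsv"
        write_bedmethyl(pile, path)
        back = read_bedmethyl(path)
        assert set(back) == set(pile.rows)
        for key, row in pile.rows.items():
            assert back[key]["coverage_total"] == row.coverage_total
            assert back[key]["n_5mC"] == row.n_5mC
            assert back[key]["n_filtered"] == row.n_filtered
            assert back[key]["chrom"] == amplicon.id

    def test_strand_column_convention(self, tmp_path):
        idx = find_cpg_sites(TestPileup.REF)
        reads = [
            ReadModCalls("f", "+", {1: triple(1.0, 0.0, 0.0)}),
            ReadModCalls("r", "-", {1: triple(0.0, 1.0, 0.0)}),
        ]
        pile = pileup(reads, idx, 0.65, "ref")
        path = tmp_path / "out.tsv"
        write_bedmethyl(pile, path)
        strands = [line.split("\t")[4] for line in path.read_text().splitlines()[1:]]
        assert strands == ["+", "-"]


class TestModBam:
    REF_NAME = "ref"
    REF_SEQ = "ACGTTACGT"  # CpG sites at 1 and 6

    def _write_sam(self, path, records):
        import pysam

        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "unknown"},
                "SQ": [{"SN": self.REF_NAME, "LN": len(self.REF_SEQ)}],
            }
        )
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for rec in records:
                out.write(rec)
        return path

    def _aligned(self, name, seq, flag, mm, ml):
        import pysam

        a = pysam.AlignedSegment(
            pysam.AlignmentHeader.from_dict(
                {
                    "HD": {"VN": "1.6"},
                    "SQ": [{"SN": self.REF_NAME, "LN": len(self.REF_SEQ)}],
                }
            )
        )
        a.query_name = name
        a.query_sequence = seq
        a.flag = flag
        a.reference_id = 0
        a.reference_start = 0
        a.mapping_quality = 60
        a.cigarstring = f"{len(seq)}M"
        a.set_tag("MM", mm)
        a.set_tag("ML", ml)
        return a

    @property
    def amplicon(self):
        return AmpliconSequence("ref", self.REF_SEQ)

    def test_forward_read_decoding(self, tmp_path):
        import array

        # two C's in CpG context at query/ref 1 and 6
        rec = self._aligned(
            "fwd1", self.REF_SEQ, 0, "C+m,0,0;C+h,0,0;",
            array.array("B", [255, 0, 0, 0]),
        )
        sam = self._write_sam(tmp_path / "f.sam", [rec])
        from g4methyl.pileup import read_modbam

        reads = read_modbam(sam, self.amplicon)
        assert len(reads) == 1
        read = reads[0]
        assert read.strand == "+"
        assert set(read.calls) == {1, 6}
        assert read.calls[1].p_m == pytest.approx((255 + 0.5) / 256)
        assert classify_call(read.calls[1], 0.65).state == "5mC"
        assert read.calls[6].p_m == pytest.approx(0.5 / 256)

    def test_reverse_read_maps_to_paired_site(self, tmp_path):
        import array

        # reverse alignment: stored SEQ equals the reference, original read is
        # its revcomp with C's (original coords 1 and 6) opposite ref G's 7, 2
        rec = self._aligned(
            "rev1", self.REF_SEQ, 16, "C+m,0,0;C+h,0,0;",
            array.array("B", [200, 10, 0, 0]),
        )
        sam = self._write_sam(tmp_path / "r.sam", [rec])
        from g4methyl.pileup import read_modbam

        reads = read_modbam(sam, self.amplicon)
        assert len(reads) == 1
        read = reads[0]
        assert read.strand == "-"
        # ref G at 7 pairs with coding C at 6; ref G at 2 with coding C at 1
        assert set(read.calls) == {1, 6}

    def test_missing_tags_rejected(self, tmp_path):
        import pysam

        a = self._aligned("x", self.REF_SEQ, 0, "C+m,0,0;", None)
        a.set_tag("MM", None)
        a.set_tag("ML", None)
        sam = self._write_sam(tmp_path / "m.sam", [a])
        from g4methyl.pileup import read_modbam

        with pytest.raises(ValueError, match="MM/ML"):
            read_modbam(sam, self.amplicon)

    def test_unaligned_read_skipped(self, tmp_path):
        import array

        good = self._aligned(
            "ok", self.REF_SEQ, 0, "C+m,0,0;C+h,0,0;", array.array("B", [255, 0, 0, 0])
        )
        bad = self._aligned(
            "un", self.REF_SEQ, 4, "C+m,0,0;C+h,0,0;", array.array("B", [255, 0, 0, 0])
        )
        sam = self._write_sam(tmp_path / "u.sam", [good, bad])
        from g4methyl.pileup import read_modbam

        reads = read_modbam(sam, self.amplicon)
        assert [r.read_id for r in reads] == ["ok"]

    def test_ml_byte_round_trip(self):
        from g4methyl.pileup import _decode_ml, _encode_ml

        for byte in range(256):
            prob = _decode_ml(byte)
            assert _encode_ml(prob) == byte
            assert abs(_decode_ml(_encode_ml(prob)) - prob) < 1 / 256
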