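"""Candidate parsing, filtering, and read-pair/window retrieval."""

import warnings

import pysam
import pytest
from hypothesis import given, settings, strategies as st

from svrescore.candidates import (
    CandidateParseError,
    CandidateSV,
    GenomicLocus,
    ReadEnd,
    ReadPair,
    ZeroSupportWarning,
    extract_supporting_pairs,
    fetch_window,
    filter_candidates,
    parse_candidates,
    write_candidates,
)


def _pair(name="p", nm1=0, nm2=0, seq="ACGT"):
    return ReadPair(
        name=name,
        read1=ReadEnd(seq=seq, qual="I" * len(seq), nm=nm1),
        read2=ReadEnd(seq=seq, qual="I" * len(seq), nm=nm2),
    )


class TestParse:
    def test_deletion_signature_breakpoints_at_inner_edges(self, tmp_path):
        p = tmp_path / "c.bedpe"
        p.write_text("chr1\t100\t200\tchr1\t5100\t5200\tcand1\t.\t+\t-\n")
        (cand,) = parse_candidates(p)
        assert cand.id == "cand1"
        assert cand.side5 == GenomicLocus("chr1", 200, "+")
        assert cand.side3 == GenomicLocus("chr1", 5100, "-")
        assert cand.event_class == "deletion"

    def test_empty_file_yields_empty_list(self, tmp_path):
        p = tmp_path / "c.bedpe"
        p.write_text("")
        assert parse_candidates(p) == []

    def test_short_record_errors_with_line_number(self, tmp_path):
        p = tmp_path / "c.bedpe"
        p.write_text("chr1\t100\t200\tchr1\t5100\n")
        with pytest.raises(CandidateParseError, match="line 1"):
            parse_candidates(p)

    def test_unknown_dialect_is_a_configuration_error(self, tmp_path):
        p = tmp_path / "c.bedpe"
        p.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            parse_candidates(p, dialect="vcfish")

    def test_event_classification_by_strand_signature(self, tmp_path):
        p = tmp_path / "c.bedpe"
        p.write_text(
            "chr1\t100\t200\tchr1\t5100\t5200\tinv\t.\t+\t+\n"
            "chr1\t100\t200\tchr2\t5100\t5200\ttra\t.\t+\t-\n"
        )
        inv, tra = parse_candidates(p)
        assert inv.event_class == "inversion"
        assert tra.event_class == "translocation"


@st.composite
def candidates(draw):
    contig5 = draw(st.sampled_from(["chr1", "chr2"]))
    contig3 = draw(st.sampled_from(["chr1", "chr2"]))
    pos5 = draw(st.integers(1, 10_000))
    pos3 = draw(st.integers(1, 10_000))
    s5 = draw(st.sampled_from("+-"))
    s3 = draw(st.sampled_from("+-"))
    side5 = GenomicLocus(contig5, pos5, s5)
    side3 = GenomicLocus(contig3, pos3, s3)
    from svrescore.candidates import _classify

    score = draw(st.one_of(st.none(), st.integers(0, 500).map(float)))
    return CandidateSV(
        id=draw(st.uuids().map(lambda u: f"c{u.hex[:8]}")),
        side5=side5,
        side3=side3,
        event_class=_classify(side5, side3),
        caller_score=score,
    )


class TestRoundTrip:
    @settings(max_examples=50, derandomize=True)
    @given(st.lists(candidates(), max_size=8, unique_by=lambda c: c.id))
    def test_bedpe_write_parse_roundtrip(self, cands):
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".bedpe", delete=False) as fh:
            path = fh.name
        write_candidates(cands, path)
        parsed = parse_candidates(path)
        assert len(parsed) == len(cands)
        for a, b in zip(cands, parsed):
            assert (a.id, a.side5, a.side3, a.event_class, a.caller_score) == (
                b.id, b.side5, b.side3, b.event_class, b.caller_score
            )


class TestFilters:
    def test_five_pairs_low_edit_distance_retained(self):
        c = CandidateSV("c", GenomicLocus("chr1", 10, "+"), GenomicLocus("chr1", 99, "-"),
                        "deletion", support_pairs=[_pair(f"p{i}", 1, 1) for i in range(5)])
        assert filter_candidates([c]) == [c]

    def test_four_pairs_removed(self):
        c = CandidateSV("c", GenomicLocus("chr1", 10, "+"), GenomicLocus("chr1", 99, "-"),
                        "deletion", support_pairs=[_pair(f"p{i}") for i in range(4)])
        assert filter_candidates([c]) == []

    def test_mean_edit_distance_boundary_is_strict(self):
        # 10 reads with total NM 26 -> mean exactly 2.6 -> removed
        nms = [(3, 3), (3, 3), (3, 3), (2, 2), (2, 2)]
        c = CandidateSV("c", GenomicLocus("chr1", 10, "+"), GenomicLocus("chr1", 99, "-"),
                        "deletion",
                        support_pairs=[_pair(f"p{i}", a, b) for i, (a, b) in enumerate(nms)])
        assert c.mean_edit_distance() == pytest.approx(2.6)
        assert filter_candidates([c]) == []
        # strictly below the threshold passes
        assert filter_candidates([c], max_mean_edit_distance=2.61) == [c]

    def test_target_overlap_filter(self):
        c = CandidateSV("c", GenomicLocus("chr1", 10, "+"), GenomicLocus("chr1", 99, "-"),
                        "deletion", support_pairs=[_pair(f"p{i}") for i in range(5)])
        assert filter_candidates([c], targets=[("chr1", 90, 120)]) == [c]
        assert filter_candidates([c], targets=[("chr2", 0, 1000)]) == []

    def test_raising_pair_support_is_monotone(self):
        cands = [
            CandidateSV(f"c{n}", GenomicLocus("chr1", 10, "+"),
                        GenomicLocus("chr1", 99, "-"), "deletion",
                        support_pairs=[_pair(f"p{i}") for i in range(n)])
            for n in range(8)
        ]
        previous = None
        for threshold in range(10):
            kept = {c.id for c in filter_candidates(cands, pair_support=threshold,
                                                    max_mean_edit_distance=None)}
            if previous is not None:
                assert kept <= previous
            previous = kept


def _write_bam(path, records, contig="chr1", length=3000):
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": contig, "LN": length}]}
    records = sorted(records, key=lambda r: r[1])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for name, pos, flagset in records:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.query_sequence = "ACGTACGTAC"
            a.cigar = [(0, 10)]
            a.is_paired = True
            for attr in flagset:
                setattr(a, attr, True)
            bam.write(a)
    pysam.index(str(path))


class TestExtraction:
    @pytest.fixture
    def candidate(self):
        return CandidateSV("c", GenomicLocus("chr1", 200, "+"),
                           GenomicLocus("chr1", 2000, "-"), "deletion")

    def test_one_read_per_window_included_one_sided_excluded(self, tmp_path, candidate):
        bam = tmp_path / "r.bam"
        _write_bam(bam, [
            ("spanning", 210, ["is_read1"]),
            ("spanning", 1980, ["is_read2", "is_reverse"]),
            ("onesided", 190, ["is_read1"]),
            ("onesided", 260, ["is_read2", "is_reverse"]),
        ])
        pairs = extract_supporting_pairs(bam, candidate, pad=500)
        assert [p.name for p in pairs] == ["spanning"]

    def test_secondary_alignments_deduplicated_by_name(self, tmp_path, candidate):
        bam = tmp_path / "r.bam"
        _write_bam(bam, [
            ("dup", 210, ["is_read1"]),
            ("dup", 250, ["is_read1", "is_secondary"]),
            ("dup", 1980, ["is_read2", "is_reverse"]),
            ("dup", 2040, ["is_read2", "is_reverse", "is_secondary"]),
        ])
        pairs = extract_supporting_pairs(bam, candidate, pad=500)
        assert len(pairs) == 1
        assert pairs[0].name == "dup"

    def test_reverse_records_reported_in_sequencing_orientation(self, tmp_path, candidate):
        bam = tmp_path / "r.bam"
        _write_bam(bam, [
            ("s", 210, ["is_read1"]),
            ("s", 1980, ["is_read2", "is_reverse"]),
        ])
        (pair,) = extract_supporting_pairs(bam, candidate, pad=500)
        assert pair.read1.seq == "ACGTACGTAC"
        assert pair.read2.seq == "GTACGTACGT"  # revcomp of the stored record

    def test_zero_pairs_warns(self, tmp_path, candidate):
        bam = tmp_path / "r.bam"
        _write_bam(bam, [("far", 2900, ["is_read1"])])
        with pytest.warns(ZeroSupportWarning):
            assert extract_supporting_pairs(bam, candidate, pad=100) == []

    def test_unknown_contig_errors(self, tmp_path):
        bam = tmp_path / "r.bam"
        _write_bam(bam, [("x", 100, ["is_read1"])])
        cand = CandidateSV("c", GenomicLocus("chrMISSING", 200, "+"),
                           GenomicLocus("chr1", 2000, "-"))
        with pytest.raises(ValueError, match="chrMISSING"):
            extract_supporting_pairs(bam, cand, pad=100)


class TestFetchWindow:
    GENOME = {"c": "ACGTACGT"}

    def test_direct_slice(self):
        w = fetch_window(self.GENOME, GenomicLocus("c", 4, "+"), left=2, right=2)
        assert w.seq == "GTAC"
        assert (w.clamp_left, w.clamp_right) == (0, 0)

    def test_clamped_at_contig_start(self):
        w = fetch_window(self.GENOME, GenomicLocus("c", 1, "+"), left=5, right=2)
        assert w.seq == "ACG"
        assert w.clamp_left == 4

    def test_unknown_contig(self):
        with pytest.raises(KeyError, match="nope"):
            fetch_window(self.GENOME, GenomicLocus("nope", 1, "+"), left=1, right=1)
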