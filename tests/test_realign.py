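"""Alignment kernel: oracle equivalence, traceback ops, tallying rules."""

import numpy as np
import pytest

from oracle import local_alignment_score
from svrescore._seq import revcomp
from svrescore.candidates import ReadEnd, ReadPair
from svrescore.errors import ErrorProfile
from svrescore.realign import (
    ReadAlignment,
    Op,
    SWParams,
    align_triple,
    derive_sw_params,
    smith_waterman,
    sw_params_from_rates,
    tally,
)
from svrescore.references import JunctionReference, ReferenceTriple

GENTLE = SWParams(1.0, -1.0, -2.0, -0.5)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestParams:
    def test_rates_out_of_range_error(self):
        with pytest.raises(ValueError):
            sw_params_from_rates(0.75, 0.001)
        with pytest.raises(ValueError):
            sw_params_from_rates(0.01, 0.0)

    def test_log_odds_construction(self):
        p = sw_params_from_rates(0.01, 0.001)
        assert p.match_score == 1.0
        assert p.mismatch_score == pytest.approx(-3.137, abs=1e-3)
        assert p.gap_extend == pytest.approx(p.gap_open / 4)

    def test_identical_profile_means_give_identical_params(self):
        a = ErrorProfile(np.full(10, 0.01), np.full(10, 0.001), 100, 1e-6)
        b = ErrorProfile(np.linspace(0.005, 0.015, 10), np.full(10, 0.001), 100, 1e-6)
        assert derive_sw_params(a) == derive_sw_params(b)


class TestSmithWaterman:
    def test_identity_alignment(self):
        a = smith_waterman("ACGT", "ACGT", GENTLE)
        assert a.score == 4 * GENTLE.match_score
        assert [op.kind for op in a.ops] == ["match"] * 4

    def test_single_mismatch_in_traceback(self):
        # mild mismatch penalty so the substitution beats clipping around it
        a = smith_waterman("ACGT", "AGGT", SWParams(1.0, -0.5, -2.0, -0.5))
        mismatches = [op for op in a.ops if op.kind == "mismatch"]
        assert len(mismatches) == 1
        assert mismatches[0].read_pos == 1

    def test_clips_emitted_for_unaligned_ends(self):
        a = smith_waterman("TTACGTACGTTT", "GGACGTACGTGG", SWParams())
        kinds = [op.kind for op in a.ops]
        assert kinds[:2] == ["clip", "clip"] and kinds[-2:] == ["clip", "clip"]
        assert kinds[2:-2] == ["match"] * 8

    def test_n_bases_never_match(self):
        a = smith_waterman("ACNT", "ACNT", GENTLE)
        assert all(op.kind != "match" or "N" not in "ACNT"[op.read_pos] for op in a.ops)
        assert a.score < 4 * GENTLE.match_score

    @pytest.mark.parametrize("params", [GENTLE, sw_params_from_rates(0.01, 0.001)])
    def test_score_matches_bruteforce_dp_oracle(self, params):
        rng = np.random.default_rng(42)
        for _ in range(250):
            read = _random_seq(rng, int(rng.integers(1, 13)))
            ref = _random_seq(rng, int(rng.integers(1, 13)))
            got = smith_waterman(read, ref, params).score
            want = local_alignment_score(
                read, ref, params.match_score, params.mismatch_score,
                params.gap_open, params.gap_extend,
            )
            assert got == pytest.approx(want, abs=1e-9), (read, ref)

    def test_score_matches_biopython_aligner(self):
        Align = pytest.importorskip("Bio.Align")
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = GENTLE.match_score
        aligner.mismatch_score = GENTLE.mismatch_score
        aligner.open_gap_score = GENTLE.gap_open
        aligner.extend_gap_score = GENTLE.gap_extend
        rng = np.random.default_rng(7)
        for _ in range(50):
            read = _random_seq(rng, int(rng.integers(4, 16)))
            ref = _random_seq(rng, int(rng.integers(4, 30)))
            assert smith_waterman(read, ref, GENTLE).score == pytest.approx(
                aligner.score(ref, read)
            )

    def test_deterministic_traceback(self):
        a1 = smith_waterman("ACGTAC", "ACGTACGTAC", GENTLE)
        a2 = smith_waterman("ACGTAC", "ACGTACGTAC", GENTLE)
        assert a1.ops == a2.ops
        # among equal-scoring end cells, the smallest (ref_end, read_end) wins
        assert a1.ref_end == 6


def _perfect_alignment(name, which, ref_start, length=100, is_reverse=False):
    return ReadAlignment(
        read_name=name, which_read=which,
        ref_start=ref_start, ref_end=ref_start + length,
        ops=[Op("match", p, ref_start + p) for p in range(length)],
        score=float(length), is_reverse=is_reverse, read_length=length,
    )


class TestTally:
    def test_perfect_alignments(self):
        t = tally([_perfect_alignment(f"r{i}", 1, 0) for i in range(10)])
        assert np.all(t.l == 10)
        assert not t.mm.any() and not t.ind.any()

    def test_multibase_deletion_counts_once_at_opening_position(self):
        a = _perfect_alignment("r", 1, 0)
        a.ops = (
            [Op("match", p, p) for p in range(40)]
            + [Op("deletion", 40, 40 + k) for k in range(3)]
            + [Op("match", p, p + 3) for p in range(40, 100)]
        )
        t = tally([a])
        assert t.ind[40] == 1 and t.ind[41] == 0
        assert t.mm.sum() == 0

    def test_clips_count_as_mismatches(self):
        a = _perfect_alignment("r", 1, 0)
        a.ops = [Op("clip", 0, -1), Op("clip", 1, -1)] + [
            Op("match", p, p) for p in range(2, 100)
        ]
        a.ref_start, a.ref_end = 2, 100
        t = tally([a])
        assert t.mm[0] == 1 and t.mm[1] == 1 and t.mm[2:].sum() == 0

    def test_reverse_alignment_maps_positions_to_cycles(self):
        a = _perfect_alignment("r", 1, 0, is_reverse=True)
        a.ops[5] = Op("mismatch", 5, 5)  # alignment position 5 = cycle 94
        t = tally([a])
        assert t.mm[94] == 1 and t.mm.sum() == 1

    def test_split_read_over_junction_has_no_errors(self, flat_profile):
        rng = np.random.default_rng(3)
        left = _random_seq(rng, 200)
        right = _random_seq(rng, 200)
        refs = ReferenceTriple(
            sv=JunctionReference(left + right, 200, ()),
            contig5=left + _random_seq(rng, 200),
            contig3=_random_seq(rng, 200) + right,
        )
        read1 = (left + right)[150:250]  # crosses the junction
        read2 = revcomp((left + right)[260:360])
        pair = ReadPair("p", ReadEnd(read1, "I" * 100), ReadEnd(read2, "I" * 100))
        triple = align_triple([pair], refs, GENTLE)
        sv_r1 = next(a for a in triple.sv if a.which_read == 1)
        assert sv_r1.crosses_junction
        t = tally([sv_r1])
        assert t.mm.sum() == 0 and t.ind.sum() == 0


class TestAlignTriple:
    def _refs_identical(self, seq):
        return ReferenceTriple(
            sv=JunctionReference(seq, len(seq) // 2, ()), contig5=seq, contig3=seq
        )

    def test_identical_references_give_identical_alignments(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 300)
        pair = ReadPair("p", ReadEnd(seq[20:120], "I" * 100),
                        ReadEnd(revcomp(seq[150:250]), "I" * 100))
        triple = align_triple([pair], self._refs_identical(seq), GENTLE)
        for a_sv, a_c5, a_c3 in zip(triple.sv, triple.c5, triple.c3):
            assert a_sv.score == a_c5.score == a_c3.score
            assert a_sv.ops == a_c5.ops == a_c3.ops

    def test_tallies_invariant_under_pair_permutation(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 400)
        pairs = [
            ReadPair(f"p{i}", ReadEnd(seq[i * 10 : i * 10 + 80], "I" * 80),
                     ReadEnd(revcomp(seq[i * 10 + 150 : i * 10 + 230]), "I" * 80))
            for i in range(6)
        ]
        refs = self._refs_identical(seq)
        t1 = tally(align_triple(pairs, refs, GENTLE).sv)
        t2 = tally(align_triple(pairs[::-1], refs, GENTLE).sv)
        assert np.array_equal(t1.l, t2.l)
        assert np.array_equal(t1.mm, t2.mm)
        assert np.array_equal(t1.ind, t2.ind)

    def test_mismatch_conservation(self):
        rng = np.random.default_rng(2)
        seq = _random_seq(rng, 300)
        read = list(seq[50:150])
        read[10] = "ACGT"[("ACGT".index(read[10]) + 1) % 4]
        pair = ReadPair("p", ReadEnd("".join(read), "I" * 100),
                        ReadEnd(revcomp(seq[180:280]), "I" * 100))
        triple = align_triple([pair], self._refs_identical(seq), sw_params_from_rates(0.01, 0.001))
        for _, alignments in triple.items():
            t = tally(alignments)
            total_ops = sum(
                1 for a in alignments for op in a.ops if op.kind in ("mismatch", "clip")
            )
            assert t.mm.sum() == total_ops

    def test_fast_mode_elides_ops_but_preserves_tallies(self):
        rng = np.random.default_rng(5)
        seq = _random_seq(rng, 300)
        read = list(seq[50:150])
        read[40] = "ACGT"[("ACGT".index(read[40]) + 2) % 4]
        pairs = [
            ReadPair("clean", ReadEnd(seq[20:120], "I" * 100),
                     ReadEnd(revcomp(seq[150:250]), "I" * 100)),
            ReadPair("dirty", ReadEnd("".join(read), "I" * 100),
                     ReadEnd(revcomp(seq[160:260]), "I" * 100)),
        ]
        refs = self._refs_identical(seq)
        full = align_triple(pairs, refs, GENTLE, mode="full")
        fast = align_triple(pairs, refs, GENTLE, mode="fast")
        for (name, a_full), (_, a_fast) in zip(full.items(), fast.items()):
            tf, tq = tally(a_full), tally(a_fast)
            assert np.array_equal(tf.mm, tq.mm)
            assert np.array_equal(tf.ind, tq.ind)
            assert [a.score for a in a_full] == [a.score for a in a_fast]
        assert any(not a.detail for a in fast.sv)  # clean read elided
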