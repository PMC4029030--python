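"""Position-specific (per-cycle) sequencing-error profile estimation.

Illumina error rates rise along the read (phasing errors accumulate with
cycle number), so the scoring model uses a separate binomial distribution
per read position.  The rates are estimated empirically per experiment:
concordant (properly paired) read-pairs are sampled from the alignment
file, realigned end-to-end to their mapped reference windows, and the
per-cycle mismatch and indel-event frequencies become the profile.  SNPs
are not separated from sequencing errors; both count as mismatches.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pysam

from ._seq import revcomp
from .candidates import ReadEnd, ReadPair, GenomicLocus, fetch_window
from .realign import SWParams, smith_waterman, tally

__all__ = ["ErrorProfile", "sample_concordant_pairs", "estimate_error_profile"]

_RATE_CAP = 0.5 - 1e-9


@dataclass
class ErrorProfile:
    """Per-cycle mismatch and indel rates.

    Rates are floored at ``floor = 1 / (2 * n_reads_sampled)``: an exactly
    zero rate would assign probability zero (infinite log-penalty) to any
    observed error at that cycle.
    """

    mismatch_rate: np.ndarray
    indel_rate: np.ndarray
    n_reads_sampled: int
    floor: float

    def __post_init__(self):
        self.mismatch_rate = np.asarray(self.mismatch_rate, dtype=float)
        self.indel_rate = np.asarray(self.indel_rate, dtype=float)
        if self.mismatch_rate.shape != self.indel_rate.shape:
            raise ValueError("rate vectors must have equal length")
        for v in (self.mismatch_rate, self.indel_rate):
            if np.any(v < self.floor - 1e-15) or np.any(v >= 0.5):
                raise ValueError("rates must lie in [floor, 0.5)")

    def __len__(self):
        return len(self.mismatch_rate)

    def to_tsv(self, path, bam_path: str = "") -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_reads_sampled={self.n_reads_sampled}\n")
            fh.write(f"# floor={self.floor!r}\n")
            fh.write(f"# bam={bam_path}\n")
            fh.write("position\tmismatch_rate\tindel_rate\n")
            for p, (m, i) in enumerate(zip(self.mismatch_rate, self.indel_rate)):
                fh.write(f"{p}\t{float(m)!r}\t{float(i)!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "ErrorProfile":
        n_reads, floor = 0, 0.0
        mm, ind = [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    if key.strip() == "n_reads_sampled":
                        n_reads = int(val)
                    elif key.strip() == "floor":
                        floor = float(val)
                    continue
                if line.startswith("position"):
                    continue
                _, m, i = line.split("\t")
                mm.append(float(m))
                ind.append(float(i))
        return cls(np.array(mm), np.array(ind), n_reads, floor)


def _qualstring(rec: pysam.AlignedSegment) -> str:
    if rec.query_qualities is None:
        return "I" * len(rec.query_sequence)
    return pysam.qualities_to_qualitystring(rec.query_qualities)


def _record_to_end(rec: pysam.AlignedSegment) -> ReadEnd:
    seq, qual = rec.query_sequence, _qualstring(rec)
    if rec.is_reverse:
        seq, qual = revcomp(seq), qual[::-1]
    return ReadEnd(
        seq=seq, qual=qual, contig=rec.reference_name,
        pos=rec.reference_start, is_reverse=rec.is_reverse,
        nm=rec.get_tag("NM") if rec.has_tag("NM") else None,
    )


def sample_concordant_pairs(bam_path, n: int = 100_000, seed: int = 0) -> list[ReadPair]:
    """Seeded uniform reservoir sample of concordant read-pairs.

    Concordant means: both mates mapped on the same contig, proper-pair
    flag set, and absolute insert size within mean ± 3 SD of the
    proper-pair insert distribution.  Returns fewer than ``n`` pairs (with
    a warning) when the file does not contain enough.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    # Pass 1: insert-size distribution of proper pairs.
    tlens = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for rec in bam.fetch():
            if rec.is_proper_pair and rec.is_read1 and not rec.is_secondary \
                    and not rec.is_supplementary and rec.template_length > 0:
                tlens.append(rec.template_length)
    if not tlens:
        raise ValueError(f"no concordant read-pairs in {bam_path}")
    mean = statistics.fmean(tlens)
    sd = statistics.pstdev(tlens) if len(tlens) > 1 else 0.0
    lo, hi = mean - 3 * sd, mean + 3 * sd
    # Pass 2: reservoir-sample qualifying pairs, matching mates by name.
    reservoir: list[ReadPair] = []
    seen = 0
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for rec in bam.fetch():
            if (not rec.is_proper_pair or rec.is_secondary or rec.is_supplementary
                    or rec.mate_is_unmapped or rec.reference_id != rec.next_reference_id):
                continue
            if not lo <= abs(rec.template_length) <= hi:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            r1, r2 = (mate, rec) if mate.is_read1 else (rec, mate)
            pair = ReadPair(
                name=r1.query_name,
                read1=_record_to_end(r1), read2=_record_to_end(r2),
                is_concordant=True,
            )
            seen += 1
            if len(reservoir) < n:
                reservoir.append(pair)
            else:
                k = int(rng.integers(0, seen))
                if k < n:
                    reservoir[k] = pair
    if not reservoir:
        raise ValueError(f"no concordant read-pairs in {bam_path}")
    if seen < n:
        warnings.warn(
            f"requested {n} concordant pairs but only {seen} available", UserWarning
        )
    return reservoir


_DEFAULT_PARAMS = SWParams(1.0, -3.0, -5.0, -1.25)


def estimate_error_profile(
    pairs: Sequence[ReadPair],
    genome,
    params: Optional[SWParams] = None,
    pad: int = 25,
) -> ErrorProfile:
    """Estimate per-cycle mismatch/indel rates from concordant pairs.

    Each read is realigned end-to-end (``fit`` mode) to the reference
    window around its recorded mapping coordinates — stored CIGARs are not
    trusted.  ``mismatch_rate[p]`` is the mismatch count at cycle ``p``
    divided by the number of reads covering ``p``; indel rates count gap
    openings.  Rates are floored at ``1/(2·n_reads)`` and capped just below
    0.5.
    """
    if not pairs:
        raise ValueError("estimate_error_profile requires at least one pair")
    params = params or _DEFAULT_PARAMS
    alignments = []
    for pair in pairs:
        for end in (pair.read1, pair.read2):
            if end.contig is None or end.pos is None:
                raise ValueError("reads must carry mapping coordinates")
            win = fetch_window(
                genome,
                GenomicLocus(end.contig, max(0, end.pos), "+"),
                left=pad,
                right=len(end.seq) + pad,
            )
            oriented = revcomp(end.seq) if end.is_reverse else end.seq
            aln = smith_waterman(oriented, win.seq, params, mode="fit")
            aln.is_reverse = end.is_reverse
            alignments.append(aln)
    t = tally(alignments)
    n_reads = len(alignments)
    floor = 1.0 / (2.0 * n_reads)
    with np.errstate(invalid="ignore", divide="ignore"):
        mm = np.where(t.l > 0, t.mm / np.maximum(t.l, 1), 0.0)
        ind = np.where(t.l > 0, t.ind / np.maximum(t.l, 1), 0.0)
    mm = np.clip(mm, floor, _RATE_CAP)
    ind = np.clip(ind, floor, _RATE_CAP)
    return ErrorProfile(mm, ind, n_reads_sampled=n_reads, floor=floor)
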