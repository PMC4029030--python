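"""Candidate SV lists: parsing, support filters, and read-pair retrieval.

Discordant-pair SV callers emit putative rearrangements as pairs of genomic
intervals with strands (BEDPE).  This module turns those records into
:class:`CandidateSV` objects, applies the support filters (minimum read-pair
support, mean edit distance, optional target-interval overlap) and pulls the
supporting read-pairs and reference windows needed for realignment.

Coordinate conventions
----------------------
BEDPE intervals are 0-based half-open; internal breakpoint positions are
0-based.  The breakpoint of each BEDPE interval is its *inner* edge — the
edge facing the junction — selected by strand: ``+`` means the junction
continues to the right of the reads, so the breakpoint is the interval end;
``-`` means it continues to the left, so the breakpoint is the interval
start.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import pysam

from ._seq import revcomp

__all__ = [
    "GenomicLocus",
    "CandidateSV",
    "ReadEnd",
    "ReadPair",
    "Window",
    "CandidateParseError",
    "ZeroSupportWarning",
    "parse_candidates",
    "write_candidates",
    "filter_candidates",
    "extract_supporting_pairs",
    "fetch_window",
    "estimate_insert_stats",
]


class CandidateParseError(ValueError):
    """Malformed candidate record; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ZeroSupportWarning(UserWarning):
    """Raised (as a warning) when no supporting pairs are found."""


@dataclass(frozen=True)
class GenomicLocus:
    """One side of a candidate junction.

    ``orientation`` is the strand the caller reports for that breakpoint
    side: '+' (forward) or '-' (reverse).
    """

    contig: str
    position: int  # 0-based
    orientation: str  # '+' or '-'

    def __post_init__(self):
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")


@dataclass(frozen=True)
class ReadEnd:
    """One read of a pair: sequence in original sequencing orientation."""

    seq: str
    qual: str
    contig: Optional[str] = None
    pos: Optional[int] = None  # 0-based leftmost mapping coordinate
    is_reverse: bool = False
    nm: Optional[int] = None  # edit distance of the original alignment


@dataclass(frozen=True)
class ReadPair:
    name: str
    read1: ReadEnd
    read2: ReadEnd
    is_concordant: bool = False

    def __post_init__(self):
        for end in (self.read1, self.read2):
            if len(end.seq) < 1:
                raise ValueError("read sequences must be non-empty")
            if set(end.seq.upper()) - set("ACGTN"):
                raise ValueError(f"read sequence contains non-ACGTN characters: {end.seq!r}")


@dataclass
class CandidateSV:
    """A putative rearrangement: two breakpoint loci plus an event class."""

    id: str
    side5: GenomicLocus
    side3: GenomicLocus
    event_class: str = "generic"  # deletion | inversion | translocation | generic
    support_pairs: list = field(default_factory=list)  # list[ReadPair]
    caller_score: Optional[float] = None

    def __post_init__(self):
        if self.event_class == "deletion":
            if self.side5.contig != self.side3.contig:
                raise ValueError(f"{self.id}: deletion breakpoints must share a contig")
            if not self.side5.position < self.side3.position:
                raise ValueError(f"{self.id}: deletion requires side5.position < side3.position")

    @property
    def n_support(self) -> int:
        return len(self.support_pairs)

    def mean_edit_distance(self) -> Optional[float]:
        """Mean per-read edit distance (NM) over supporting reads.

        Returns None when no supporting read carries an NM value.
        """
        nms = [
            end.nm
            for pair in self.support_pairs
            for end in (pair.read1, pair.read2)
            if end.nm is not None
        ]
        return statistics.fmean(nms) if nms else None


def _classify(side5: GenomicLocus, side3: GenomicLocus) -> str:
    if side5.contig != side3.contig:
        return "translocation"
    s5, s3 = side5.orientation, side3.orientation
    if s5 == s3:
        return "inversion"
    if s5 == "+" and s3 == "-" and side5.position < side3.position:
        return "deletion"
    return "generic"


def _inner_edge(start: int, end: int, strand: str) -> int:
    # '+' faces the partner to the right -> breakpoint at interval end;
    # '-' faces left -> breakpoint at interval start.
    return end if strand == "+" else start


def parse_candidates(path, dialect: str = "bedpe") -> list[CandidateSV]:
    """Parse a candidate SV list.

    Dialects: ``bedpe`` (10+ columns, as emitted by HYDRA-style callers;
    ``hydra`` is an alias), or ``generic-tsv`` with columns
    ``id chrom5 pos5 strand5 chrom3 pos3 strand3 [class]``.
    """
    if dialect not in ("bedpe", "hydra", "generic-tsv"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    out: list[CandidateSV] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated toy files
                fields = line.split()
            if dialect in ("bedpe", "hydra"):
                cand = _parse_bedpe_record(fields, ln)
            else:
                cand = _parse_generic_record(fields, ln)
            if cand.id in seen_ids:
                raise CandidateParseError(f"duplicate candidate id {cand.id!r}", ln)
            seen_ids.add(cand.id)
            out.append(cand)
    return out


def _parse_bedpe_record(fields: Sequence[str], ln: int) -> CandidateSV:
    if len(fields) < 10:
        raise CandidateParseError(
            f"BEDPE record needs >= 10 columns, got {len(fields)}", ln
        )
    try:
        c1, s1, e1, c2, s2, e2, name, score, st1, st2 = fields[:10]
        s1, e1, s2, e2 = int(s1), int(e1), int(s2), int(e2)
    except ValueError as exc:
        raise CandidateParseError(f"bad BEDPE coordinates ({exc})", ln) from None
    if st1 not in "+-" or st2 not in "+-":
        raise CandidateParseError(f"bad strands {st1!r}/{st2!r}", ln)
    side5 = GenomicLocus(c1, _inner_edge(s1, e1, st1), st1)
    side3 = GenomicLocus(c2, _inner_edge(s2, e2, st2), st2)
    caller_score = None
    if score not in (".", ""):
        try:
            caller_score = float(score)
        except ValueError:
            pass  # HYDRA puts non-numeric values here
    try:
        return CandidateSV(
            id=name, side5=side5, side3=side3,
            event_class=_classify(side5, side3), caller_score=caller_score,
        )
    except ValueError as exc:
        raise CandidateParseError(str(exc), ln) from None


def _parse_generic_record(fields: Sequence[str], ln: int) -> CandidateSV:
    if len(fields) < 7:
        raise CandidateParseError(
            f"generic-tsv record needs >= 7 columns, got {len(fields)}", ln
        )
    try:
        name, c5, p5, st5, c3, p3, st3 = fields[:7]
        side5 = GenomicLocus(c5, int(p5), st5)
        side3 = GenomicLocus(c3, int(p3), st3)
    except ValueError as exc:
        raise CandidateParseError(str(exc), ln) from None
    cls = fields[7] if len(fields) > 7 else _classify(side5, side3)
    try:
        return CandidateSV(id=name, side5=side5, side3=side3, event_class=cls)
    except ValueError as exc:
        raise CandidateParseError(str(exc), ln) from None


def write_candidates(candidates: Iterable[CandidateSV], path) -> None:
    """Write candidates as 10-column BEDPE (round-trips with parse_candidates).

    Each breakpoint becomes a 1 bp interval whose inner edge equals the
    stored position under the strand convention above.
    """
    with open(path, "w") as fh:
        for c in candidates:
            iv = []
            for locus in (c.side5, c.side3):
                if locus.orientation == "+":
                    iv.append((locus.position - 1, locus.position))
                else:
                    iv.append((locus.position, locus.position + 1))
            score = "." if c.caller_score is None else f"{c.caller_score:g}"
            fh.write(
                f"{c.side5.contig}\t{iv[0][0]}\t{iv[0][1]}"
                f"\t{c.side3.contig}\t{iv[1][0]}\t{iv[1][1]}"
                f"\t{c.id}\t{score}\t{c.side5.orientation}\t{c.side3.orientation}\n"
            )


def write_candidate_table(candidates: Iterable[CandidateSV], path) -> None:
    """Normalized candidate table (TSV with header)."""
    with open(path, "w") as fh:
        fh.write("id\tchrom5\tpos5\tstrand5\tchrom3\tpos3\tstrand3\tclass\tn_pairs\n")
        for c in candidates:
            fh.write(
                f"{c.id}\t{c.side5.contig}\t{c.side5.position}\t{c.side5.orientation}"
                f"\t{c.side3.contig}\t{c.side3.position}\t{c.side3.orientation}"
                f"\t{c.event_class}\t{c.n_support}\n"
            )


def filter_candidates(
    candidates: Iterable[CandidateSV],
    pair_support: Optional[int] = 5,
    max_mean_edit_distance: Optional[float] = 2.6,
    targets: Optional[Sequence[tuple[str, int, int]]] = None,
) -> list[CandidateSV]:
    """Apply the standard candidate filters.

    A candidate is retained when it (i) has at least ``pair_support``
    supporting read-pairs, (ii) has mean per-read edit distance strictly
    below ``max_mean_edit_distance``, and (iii) has at least one breakpoint
    inside a target interval when ``targets`` is given.  Pass ``None`` for
    any threshold to disable that filter.  Candidates without edit-distance
    information pass filter (ii) vacuously.
    """
    kept = []
    for c in candidates:
        if pair_support is not None and c.n_support < pair_support:
            continue
        if max_mean_edit_distance is not None:
            med = c.mean_edit_distance()
            if med is not None and not med < max_mean_edit_distance:
                continue
        if targets is not None and not _hits_targets(c, targets):
            continue
        kept.append(c)
    return kept


def _hits_targets(c: CandidateSV, targets) -> bool:
    for contig, start, end in targets:
        for locus in (c.side5, c.side3):
            if locus.contig == contig and start <= locus.position < end:
                return True
    return False


def estimate_insert_stats(bam_path, max_pairs: int = 100_000) -> tuple[float, float]:
    """Mean and SD of the absolute template length over proper pairs."""
    tlens = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for rec in bam.fetch():
            if rec.is_proper_pair and rec.is_read1 and not rec.is_secondary and rec.template_length > 0:
                tlens.append(rec.template_length)
                if len(tlens) >= max_pairs:
                    break
    if not tlens:
        raise ValueError(f"no proper pairs in {bam_path}")
    mean = statistics.fmean(tlens)
    sd = statistics.pstdev(tlens) if len(tlens) > 1 else 0.0
    return mean, sd


def default_pad(bam_path) -> int:
    """Default extraction window half-width: insert mean + 3 SD."""
    mean, sd = estimate_insert_stats(bam_path)
    return int(round(mean + 3 * sd))


def _record_to_end(rec: pysam.AlignedSegment) -> ReadEnd:
    seq = rec.query_sequence
    qual = rec.qual or "I" * len(seq)
    if rec.is_reverse:
        seq = revcomp(seq)
        qual = qual[::-1]
    nm = rec.get_tag("NM") if rec.has_tag("NM") else None
    return ReadEnd(
        seq=seq, qual=qual, contig=rec.reference_name,
        pos=rec.reference_start, is_reverse=rec.is_reverse, nm=nm,
    )


def extract_supporting_pairs(bam, candidate: CandidateSV, pad: int) -> list[ReadPair]:
    """Fetch read-pairs with one read mapping near each breakpoint.

    Scans ``[position - pad, position + pad]`` around each breakpoint;
    secondary alignments count for locating pairs, but sequences are taken
    from records that carry them (primaries).  Output is de-duplicated by
    read name and reported in original sequencing orientation.
    """
    if pad <= 0:
        raise ValueError("pad must be > 0")
    own_handle = isinstance(bam, (str,)) or hasattr(bam, "__fspath__")
    bamfile = pysam.AlignmentFile(str(bam)) if own_handle else bam
    try:
        contigs = set(bamfile.references)
        for locus in (candidate.side5, candidate.side3):
            if locus.contig not in contigs:
                raise ValueError(f"contig {locus.contig!r} absent from BAM header")
        windows = []
        for locus in (candidate.side5, candidate.side3):
            start = max(0, locus.position - pad)
            windows.append((locus.contig, start, locus.position + pad))
        # name -> {1: [records in w5, records in w3], 2: ...}
        hits: dict[str, dict[int, list[set]]] = {}
        seqs: dict[tuple[str, int], pysam.AlignedSegment] = {}
        for widx, (contig, start, end) in enumerate(windows):
            for rec in bamfile.fetch(contig, start, end):
                if rec.is_unmapped or rec.query_name is None:
                    continue
                which = 1 if rec.is_read1 else 2
                hits.setdefault(rec.query_name, {1: set(), 2: set()})[which].add(widx)
                if rec.query_sequence and (rec.query_name, which) not in seqs:
                    seqs[(rec.query_name, which)] = rec
                elif rec.query_sequence and not rec.is_secondary:
                    seqs[(rec.query_name, which)] = rec
        pairs = []
        for name in sorted(hits):
            w = hits[name]
            spans = (0 in w[1] and 1 in w[2]) or (1 in w[1] and 0 in w[2])
            if not spans:
                continue
            r1 = seqs.get((name, 1))
            r2 = seqs.get((name, 2))
            if r1 is None or r2 is None:
                continue  # mate's sequence not present in either window
            pairs.append(
                ReadPair(
                    name=name,
                    read1=_record_to_end(r1),
                    read2=_record_to_end(r2),
                    is_concordant=r1.is_proper_pair,
                )
            )
        if not pairs:
            warnings.warn(
                f"no supporting pairs found for candidate {candidate.id}",
                ZeroSupportWarning,
            )
        return pairs
    finally:
        if own_handle:
            bamfile.close()


class Window(NamedTuple):
    """A reference slice with clamping bookkeeping."""

    seq: str
    start: int
    end: int
    clamp_left: int
    clamp_right: int


def fetch_window(genome, locus: GenomicLocus, left: int, right: int) -> Window:
    """Upper-case reference window ``[position - left, position + right)``.

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping of contig name to
    sequence supporting ``len`` and slicing).  Windows are clamped at contig
    ends; the clamp amounts are reported in the returned :class:`Window`.
    """
    try:
        contig = genome[locus.contig]
    except KeyError:
        raise KeyError(f"contig {locus.contig!r} not found in genome") from None
    clen = len(contig)
    start = locus.position - left
    end = locus.position + right
    clamp_left = max(0, -start)
    clamp_right = max(0, end - clen)
    start = max(0, start)
    end = min(clen, end)
    seq = str(contig[start:end]).upper()
    return Window(seq=seq, start=start, end=end, clamp_left=clamp_left, clamp_right=clamp_right)
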