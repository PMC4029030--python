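"""Synthetic benchmark generator.

Builds everything the rescoring pipeline consumes, from a seed alone: a
random genome carrying a diverged segmental duplication, a donor haplotype
with implanted deletions, Illumina-like paired-end reads with
cycle-dependent mismatch/indel rates and Gaussian insert sizes, a minimal
coordinate-sorted BAM, a BEDPE of candidates, and a truth table.

Two kinds of candidates are emitted:

* ``true_sv`` — the implanted deletions, with their exact breakpoints;
* ``decoy`` — the classic repeat artifact: a deletion-signature junction
  joining homologous positions of the two duplication copies.  Read-pairs
  whose fragments span the decoy point inside the *source* copy have their
  second mate deliberately relocated to the homologous coordinate of the
  other copy, emulating the cross-copy mismapping that makes discordant
  callers report such junctions.

Reads are placed at their true source coordinates with a flat ``<len>M``
CIGAR (the rescorer distrusts CIGARs anyway); proper-pair flags mark
concordant fragments.  Everything is reproducible byte-for-byte from the
seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pysam

from ._seq import revcomp
from .candidates import CandidateSV, GenomicLocus, write_candidates

__all__ = [
    "SegDup",
    "SimConfig",
    "TruthRecord",
    "SimPair",
    "ReadSet",
    "simulate_genome",
    "simulate_read_pairs",
    "make_benchmark",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SegDup:
    """A segmental duplication: ``copy`` is a mutated copy of ``source``."""

    source: int = 20_000
    copy: int = 120_000
    length: int = 2_000
    identity: float = 0.95

    def __post_init__(self):
        if not 0.5 < self.identity <= 1.0:
            raise ValueError("identity must be in (0.5, 1]")


def _default_mismatch_profile(read_length: int) -> np.ndarray:
    # Illumina-like ramp: error rate grows with cycle number.
    return np.linspace(0.001, 0.01, read_length)


@dataclass
class SimConfig:
    """Benchmark study conditions.

    Defaults describe the canonical setup at ``genome_length=200_000``:
    one 2 kb duplication at 95% identity (source at 20 kb, copy at 120 kb),
    three implanted deletions (60-63 kb, 80-83.5 kb, 100-103 kb) and three
    decoy junctions at offsets 500/1000/1500 into the duplication; smaller
    genomes scale these placements proportionally.
    """

    seed: int
    genome_length: int = 200_000
    contig: str = "chr1"
    segdup: object = "auto"  # SegDup | None | "auto"
    deletions: Optional[list] = None  # list[(start, end)]; None -> 3 defaults
    decoy_offsets: Optional[list] = None  # offsets into the dup; None -> 3 defaults
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    coverage: float = 30.0
    mismatch_profile: Optional[np.ndarray] = None
    indel_profile: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.mismatch_profile is None:
            self.mismatch_profile = _default_mismatch_profile(self.read_length)
        if self.indel_profile is None:
            self.indel_profile = np.full(self.read_length, 1e-4)
        self.mismatch_profile = np.asarray(self.mismatch_profile, dtype=float)
        self.indel_profile = np.asarray(self.indel_profile, dtype=float)
        L = self.genome_length
        if self.segdup == "auto":
            self.segdup = SegDup(
                source=L // 10, copy=(6 * L) // 10, length=L // 100, identity=0.95
            )
        if self.deletions is None:
            self.deletions = [
                (int(0.30 * L), int(0.315 * L)),
                (int(0.40 * L), int(0.4175 * L)),
                (int(0.50 * L), int(0.515 * L)),
            ]
        if self.decoy_offsets is None:
            if self.segdup:
                d = self.segdup.length
                self.decoy_offsets = [d // 4, d // 2, (3 * d) // 4]
            else:
                self.decoy_offsets = []


@dataclass(frozen=True)
class TruthRecord:
    candidate: CandidateSV
    label: str  # 'true_sv' | 'decoy'
    provenance: str = ""


def simulate_genome(cfg: SimConfig) -> tuple[dict, list[TruthRecord]]:
    """Random genome with the configured duplication, plus labeled truth.

    Returns ``({contig: sequence}, truth)``.  The reference sequence does
    NOT contain the deletions — those live on the donor haplotype that
    reads are drawn from.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    codes = rng.integers(0, 4, cfg.genome_length)
    seq = _BASES[codes].copy()
    if cfg.segdup:
        d = cfg.segdup
        if d.source + d.length > cfg.genome_length or d.copy + d.length > cfg.genome_length:
            raise ValueError("segdup does not fit in the genome")
        segment = codes[d.source : d.source + d.length].copy()
        mutate = rng.random(d.length) < (1.0 - d.identity)
        segment[mutate] = (segment[mutate] + rng.integers(1, 4, int(mutate.sum()))) % 4
        seq[d.copy : d.copy + d.length] = _BASES[segment]
    genome = {cfg.contig: seq.tobytes().decode("ascii")}
    truth: list[TruthRecord] = []
    for k, (start, end) in enumerate(cfg.deletions, start=1):
        cand = CandidateSV(
            id=f"del{k}",
            side5=GenomicLocus(cfg.contig, start, "+"),
            side3=GenomicLocus(cfg.contig, end, "-"),
            event_class="deletion",
        )
        truth.append(TruthRecord(cand, "true_sv", f"implanted deletion {start}-{end}"))
    if cfg.segdup:
        d = cfg.segdup
        for k, off in enumerate(cfg.decoy_offsets, start=1):
            if not 0 < off < d.length:
                raise ValueError(f"decoy offset {off} outside the duplication")
            cand = CandidateSV(
                id=f"decoy{k}",
                side5=GenomicLocus(cfg.contig, d.source + off, "+"),
                side3=GenomicLocus(cfg.contig, d.copy + off, "-"),
                event_class="deletion",
            )
            truth.append(
                TruthRecord(cand, "decoy", f"segdup copies at {d.source}/{d.copy}")
            )
    return genome, truth


@dataclass
class SimPair:
    name: str
    seq1: str  # sequencing orientation (forward strand)
    seq2: str  # sequencing orientation (reverse strand)
    pos1: int  # 0-based leftmost reference coordinate
    pos2: int
    nm1: int
    nm2: int
    proper: bool


@dataclass
class ReadSet:
    contig: str
    contig_length: int
    read_length: int
    pairs: list

    def write_fastq(self, prefix) -> tuple[str, str]:
        p1, p2 = f"{prefix}_1.fastq", f"{prefix}_2.fastq"
        qual = "I" * self.read_length
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for pr in self.pairs:
                f1.write(f"@{pr.name}/1\n{pr.seq1}\n+\n{qual}\n")
                f2.write(f"@{pr.name}/2\n{pr.seq2}\n+\n{qual}\n")
        return p1, p2

    def write_bam(self, path) -> str:
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": self.contig, "LN": self.contig_length}],
        }
        rl = self.read_length
        records = []
        for pr in self.pairs:
            records.append((pr.pos1, pr.name, 1, pr))
            records.append((pr.pos2, pr.name, 2, pr))
        records.sort(key=lambda r: (r[0], r[1], r[2]))
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for pos, name, which, pr in records:
                a = pysam.AlignedSegment(bam.header)
                a.query_name = name
                a.reference_id = 0
                a.mapping_quality = 60
                a.cigar = [(0, rl)]
                a.is_paired = True
                a.is_proper_pair = pr.proper
                if which == 1:
                    a.is_read1 = True
                    a.reference_start = pr.pos1
                    a.next_reference_start = pr.pos2
                    a.is_reverse = False
                    a.mate_is_reverse = True
                    a.query_sequence = pr.seq1
                    a.template_length = (pr.pos2 + rl) - pr.pos1
                    a.set_tag("NM", pr.nm1)
                else:
                    a.is_read2 = True
                    a.reference_start = pr.pos2
                    a.next_reference_start = pr.pos1
                    a.is_reverse = True
                    a.mate_is_reverse = False
                    a.query_sequence = revcomp(pr.seq2)
                    a.template_length = -((pr.pos2 + rl) - pr.pos1)
                    a.set_tag("NM", pr.nm2)
                a.next_reference_id = 0
                a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                bam.write(a)
        pysam.index(str(path))
        return str(path)


def _hap_coordinate_map(genome_length: int, deletions: list):
    """Kept-segment tables mapping haplotype coords to reference coords."""
    deletions = sorted(deletions)
    seg_ref, seg_hap, lengths = [], [], []
    ref_cursor, hap_cursor = 0, 0
    for start, end in deletions:
        seg_ref.append(ref_cursor)
        seg_hap.append(hap_cursor)
        lengths.append(start - ref_cursor)
        hap_cursor += start - ref_cursor
        ref_cursor = end
    seg_ref.append(ref_cursor)
    seg_hap.append(hap_cursor)
    lengths.append(genome_length - ref_cursor)
    return np.array(seg_ref), np.array(seg_hap), np.array(lengths)


def _mutate_read(template: str, mm_mask, ind_mask, rng, read_length: int) -> tuple[str, int]:
    """Apply cycle-indexed substitutions and indels to a template walk."""
    out = []
    ti = 0
    nerr = 0
    for p in range(read_length):
        if ind_mask[p]:
            nerr += 1
            if rng.random() < 0.5:  # insertion: extra base, no template consumed
                out.append("ACGT"[rng.integers(4)])
                continue
            ti += 1  # deletion: skip one template base
        base = template[ti] if ti < len(template) else "ACGT"[rng.integers(4)]
        ti += 1
        if mm_mask[p]:
            base = "ACGT"[("ACGT".index(base) + int(rng.integers(1, 4))) % 4]
            nerr += 1
        out.append(base)
    return "".join(out), nerr


def simulate_read_pairs(cfg: SimConfig, genome: dict, truth: list) -> ReadSet:
    """Paired-end reads from the donor haplotype (reference minus deletions).

    Fragment lengths are Normal(insert_mean, insert_sd) truncated at the
    read length; per-cycle substitutions and indels follow the config's
    error vectors.  Pairs spanning a decoy point in the duplication source
    have their reverse mate relocated to the homologous copy coordinate.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    ref = genome[cfg.contig]
    L = len(ref)
    rl = cfg.read_length
    seg_ref, seg_hap, seg_len = _hap_coordinate_map(L, cfg.deletions)
    hap_parts = [ref[r : r + n] for r, n in zip(seg_ref, seg_len)]
    hap = "".join(hap_parts)

    def hap2ref(h: int) -> int:
        k = int(np.searchsorted(seg_hap, h, side="right")) - 1
        return int(seg_ref[k] + (h - seg_hap[k]))

    def segment_of(h: int) -> int:
        return int(np.searchsorted(seg_hap, h, side="right")) - 1

    n_pairs = int(round(cfg.coverage * len(hap) / (2.0 * rl)))
    if n_pairs < 1:
        raise ValueError("coverage too low to yield a single pair")
    inserts = np.clip(
        np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, n_pairs)), rl, None
    ).astype(int)
    starts = np.floor(rng.random(n_pairs) * (len(hap) - inserts)).astype(int)
    mm1 = rng.random((n_pairs, rl)) < cfg.mismatch_profile
    mm2 = rng.random((n_pairs, rl)) < cfg.mismatch_profile
    in1 = rng.random((n_pairs, rl)) < cfg.indel_profile
    in2 = rng.random((n_pairs, rl)) < cfg.indel_profile

    ref_bytes = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    slack = 8
    pairs: list[SimPair] = []
    width = len(str(n_pairs))
    for k in range(n_pairs):
        s, ins = int(starts[k]), int(inserts[k])
        e = s + ins
        t1 = hap[s : s + rl + slack]
        t2 = revcomp(hap[max(0, e - rl - slack) : e])
        seq1, _ = _mutate_read(t1, mm1[k], in1[k], rng, rl)
        seq2, _ = _mutate_read(t2, mm2[k], in2[k], rng, rl)
        pos1 = hap2ref(s)
        pos2 = hap2ref(e - rl)
        spans = segment_of(s) != segment_of(e - 1)
        proper = (not spans) and abs(
            ins - cfg.insert_mean
        ) <= 3 * cfg.insert_sd
        pairs.append(
            SimPair(
                name=f"frag{k:0{width}d}",
                seq1=seq1, seq2=seq2, pos1=pos1, pos2=pos2,
                nm1=0, nm2=0, proper=proper,
            )
        )

    # Decoy mismapping: relocate the reverse mate of fragments spanning a
    # decoy point inside the duplication source to the homologous copy
    # coordinate, as a multi-mapping-confused aligner would.
    if cfg.segdup:
        d = cfg.segdup
        shift = d.copy - d.source
        decoy_points = [d.source + off for off in cfg.decoy_offsets]
        for pr in pairs:
            if not pr.proper:
                continue
            for pa in decoy_points:
                if pr.pos1 + rl <= pa <= pr.pos2 and pr.pos2 + rl <= d.source + d.length:
                    pr.pos2 += shift
                    pr.proper = False
                    break

    # Honest NM tags: Hamming distance of each stored read against the
    # reference at its recorded mapping position (flat-M placement).
    for pr in pairs:
        fwd2 = revcomp(pr.seq2)
        pr.nm1 = int(
            np.sum(
                ref_bytes[pr.pos1 : pr.pos1 + rl]
                != np.frombuffer(pr.seq1.encode("ascii"), dtype=np.uint8)[: min(rl, L - pr.pos1)]
            )
        )
        pr.nm2 = int(
            np.sum(
                ref_bytes[pr.pos2 : pr.pos2 + rl]
                != np.frombuffer(fwd2.encode("ascii"), dtype=np.uint8)[: min(rl, L - pr.pos2)]
            )
        )
    return ReadSet(contig=cfg.contig, contig_length=L, read_length=rl, pairs=pairs)


@dataclass(frozen=True)
class BenchmarkPaths:
    fasta: str
    bam: str
    bedpe: str
    truth_tsv: str


def write_fasta(genome: dict, path) -> str:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    return str(path)


def make_benchmark(cfg: SimConfig, outdir) -> tuple[BenchmarkPaths, list[TruthRecord]]:
    """Self-contained input set for the scoring pipeline, with labeled truth."""
    os.makedirs(str(outdir), exist_ok=True)
    genome, truth = simulate_genome(cfg)
    reads = simulate_read_pairs(cfg, genome, truth)
    fasta = write_fasta(genome, os.path.join(str(outdir), "ref.fa"))
    bam = reads.write_bam(os.path.join(str(outdir), "reads.bam"))
    bedpe = os.path.join(str(outdir), "candidates.bedpe")
    write_candidates([t.candidate for t in truth], bedpe)
    truth_tsv = os.path.join(str(outdir), "truth.tsv")
    with open(truth_tsv, "w") as fh:
        fh.write("id\tlabel\tprovenance\n")
        for t in truth:
            fh.write(f"{t.candidate.id}\t{t.label}\t{t.provenance}\n")
    return BenchmarkPaths(fasta, bam, bedpe, truth_tsv), truth
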