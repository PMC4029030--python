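"""Smith–Waterman realignment and per-cycle error tallying.

Every supporting read is realigned to each of the three per-candidate
references with an affine-gap Gotoh dynamic program (match/mismatch scores
and gap open/extend penalties derived from the experiment's error rates as
log-odds).  Alignments are then tallied per *sequencing cycle*: ``l_p``
reads cover cycle ``p``, of which ``m_p`` disagree with the reference
(mismatches, plus locally-unaligned/clipped bases — see below) and ``i_p``
open an indel.  These tallies are the sufficient statistics of the binomial
scoring model.

Two alignment modes exist:

* ``local`` — classic Smith–Waterman; unaligned read ends are emitted as
  ``clip`` ops.  Clipped bases count as mismatches in the tally: a local
  aligner otherwise clips away exactly the disagreement that distinguishes
  the rearranged reference from the contiguous ones.
* ``fit`` — the read is aligned end-to-end against a locally-free
  reference (no clips).  Used for error-profile estimation, where the
  read's locus is known and unbiased per-cycle counts are needed.

A multi-base gap counts once in ``i_p``, at its opening read position.  The
junction inside a rearranged reference is a reference feature: reads cross
it freely and the crossing is never an indel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from numba import njit

from ._seq import encode, revcomp
from .candidates import ReadPair
from .references import ReferenceTriple

__all__ = [
    "SWParams",
    "Op",
    "ReadAlignment",
    "TripleAlignment",
    "AlignmentTally",
    "derive_sw_params",
    "sw_params_from_rates",
    "smith_waterman",
    "align_triple",
    "tally",
]


@dataclass(frozen=True)
class SWParams:
    """Affine-gap alignment scores.

    A gap of length ``k`` scores ``gap_open + (k - 1) * gap_extend``.
    """

    match_score: float = 1.0
    mismatch_score: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -1.25

    def __post_init__(self):
        if not self.match_score > 0:
            raise ValueError("match_score must be > 0")
        if not self.mismatch_score < 0:
            raise ValueError("mismatch_score must be < 0")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


def sw_params_from_rates(mean_mismatch_rate: float, mean_indel_rate: float) -> SWParams:
    """Log-odds alignment scores from mean per-base error rates.

    Scores are log2-odds of each event against the 0.25 background base
    probability, rescaled so that a match scores exactly +1:
    ``match = log2((1 - e_mm)/0.25)``, ``mismatch = log2((e_mm/3)/0.25)``,
    ``gap_open = log2(e_ind)``, ``gap_extend = gap_open / 4``.
    """
    for name, rate in (("mismatch", mean_mismatch_rate), ("indel", mean_indel_rate)):
        if not 0.0 < rate < 0.5:
            raise ValueError(f"mean {name} rate must be in (0, 0.5), got {rate}")
    match = math.log2((1.0 - mean_mismatch_rate) / 0.25)
    mismatch = math.log2((mean_mismatch_rate / 3.0) / 0.25)
    gap_open = math.log2(mean_indel_rate)
    gap_extend = gap_open / 4.0
    scale = 1.0 / match
    return SWParams(1.0, mismatch * scale, gap_open * scale, gap_extend * scale)


def derive_sw_params(profile) -> SWParams:
    """Alignment scores from an :class:`~svrescore.errors.ErrorProfile`."""
    return sw_params_from_rates(
        float(np.mean(profile.mismatch_rate)), float(np.mean(profile.indel_rate))
    )


class Op(NamedTuple):
    kind: str  # match | mismatch | insertion | deletion | clip
    read_pos: int  # position in alignment orientation; gaps: opening position
    ref_pos: int  # -1 for clip


@dataclass
class ReadAlignment:
    read_name: str
    which_read: int
    ref_start: int  # 0-based inclusive
    ref_end: int  # 0-based exclusive
    ops: list
    score: float
    crosses_junction: bool = False
    is_reverse: bool = False  # aligned as reverse-complement of sequencing orientation
    read_length: int = 0
    detail: bool = True  # False when ops were elided (fast mode, perfect read)


@dataclass
class TripleAlignment:
    """Alignments of one candidate's supporting reads to all three references."""

    candidate_id: str
    sv: list = field(default_factory=list)
    c5: list = field(default_factory=list)
    c3: list = field(default_factory=list)
    junction_offset: int = 0
    mode: str = "full"

    def items(self):
        return (("sv", self.sv), ("c5", self.c5), ("c3", self.c3))


@dataclass
class AlignmentTally:
    """Per-cycle coverage, mismatch and indel-event counts."""

    l: np.ndarray
    mm: np.ndarray
    ind: np.ndarray

    def __len__(self):
        return len(self.l)


_NEG = -1.0e30


@njit(cache=False)
def _gotoh_fill(x, y, match, mismatch, go, ge, local):  # pragma: no cover - jit
    n = x.shape[0]
    m = y.shape[0]
    H = np.zeros((n + 1, m + 1), np.float64)
    E = np.full((n + 1, m + 1), _NEG, np.float64)
    F = np.full((n + 1, m + 1), _NEG, np.float64)
    PH = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 left(E), 3 up(F)
    PE = np.zeros((n + 1, m + 1), np.uint8)  # 1 open, 2 extend
    PF = np.zeros((n + 1, m + 1), np.uint8)
    if not local:
        for i in range(1, n + 1):
            F[i, 0] = go + (i - 1) * ge
            H[i, 0] = F[i, 0]
            PH[i, 0] = 3
            PF[i, 0] = 1 if i == 1 else 2
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + go
            e_ext = E[i, j - 1] + ge
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 1
            else:
                E[i, j] = e_ext
                PE[i, j] = 2
            f_open = H[i - 1, j] + go
            f_ext = F[i - 1, j] + ge
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 1
            else:
                F[i, j] = f_ext
                PF[i, j] = 2
            s = match if (xi == y[j - 1] and xi < 4) else mismatch
            h = H[i - 1, j - 1] + s
            p = 1
            if F[i, j] > h:  # preference: diag > up > left
                h = F[i, j]
                p = 3
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if local and h < 0.0:
                h = 0.0
                p = 0
            H[i, j] = h
            PH[i, j] = p
    return H, E, F, PH, PE, PF


@njit(cache=False)
def _gotoh_score_local(x, y, match, mismatch, go, ge):  # pragma: no cover - jit
    """Score-only local DP: best score and its end cell (smallest (j, i))."""
    n = x.shape[0]
    m = y.shape[0]
    Hrow = np.zeros(m + 1, np.float64)
    Erow = np.full(m + 1, _NEG, np.float64)
    Fprev = np.full(m + 1, _NEG, np.float64)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        xi = x[i - 1]
        diag = Hrow[0]
        Hrow[0] = 0.0
        Erow[0] = _NEG
        for j in range(1, m + 1):
            e = max(Hrow[j - 1] + go, Erow[j - 1] + ge)
            f = max(Hrow[j] + go, Fprev[j] + ge)
            s = match if (xi == y[j - 1] and xi < 4) else mismatch
            h = diag + s
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0.0:
                h = 0.0
            diag = Hrow[j]
            Hrow[j] = h
            Erow[j] = e
            Fprev[j] = f
            if h > best or (h == best and (j < bj or (j == bj and i < bi))):
                best = h
                bi = i
                bj = j
    return best, bi, bj


def _best_cell(H, local: bool) -> tuple[float, int, int]:
    n = H.shape[0] - 1
    m = H.shape[1] - 1
    if local:
        best, bi, bj = 0.0, 0, 0
        # column-major scan -> first maximum has smallest (ref_end, read_end)
        for j in range(m + 1):
            col = H[:, j]
            i = int(np.argmax(col))
            if col[i] > best:
                best, bi, bj = float(col[i]), i, j
        return best, bi, bj
    row = H[n, :]
    bj = int(np.argmax(row))
    return float(row[bj]), n, bj


def _traceback(x, y, H, PH, PE, PF, bi, bj, local: bool) -> tuple[list, int, int]:
    """Walk pointers from (bi, bj); returns (aligned ops, read_start, ref_start)."""
    ops: list[Op] = []
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            if i == 0 or (local and (j == 0 or H[i, j] == 0.0)):
                break
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                kind = "match" if (x[i - 1] == y[j - 1] and x[i - 1] < 4) else "mismatch"
                ops.append(Op(kind, i - 1, j - 1))
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in read, consumes reference (deletion)
            ops.append(Op("deletion", i, j - 1))
            opener = PE[i, j] == 1
            j -= 1
            if opener:
                state = "H"
        else:  # state == "F": gap in reference, consumes read (insertion)
            ops.append(Op("insertion", i - 1, j))
            opener = PF[i, j] == 1
            i -= 1
            if opener:
                state = "H"
    ops.reverse()
    return ops, i, j


def smith_waterman(read: str, ref: str, params: SWParams, mode: str = "local") -> ReadAlignment:
    """Optimal affine-gap alignment of ``read`` against ``ref``.

    ``mode='local'`` is Smith–Waterman with unaligned read ends reported as
    ``clip`` ops; ``mode='fit'`` aligns the read end-to-end (free reference
    ends, no clips).  Traceback is deterministic: diagonal is preferred over
    an up-gap over a left-gap, and among equal-scoring end cells the one
    with the smallest ``(ref_end, read_end)`` is chosen.
    """
    if not read or not ref:
        raise ValueError("read and ref must be non-empty")
    if mode not in ("local", "fit"):
        raise ValueError(f"unknown mode {mode!r}")
    local = mode == "local"
    x = encode(read)
    y = encode(ref)
    H, E, F, PH, PE, PF = _gotoh_fill(
        x, y, params.match_score, params.mismatch_score,
        params.gap_open, params.gap_extend, local,
    )
    score, bi, bj = _best_cell(H, local)
    aligned_ops, read_start, ref_start = _traceback(x, y, H, PH, PE, PF, bi, bj, local)
    n = len(read)
    ops: list[Op] = []
    if local:
        ops.extend(Op("clip", p, -1) for p in range(read_start))
    ops.extend(aligned_ops)
    if local:
        ops.extend(Op("clip", p, -1) for p in range(bi, n))
    return ReadAlignment(
        read_name="", which_read=0,
        ref_start=ref_start, ref_end=bj,
        ops=ops, score=score, read_length=n,
    )


def _align_best_orientation(
    seq: str, ref_enc: np.ndarray, ref_str: str, params: SWParams, fast: bool
) -> ReadAlignment:
    """Align both orientations, keep the better (ties -> forward)."""
    n = len(seq)
    fwd = encode(seq)
    rev = encode(revcomp(seq))
    s_f = _gotoh_score_local(
        fwd, ref_enc, params.match_score, params.mismatch_score,
        params.gap_open, params.gap_extend,
    )
    s_r = _gotoh_score_local(
        rev, ref_enc, params.match_score, params.mismatch_score,
        params.gap_open, params.gap_extend,
    )
    is_reverse = s_r[0] > s_f[0]
    score, bi, bj = s_r if is_reverse else s_f
    # The perfect bound n * match_score is reachable only by an all-match
    # alignment (every other op scores strictly less than a match).
    perfect = abs(score - n * params.match_score) < 1e-9
    if fast and perfect:
        aln = ReadAlignment(
            read_name="", which_read=0,
            ref_start=bj - n, ref_end=bj,
            ops=[], score=score,
            is_reverse=is_reverse, read_length=n, detail=False,
        )
        return aln
    oriented = revcomp(seq) if is_reverse else seq
    aln = smith_waterman(oriented, ref_str, params, mode="local")
    aln.is_reverse = is_reverse
    return aln


def align_triple(
    pairs: Sequence[ReadPair],
    refs: ReferenceTriple,
    params: SWParams,
    mode: str = "full",
    candidate_id: str = "",
) -> TripleAlignment:
    """Realign every read of every supporting pair to all three references.

    Both read orientations are tried per reference (extraction reports
    sequencing orientation) and the better-scoring one kept, ties going to
    forward.  In ``fast`` mode, per-base op lists are elided for reads whose
    score reaches the perfect bound (their tally contribution is provably
    zero), so downstream scores are identical to ``full`` mode but plot data
    are not guaranteed.
    """
    if not pairs:
        raise ValueError("align_triple requires at least one read pair")
    if mode not in ("full", "fast"):
        raise ValueError(f"unknown mode {mode!r}")
    fast = mode == "fast"
    triple = TripleAlignment(
        candidate_id=candidate_id, junction_offset=refs.sv.junction_offset, mode=mode
    )
    targets = (
        ("sv", refs.sv.seq, triple.sv),
        ("c5", refs.contig5, triple.c5),
        ("c3", refs.contig3, triple.c3),
    )
    encoded = {name: encode(seq) for name, seq, _ in targets}
    for pair in pairs:
        for which, end in ((1, pair.read1), (2, pair.read2)):
            for name, ref_str, bucket in targets:
                aln = _align_best_orientation(end.seq, encoded[name], ref_str, params, fast)
                aln.read_name = pair.name
                aln.which_read = which
                if name == "sv":
                    jo = refs.sv.junction_offset
                    aln.crosses_junction = aln.ref_start < jo < aln.ref_end
                bucket.append(aln)
    return triple


def _cycle(p: int, read_length: int, is_reverse: bool) -> int:
    """Map an alignment-orientation read position to its sequencing cycle."""
    return read_length - 1 - p if is_reverse else p


def tally(alignments: Iterable[ReadAlignment], max_len: Optional[int] = None) -> AlignmentTally:
    """Per-cycle coverage / mismatch / indel-event counts for one configuration.

    Clipped read positions count as mismatches; a multi-base gap counts once
    at its opening read position.  Cycle coordinates refer to the original
    sequencing orientation of each read.
    """
    alignments = list(alignments)
    if max_len is None:
        max_len = max((a.read_length for a in alignments), default=0)
    l = np.zeros(max_len, dtype=np.int64)
    mm = np.zeros(max_len, dtype=np.int64)
    ind = np.zeros(max_len, dtype=np.int64)
    for a in alignments:
        l[: a.read_length] += 1
        if not a.detail:
            continue  # elided perfect alignment: zero contribution
        prev_kind = None
        for op in a.ops:
            if op.kind in ("mismatch", "clip"):
                mm[_cycle(op.read_pos, a.read_length, a.is_reverse)] += 1
            elif op.kind in ("insertion", "deletion"):
                if op.kind != prev_kind:  # gap opening
                    ind[_cycle(op.read_pos, a.read_length, a.is_reverse)] += 1
            prev_kind = op.kind
    return AlignmentTally(l=l, mm=mm, ind=ind)
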