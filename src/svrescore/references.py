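"""Per-candidate reference construction.

For each candidate junction three references are built: one *rearranged*
sequence that joins the two breakpoint-adjacent windows the way the SV
would, and two *contiguous* sequences, each simply the reference around one
breakpoint.  Reads from a real SV fit the rearranged sequence; reads from a
repeat-induced artifact fit one of the contiguous sequences.

Orientation handling
--------------------
Each side contributes the window adjacent to the junction, oriented so the
junction-facing base sits at the join:

* side5 ``+``  -> the ``flank`` bases ending at the breakpoint, as-is;
* side5 ``-``  -> the ``flank`` bases starting at the breakpoint,
  reverse-complemented (so the breakpoint base ends the left part);
* side3 ``-``  -> the ``flank`` bases starting at the breakpoint, as-is;
* side3 ``+``  -> the ``flank`` bases ending at the breakpoint,
  reverse-complemented.

The deletion signature (+,-) therefore joins as-is and the inversion
signatures ((+,+), (-,-)) reverse-complement one window, matching standard
discordant-pair geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp
from .candidates import CandidateSV, GenomicLocus, Window, fetch_window

__all__ = ["JunctionReference", "ReferenceTriple", "build_reference_triple"]


@dataclass(frozen=True)
class JunctionReference:
    """The rearranged (SV-supporting) reference sequence.

    ``junction_offset`` is the 0-based index of the first base originating
    from the 3'-side window.
    """

    seq: str
    junction_offset: int
    provenance: tuple  # (side5 Window, side3 Window, (op5, op3))

    def __post_init__(self):
        if not 0 < self.junction_offset < len(self.seq):
            raise ValueError(
                f"junction_offset {self.junction_offset} outside (0, {len(self.seq)})"
            )


@dataclass(frozen=True)
class ReferenceTriple:
    sv: JunctionReference
    contig5: str
    contig3: str
    contig5_start: int = 0  # genome coordinate of contig5[0]
    contig3_start: int = 0


def _side_window(genome, locus: GenomicLocus, flank: int, is_side5: bool) -> tuple[Window, str, str]:
    """Window adjacent to the junction for one side, junction-oriented.

    Returns (raw window, oriented sequence, op name).
    """
    # '+' side5 and '+' side3 both take the window *ending* at the
    # breakpoint; '-' takes the window starting at it.
    take_left = locus.orientation == "+"
    if take_left:
        win = fetch_window(genome, locus, left=flank, right=0)
    else:
        win = fetch_window(genome, locus, left=0, right=flank)
    need_revcomp = (is_side5 and not take_left) or (not is_side5 and take_left)
    seq = revcomp(win.seq) if need_revcomp else win.seq
    return win, seq, ("revcomp" if need_revcomp else "as-is")


def build_reference_triple(candidate: CandidateSV, genome, flank: int) -> ReferenceTriple:
    """Build the rearranged and the two contiguous references.

    ``flank`` should be at least the read length (and by default large
    enough that every supporting read fits entirely on one side).  Windows
    are clamped at contig ends; a fully empty side window is an error.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    w5, left_part, op5 = _side_window(genome, candidate.side5, flank, is_side5=True)
    w3, right_part, op3 = _side_window(genome, candidate.side3, flank, is_side5=False)
    if not left_part or not right_part:
        raise ValueError(
            f"{candidate.id}: zero-length breakpoint window "
            f"(side5 {len(left_part)} bp, side3 {len(right_part)} bp)"
        )
    sv = JunctionReference(
        seq=left_part + right_part,
        junction_offset=len(left_part),
        provenance=(w5, w3, (op5, op3)),
    )
    c5 = fetch_window(genome, candidate.side5, left=flank, right=flank)
    c3 = fetch_window(genome, candidate.side3, left=flank, right=flank)
    return ReferenceTriple(
        sv=sv,
        contig5=c5.seq,
        contig3=c3.seq,
        contig5_start=c5.start,
        contig3_start=c3.start,
    )


def write_reference_fasta(candidate_id: str, refs: ReferenceTriple, outdir) -> list[str]:
    """Dump the three references as FASTA for external inspection."""
    import os

    paths = []
    for tag, seq in (("sv", refs.sv.seq), ("c5", refs.contig5), ("c3", refs.contig3)):
        path = os.path.join(str(outdir), f"{candidate_id}.{tag}.fa")
        with open(path, "w") as fh:
            fh.write(f">{candidate_id}|{tag}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
        paths.append(path)
    return paths
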