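"""High-level wiring: candidates + BAM + FASTA + profile -> scores.

This is the library face of the ``score``/``view`` workflow: it extracts
supporting read-pairs, builds the per-candidate reference triple, realigns,
scores, and can persist/reload the realignments so that plotting does not
repeat the expensive step.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pyfaidx

from .candidates import (
    CandidateSV,
    GenomicLocus,
    ZeroSupportWarning,
    default_pad,
    estimate_insert_stats,
    extract_supporting_pairs,
    parse_candidates,
)
from .errors import ErrorProfile
from .realign import Op, ReadAlignment, SWParams, TripleAlignment, align_triple, derive_sw_params
from .references import JunctionReference, ReferenceTriple, build_reference_triple
from .scoring import ScoreResult, likelihood_score

log = logging.getLogger("svrescore")

__all__ = ["CandidateResult", "rescore", "save_run", "load_run"]


@dataclass
class CandidateResult:
    candidate: CandidateSV
    refs: ReferenceTriple
    triple: TripleAlignment
    result: ScoreResult


def rescore(
    candidates: Sequence[CandidateSV] | str,
    bam,
    fasta,
    profile: ErrorProfile,
    pad: Optional[int] = None,
    flank: Optional[int] = None,
    mode: str = "full",
    params: Optional[SWParams] = None,
    dialect: str = "bedpe",
) -> list[CandidateResult]:
    """Score every candidate; candidates without support are skipped.

    ``pad`` defaults to insert mean + 3 SD (estimated from the BAM);
    ``flank`` defaults to read length + pad, so any supporting read fits
    entirely on one side of the junction.
    """
    if isinstance(candidates, (str, bytes)) or hasattr(candidates, "__fspath__"):
        candidates = parse_candidates(candidates, dialect=dialect)
    genome = pyfaidx.Fasta(str(fasta)) if not hasattr(fasta, "keys") else fasta
    if pad is None:
        pad = default_pad(bam)
    if flank is None:
        flank = len(profile) + pad
    params = params or derive_sw_params(profile)
    log.info("scoring %d candidates (pad=%d, flank=%d)", len(candidates), pad, flank)
    out: list[CandidateResult] = []
    for cand in candidates:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ZeroSupportWarning)
            pairs = extract_supporting_pairs(bam, cand, pad=pad)
        if not pairs:
            log.warning("candidate %s: no supporting pairs, skipped", cand.id)
            continue
        cand.support_pairs = pairs
        refs = build_reference_triple(cand, genome, flank=flank)
        triple = align_triple(pairs, refs, params, mode=mode, candidate_id=cand.id)
        result = likelihood_score(triple, profile)
        log.info(
            "candidate %s: %d pairs, score %.1f", cand.id, result.n_pairs, result.score
        )
        out.append(CandidateResult(cand, refs, triple, result))
    return out


# ---------------------------------------------------------------------------
# Realignment cache (score -> view without re-aligning)

def _aln_to_dict(a: ReadAlignment) -> dict:
    return {
        "name": a.read_name, "which": a.which_read,
        "start": a.ref_start, "end": a.ref_end,
        "ops": [[o.kind, o.read_pos, o.ref_pos] for o in a.ops],
        "score": a.score, "cross": a.crosses_junction,
        "rev": a.is_reverse, "len": a.read_length, "detail": a.detail,
    }


def _aln_from_dict(d: dict) -> ReadAlignment:
    return ReadAlignment(
        read_name=d["name"], which_read=d["which"],
        ref_start=d["start"], ref_end=d["end"],
        ops=[Op(k, rp, fp) for k, rp, fp in d["ops"]],
        score=d["score"], crosses_junction=d["cross"],
        is_reverse=d["rev"], read_length=d["len"], detail=d["detail"],
    )


def save_run(results: Sequence[CandidateResult], path) -> None:
    payload = []
    for r in results:
        payload.append(
            {
                "id": r.candidate.id,
                "refs": {
                    "sv_seq": r.refs.sv.seq,
                    "junction_offset": r.refs.sv.junction_offset,
                    "contig5": r.refs.contig5,
                    "contig3": r.refs.contig3,
                    "contig5_start": r.refs.contig5_start,
                    "contig3_start": r.refs.contig3_start,
                },
                "mode": r.triple.mode,
                "alignments": {
                    name: [_aln_to_dict(a) for a in alns]
                    for name, alns in r.triple.items()
                },
                "score": {
                    "log_p_sv": r.result.log_p_sv,
                    "log_p_c5": r.result.log_p_c5,
                    "log_p_c3": r.result.log_p_c3,
                    "score": r.result.score,
                    "n_pairs": r.result.n_pairs,
                    "n_split_reads": r.result.n_split_reads,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_run(path) -> list[CandidateResult]:
    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for d in payload:
        jo = d["refs"]["junction_offset"]
        refs = ReferenceTriple(
            sv=JunctionReference(
                seq=d["refs"]["sv_seq"], junction_offset=jo, provenance=()
            ),
            contig5=d["refs"]["contig5"],
            contig3=d["refs"]["contig3"],
            contig5_start=d["refs"]["contig5_start"],
            contig3_start=d["refs"]["contig3_start"],
        )
        triple = TripleAlignment(
            candidate_id=d["id"],
            sv=[_aln_from_dict(a) for a in d["alignments"]["sv"]],
            c5=[_aln_from_dict(a) for a in d["alignments"]["c5"]],
            c3=[_aln_from_dict(a) for a in d["alignments"]["c3"]],
            junction_offset=jo,
            mode=d["mode"],
        )
        result = ScoreResult(candidate_id=d["id"], **d["score"])
        # breakpoint loci are not needed for plotting from cache
        cand = CandidateSV(
            id=d["id"],
            side5=GenomicLocus("cached", 0, "+"),
            side3=GenomicLocus("cached", 1, "-"),
        )
        out.append(CandidateResult(cand, refs, triple, result))
    return out
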