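"""Binomial likelihood scoring of the three alignment configurations.

For one configuration the probability that the sequencer generated the
observed errors is a product of independent binomials, one per read
position (cycle) ``p``: the mismatch count ``m_p`` among the ``l_p``
covering reads follows Binomial(l_p, err_mm(p)), and the indel-event count
``i_p`` follows Binomial(l_p, err_ind(p)).  The candidate's score is the
natural-log likelihood ratio

    L = log p_sv - max(log p_c5, log p_c3)

where ``p_sv`` is the probability under the rearranged reference and
``p_c5``/``p_c3`` under the two contiguous references; only the
better-fitting contiguous fragment is compared, since it is the more
plausible contiguous origin of the reads.  L > 0 favours the SV.

Natural logarithms are used throughout, and the recommended pass cutoff
(100 by default, 170 for target-capture experiments) is calibrated in
natural-log units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import ErrorProfile
from .realign import AlignmentTally, TripleAlignment, tally

__all__ = [
    "ScoreResult",
    "binomial_log_pmf",
    "configuration_log_prob",
    "likelihood_score",
    "classify",
    "write_scores_tsv",
    "DEFAULT_CUTOFF",
    "TARGET_CAPTURE_CUTOFF",
]

DEFAULT_CUTOFF = 100.0
TARGET_CAPTURE_CUTOFF = 170.0


@dataclass
class ScoreResult:
    candidate_id: str
    log_p_sv: float
    log_p_c5: float
    log_p_c3: float
    score: float
    n_pairs: int
    n_split_reads: int

    def __post_init__(self):
        expected = self.log_p_sv - max(self.log_p_c5, self.log_p_c3)
        if abs(self.score - expected) > 1e-6:
            raise ValueError("score must equal log_p_sv - max(log_p_c5, log_p_c3)")


def binomial_log_pmf(k, l, rate) -> float:
    """log P[Binomial(l, rate) = k], via log-gamma for stability.

    Accepts scalars or arrays (broadcast elementwise).
    """
    k = np.asarray(k)
    l = np.asarray(l)
    rate = np.asarray(rate, dtype=float)
    if np.any(k < 0) or np.any(k > l):
        raise ValueError("require 0 <= k <= l")
    if np.any(rate <= 0.0) or np.any(rate >= 1.0):
        raise ValueError("rate must be in (0, 1)")
    out = (
        gammaln(l + 1) - gammaln(k + 1) - gammaln(l - k + 1)
        + k * np.log(rate) + (l - k) * np.log1p(-rate)
    )
    return float(out) if out.ndim == 0 else out


def configuration_log_prob(t: AlignmentTally, profile: ErrorProfile) -> float:
    """Natural-log probability of one configuration's tally under the profile.

    Positions with zero coverage contribute log(1) = 0.  ``i_p`` is clamped
    to ``l_p`` (multiple gap openings of one read at one cycle collapse).
    """
    npos = len(t)
    if npos > len(profile):
        raise ValueError(
            f"tally covers {npos} positions but profile only {len(profile)}"
        )
    mask = t.l > 0
    if not np.any(mask):
        return 0.0
    l = t.l[mask]
    mm = t.mm[mask]
    ind = np.minimum(t.ind[mask], l)
    mm_rate = profile.mismatch_rate[:npos][mask]
    ind_rate = profile.indel_rate[:npos][mask]
    total = binomial_log_pmf(mm, l, mm_rate) + binomial_log_pmf(ind, l, ind_rate)
    return float(np.sum(total))


def likelihood_score(triple: TripleAlignment, profile: ErrorProfile) -> ScoreResult:
    """The SV-vs-contiguous log-likelihood score for one candidate."""
    log_ps = {}
    for name, alignments in triple.items():
        log_ps[name] = configuration_log_prob(tally(alignments), profile)
    score = log_ps["sv"] - max(log_ps["c5"], log_ps["c3"])
    n_split = sum(1 for a in triple.sv if a.crosses_junction)
    return ScoreResult(
        candidate_id=triple.candidate_id,
        log_p_sv=log_ps["sv"],
        log_p_c5=log_ps["c5"],
        log_p_c3=log_ps["c3"],
        score=score,
        n_pairs=len(triple.sv) // 2,
        n_split_reads=n_split,
    )


def classify(result: ScoreResult, cutoff: float = DEFAULT_CUTOFF) -> str:
    """'pass' when score >= cutoff, else 'fail' (boundary passes)."""
    return "pass" if result.score >= cutoff else "fail"


def write_scores_tsv(results, path, cutoff: float = DEFAULT_CUTOFF) -> None:
    """Scores table sorted by score descending (prioritization order)."""
    results = sorted(results, key=lambda r: (-r.score, r.candidate_id))
    with open(path, "w") as fh:
        fh.write(
            "id\tscore\tlog_p_sv\tlog_p_c5\tlog_p_c3\tn_pairs\tn_split_reads\tstatus\n"
        )
        for r in results:
            fh.write(
                f"{r.candidate_id}\t{r.score:.4f}\t{r.log_p_sv:.4f}"
                f"\t{r.log_p_c5:.4f}\t{r.log_p_c3:.4f}"
                f"\t{r.n_pairs}\t{r.n_split_reads}\t{classify(r, cutoff)}\n"
            )
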