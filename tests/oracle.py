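"""Independent oracles used by the tests.

Pure-Python reference implementations, deliberately written without the
package's kernels or numpy: a plain affine-gap local-alignment DP over
Python lists, and an exhaustive-enumeration binomial pmf.
"""

from itertools import product

NEG = float("-inf")


def local_alignment_score(read: str, ref: str, match, mismatch, gap_open, gap_extend) -> float:
    """Best local affine-gap score; gap of length k costs open + (k-1)*extend."""
    n, m = len(read), len(ref)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            same = read[i - 1] == ref[j - 1] and read[i - 1] in "ACGT"
            s = match if same else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def binom_pmf_enumerated(k: int, l: int, rate: float) -> float:
    """P[k successes in l trials] by summing over all 2^l outcomes."""
    total = 0.0
    for outcome in product((0, 1), repeat=l):
        if sum(outcome) == k:
            p = 1.0
            for o in outcome:
                p *= rate if o else (1.0 - rate)
            total += p
    return total
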