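"""Small sequence utilities shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Encoding used by the alignment kernels: A=0 C=1 G=2 T=3, anything else
# (including N) = 4 and never matches any base.
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes for the alignment kernels."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
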