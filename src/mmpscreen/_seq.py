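"""Low-level nucleotide encoding helpers shared by the simulator and caller.

Bases are encoded A=0, C=1, G=2, T=3; any other symbol (N, IUPAC codes)
maps to 4 and therefore never matches a flank base and is skipped when
k-mers are counted.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0..T=3, other=4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join("ACGTN"[int(x)] for x in arr)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def phred_from_string(qual: str, offset: int = 33) -> np.ndarray:
    """Decode a Phred+33 quality string into integer scores."""
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int32) - offset


def phred_to_string(scores: np.ndarray, offset: int = 33) -> str:
    return "".join(chr(int(q) + offset) for q in scores)
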