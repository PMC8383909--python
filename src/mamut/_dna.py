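"""Low-level DNA sequence utilities shared across modules."""
from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase (soft-masked) bases keep their identity


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N and case preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(COMPLEMENT)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes A=0, C=1, G=2, T=3; anything else -> -1."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    out = np.full(len(codes), ord("N"), dtype=np.uint8)
    valid = codes >= 0
    out[valid] = np.frombuffer(b"ACGT", dtype=np.uint8)[codes[valid]]
    return out.tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases."""
    codes = encode(seq)
    valid = codes >= 0
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n
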