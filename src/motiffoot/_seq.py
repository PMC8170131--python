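"""Nucleotide encoding helpers shared across the package.

Bases are encoded A=0, C=1, G=2, T=3; anything else (IUPAC ambiguity
codes, gaps) maps to 4 and is treated as unscoreable downstream.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4

_ENCODE_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

# complement in code space; the ambiguity code is its own complement
COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_DECODE = np.array(list(BASES + "N"))


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def encode_many(seqs) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) code matrix."""
    if isinstance(seqs, np.ndarray):
        return np.asarray(seqs, dtype=np.uint8)
    joined = "".join(seqs)
    n = len(seqs)
    length = len(joined) // n if n else 0
    if n and length * n != len(joined):
        raise ValueError("sequences have unequal lengths")
    return encode(joined).reshape(n, length)


def decode(codes: np.ndarray) -> str:
    return "".join(_DECODE[np.asarray(codes)])


def revcomp(seq: str) -> str:
    return decode(COMPLEMENT[encode(seq)][::-1])


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement along the last axis."""
    return COMPLEMENT[codes][..., ::-1]
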