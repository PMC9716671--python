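"""Nucleotide encoding helpers shared across modules.

Sequences are held as Python strings at module boundaries and as uint8
code arrays (A=0, C=1, G=2, T=3, anything else=4) internally, which is
what makes the vectorised mapper and pileup fast.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement a code array (N maps to N)."""
    out = codes[..., ::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def gc_percent(seq: str | np.ndarray) -> float:
    codes = encode(seq) if isinstance(seq, str) else seq
    if codes.size == 0:
        return 0.0
    gc = np.count_nonzero((codes == 1) | (codes == 2))
    return 100.0 * gc / codes.size


def random_codes(rng: np.random.Generator, n: int, gc: float = 50.0) -> np.ndarray:
    """Random sequence codes with the requested GC content (percent)."""
    g = gc / 200.0
    at = (100.0 - gc) / 200.0
    return rng.choice(4, size=n, p=[at, g, g, at]).astype(np.uint8)
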