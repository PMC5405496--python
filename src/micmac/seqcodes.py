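"""Byte-level nucleotide encoding shared across the package.

Sequences are held as ``uint8`` arrays with A=0, C=1, G=2, T=3 and 4 for
anything else (N, IUPAC ambiguity codes, contig separators).  All heavy
operations (read simulation, seed indexing, Hamming counting, depth) work on
these code arrays; strings only appear at the I/O boundary.
"""

from __future__ import annotations

import numpy as np

ALPHABET = b"ACGTN"

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENCODE[_c] = _i
    _ENCODE[_c + 32] = _i  # lower case
_DECODE = np.frombuffer(ALPHABET, dtype=np.uint8)


def encode(seq: str | bytes | np.ndarray) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array."""
    if isinstance(seq, np.ndarray):
        if seq.dtype == np.uint8:
            return seq
        seq = str(seq)
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an upper-case string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (axis -1); code 4 maps to itself."""
    flipped = codes[..., ::-1]
    return np.where(flipped < 4, 3 - flipped, flipped).astype(np.uint8)


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def random_codes(rng: np.random.Generator, n: int, gc: float = 0.5) -> np.ndarray:
    """i.i.d. random sequence with the given GC content (A/T and G/C symmetric)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Return a copy with uniform substitutions at the given per-base rate.

    Each substituted base becomes one of the three *other* bases, uniformly.
    """
    out = codes.copy()
    if rate <= 0:
        return out
    mask = rng.random(out.shape) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, n, dtype=np.uint8)) % 4
    return out
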