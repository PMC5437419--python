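"""Low-level sequence helpers: complementation, integer encoding, k-mer scans.

Everything here works on plain upper-case ACGTN strings; N (or any other
letter) encodes as 4 and never participates in a k-mer match.
"""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> int8 array with A,C,G,T -> 0..3 and anything else -> 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def kmer_ints(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every k-mer into an integer.

    Returns (ints, valid) where valid[i] is False when the window starting at
    i contains a non-ACGT base. Uses 2 bits per base, so k must be <= 31.
    """
    if k > 31:
        raise ValueError("k-mer size above 31 not supported")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    c = codes.astype(np.int64)
    ints = np.zeros(n, dtype=np.int64)
    for j in range(k):
        ints = (ints << 2) | np.clip(c[j:j + n], 0, 3)
    bad = codes >= 4
    if bad.any():
        win_bad = np.convolve(bad.astype(np.int32), np.ones(k, dtype=np.int32), "valid") > 0
        valid = ~win_bad
    else:
        valid = np.ones(n, dtype=bool)
    return ints, valid


def random_dna(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, size=n).astype(np.int8))


def phred_to_qual(q: int, n: int) -> str:
    """Constant Phred+33 quality string of length n."""
    return chr(q + 33) * n


def mean_phred(qual: str) -> float:
    if not qual:
        return 0.0
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
    return float(arr.mean()) - 33.0
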