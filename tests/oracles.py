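"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimized code paths: the aligner is
a plain-Python full dynamic-programming Smith-Waterman, and Pi is an explicit
all-pairs loop.
"""
from __future__ import annotations

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def sw_full(read: str, ref: str, match: int = 1, mismatch: int = -2, gap: int = -3):
    """Full quadratic Smith-Waterman; returns (best, H) with H as lists."""
    m, n = len(read), len(ref)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        ri = read[i - 1]
        Hi, Hp = H[i], H[i - 1]
        for j in range(1, n + 1):
            s = match if ri == ref[j - 1] else mismatch
            v = Hp[j - 1] + s
            u = Hp[j] + gap
            if u > v:
                v = u
            w = Hi[j - 1] + gap
            if w > v:
                v = w
            if v < 0:
                v = 0
            Hi[j] = v
            if v > best:
                best = v
    return best, H


def sw_traceback(H, read: str, ref: str, cell, match=1, mismatch=-2, gap=-3):
    """Trace one optimal path, preferring diagonal > up > left.

    Returns (read_iv, ref_iv, matches, columns, aligned_read_bases).
    """
    i, j = cell
    matches = columns = aligned = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        s = match if read[i - 1] == ref[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += read[i - 1] == ref[j - 1]
            columns += 1
            aligned += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            columns += 1
            aligned += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return (i, None), (j, None), matches, columns, aligned


def best_cell(H, best):
    """Max cell with smallest ref column, then smallest read row."""
    out = None
    for i in range(len(H)):
        row = H[i]
        for j in range(len(row)):
            if row[j] == best:
                key = (j, i)
                if out is None or key < out[0]:
                    out = (key, (i, j))
    return out[1]


def oracle_map(read: str, doubled_ref: str, min_length_fraction=0.5,
               min_similarity=0.8):
    """Decision-level oracle for the short-read mapper.

    Returns None or (similarity, aligned_fraction, ref_start, strand).
    """
    candidates = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        score, H = sw_full(seq, doubled_ref)
        if score <= 0:
            continue
        cell = best_cell(H, score)
        (_, _), (j0, _), matches, columns, aligned = sw_traceback(H, seq, doubled_ref, cell)
        if columns == 0:
            continue
        candidates.append((-score, j0, strand == "-",
                           (matches / columns, aligned / len(read), j0, strand)))
    if not candidates:
        return None
    candidates.sort(key=lambda t: t[:3])
    sim, af, j0, strand = candidates[0][3]
    if af >= min_length_fraction and sim >= min_similarity:
        return sim, af, j0, strand
    return None


def pi_all_pairs(seqs) -> float:
    """Mean pairwise per-site difference with pairwise deletion of gaps/N."""
    n = len(seqs)
    total = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            comp = diff = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "ACGT" and b in "ACGT":
                    comp += 1
                    if a != b:
                        diff += 1
            total += diff / comp if comp else 0.0
            pairs += 1
    return total / pairs
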