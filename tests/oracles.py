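"""Independent brute-force oracles used to validate the implementation.

Each oracle recomputes a quantity by a method unrelated to the code path
it checks: full-matrix Gotoh DP for alignment scores, exhaustive base-3
path enumeration for Viterbi, exact rational hypergeometric enumeration
for Fisher's test, and naive double loops for k-mer counting.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

NEG = -1e18


def gotoh_score(query: str, reference: str, match: float, mismatch: float,
                gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap score; first gap base costs gap_open,
    each subsequent base gap_extend.  O(n*m) three-matrix DP."""
    n, m = len(query), len(reference)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in reference (insertion)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (deletion)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if query[i - 1] == reference[j - 1] else mismatch
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def enumerate_viterbi(em: np.ndarray, log_priors: np.ndarray, trans: np.ndarray):
    """Best path over all 3^L state sequences by explicit enumeration,
    with the prior applied at both ends of the sequence.

    Returns (best_score, best_path, unique) where unique is False when a
    different path ties the maximum within 1e-9.
    """
    L = em.shape[1]
    scores = log_priors + em[:, 0]  # index = path so far, last state least significant
    for j in range(1, L):
        last = np.arange(scores.size) % 3
        scores = (scores[:, None] + trans[last] + em[None, :, j]).ravel()
    scores = scores + log_priors[np.arange(scores.size) % 3]
    best_idx = int(np.argmax(scores))
    best = float(scores[best_idx])
    ties = int((scores >= best - 1e-9).sum())
    digits = []
    idx = best_idx
    for _ in range(L):
        digits.append(idx % 3)
        idx //= 3
    return best, np.array(digits[::-1], dtype=np.int8), ties == 1


def fisher_two_sided_exact(table) -> Fraction:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    obs = comb(r1, a) * comb(r2, c)
    total = comb(r1 + r2, c1)
    acc = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= obs:
            acc += w
    return Fraction(acc, total)


def naive_kmer_hits(insertions, overhang: str, k: int):
    """Double-loop recount of unique-position k-mer hits."""
    counts = {}
    for ins in insertions:
        for i in range(len(ins) - k + 1):
            kmer = ins[i : i + k]
            hits = [p for p in range(len(overhang) - k + 1) if overhang[p : p + k] == kmer]
            if len(hits) == 1:
                counts[hits[0]] = counts.get(hits[0], 0) + 1
    return counts
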