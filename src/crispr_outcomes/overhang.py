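"""Overhang-derived insertion analytics.

Insertions at a paired-nick site frequently copy the predicted inter-nick
overhang.  Each insertion is classified against the overhang (no match /
partial: shares at least one 9-mer / full: contains the complete overhang),
tandem overhang repetitions are examined for junctional microhomology (the
MMEJ hallmark), and 4-mer position histograms localize which part of the
overhang insertions derive from.  Group comparisons use Fisher's exact
test (match-class rates) and a permutation test on the positional shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

PARTIAL_KMER = 9


@dataclass(frozen=True)
class InsertionAnnotation:
    match_class: str  # none | partial | full
    matched_kmers: tuple[tuple[str, int, int], ...]  # (kmer, insertion offset, overhang position)
    overhang_copy_count: int
    microhomology_length: Optional[int]  # None when not applicable
    full_duplication: bool


@dataclass(frozen=True)
class KmerPositionHistogram:
    k: int
    counts: np.ndarray  # per overhang start position, length len(overhang)-k+1
    excluded_kmers: frozenset[str]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_permutations: object  # int or "exhaustive"
    seed: Optional[int] = None


def _kmer_positions(sequence: str, k: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(sequence) - k + 1):
        out.setdefault(sequence[i : i + k], []).append(i)
    return out


def count_nonoverlapping(haystack: str, needle: str) -> int:
    """Leftmost non-overlapping occurrence count."""
    count = 0
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i == -1:
            return count
        count += 1
        start = i + len(needle)


def detect_microhomology(insertion: str, overhang: str) -> Optional[int]:
    """Junctional microhomology between adjacent overhang copies.

    Two tandem copies sharing an m-nt junction appear in the insertion as
    ``overhang + overhang[m:]`` (the junction sequence is present once but
    belongs to both copies, so its placement is ambiguous over m bases).
    The smallest m whose pattern occurs is reported: it corresponds to the
    longest double-copy block physically present, which keeps an exact
    tandem (m=0) from being misread through the overhang's own
    suffix/prefix self-overlaps.  Returns 0 for exact tandem copies with
    no shared junction and None ("not applicable") when the insertion has
    no repeated copy structure.
    """
    insertion = insertion.upper()
    overhang = overhang.upper()
    for m in range(len(overhang)):
        if overhang + overhang[m:] in insertion:
            return m
    return None


def classify_insertion_match(insertion: str, overhang: str) -> InsertionAnnotation:
    """Classify one insertion against the predicted overhang.

    full: the complete overhang is a substring of the insertion;
    partial: the two share at least one exact 9-mer; none otherwise.
    ``full_duplication`` is true when a complete copy sits flush at an end
    of the insertion, i.e. inserting it at a nick reconstitutes an extra
    tandem copy of the overhang at the locus.
    """
    if len(overhang) < PARTIAL_KMER:
        raise ValueError("overhang too short for 9-mer rule")
    insertion = insertion.upper()
    overhang = overhang.upper()
    over_kmers = _kmer_positions(overhang, PARTIAL_KMER)
    matched: list[tuple[str, int, int]] = []
    for i in range(len(insertion) - PARTIAL_KMER + 1):
        kmer = insertion[i : i + PARTIAL_KMER]
        for pos in over_kmers.get(kmer, ()):
            matched.append((kmer, i, pos))
    copy_count = count_nonoverlapping(insertion, overhang)
    if overhang in insertion:
        match_class = "full"
    elif matched:
        match_class = "partial"
    else:
        match_class = "none"
    full_dup = copy_count >= 1 and (
        insertion.startswith(overhang) or insertion.endswith(overhang)
    )
    mh = detect_microhomology(insertion, overhang)
    if mh is None and copy_count >= 2:
        mh = 0
    return InsertionAnnotation(
        match_class=match_class,
        matched_kmers=tuple(matched),
        overhang_copy_count=copy_count,
        microhomology_length=mh,
        full_duplication=full_dup,
    )


def kmer_position_histogram(
    insertions: Sequence[str], overhang: str, k: int = 4
) -> KmerPositionHistogram:
    """Histogram of overhang positions hit by insertion k-mers.

    Every k-mer occurrence in every insertion that matches the overhang at
    exactly one position increments that position's count; k-mers occurring
    more than once in the overhang are excluded entirely (their position is
    ambiguous).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    overhang = overhang.upper()
    over_kmers = _kmer_positions(overhang, k)
    excluded = frozenset(km for km, pos in over_kmers.items() if len(pos) > 1)
    counts = np.zeros(max(len(overhang) - k + 1, 0), dtype=np.int64)
    for ins in insertions:
        ins = ins.upper()
        for i in range(len(ins) - k + 1):
            kmer = ins[i : i + k]
            pos = over_kmers.get(kmer)
            if pos is not None and len(pos) == 1:
                counts[pos[0]] += 1
    return KmerPositionHistogram(k=k, counts=counts, excluded_kmers=excluded)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test (point-probability method)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(
        statistic=float(odds), p_value=float(p), method="fisher_exact", n_permutations="exhaustive"
    )


def permutation_position_shift(
    positions_a: Sequence[float],
    positions_b: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
    exhaustive_limit: int = 20_000,
) -> TestResult:
    """Two-sided permutation test on the difference of means.

    All C(na+nb, na) splits are enumerated when that count is at most
    ``exhaustive_limit``; otherwise ``n_permutations`` Monte-Carlo
    resamples are drawn with the stated seed and the observed split is
    included in the p-value numerator and denominator.
    """
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    na = a.size
    observed = float(a.mean() - b.mean())
    tol = 1e-12
    total_splits = math.comb(pooled.size, na)
    if total_splits <= exhaustive_limit:
        count = 0
        idx_all = set(range(pooled.size))
        for idx in combinations(range(pooled.size), na):
            sa = pooled[list(idx)]
            sb = pooled[list(idx_all - set(idx))]
            if abs(sa.mean() - sb.mean()) >= abs(observed) - tol:
                count += 1
        return TestResult(
            statistic=observed,
            p_value=count / total_splits,
            method="permutation_diff_means",
            n_permutations="exhaustive",
        )
    rng = np.random.default_rng(seed)
    count = 1  # the observed split
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        d = perm[:na].mean() - perm[na:].mean()
        if abs(d) >= abs(observed) - tol:
            count += 1
    return TestResult(
        statistic=observed,
        p_value=count / (n_permutations + 1),
        method="permutation_diff_means",
        n_permutations=n_permutations,
        seed=seed,
    )
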