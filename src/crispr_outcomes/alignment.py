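"""Global read-to-amplicon alignment and indel extraction.

Alignment is global Needleman-Wunsch with affine gaps: the first base of a
gap costs ``gap_open`` and each further base ``gap_extend``.  The default
scoring scheme (match 2, mismatch -1, gap open -50, gap extend -1) makes
long contiguous indels strongly preferred over scattered single-base gaps,
which is the behaviour wanted for amplicon repair products where a single
cut-site indel is the expected event.

The engine is Bio.Align.PairwiseAligner; results are converted to gapped
strings and a CIGAR over {M, I, D} (M covers both matches and mismatches).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .reference import ReferenceAmplicon, reverse_complement


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -50.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("expected gap_open <= gap_extend <= 0 (scores)")
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")


#: Scoring used throughout unless overridden (the Sanger insertion-analysis
#: parameters; also the default for NGS reads).
SANGER_SCHEME = ScoringScheme(2, -1, -50, -1)
#: EMBOSS needle defaults, selectable for comparison.
NEEDLE_DEFAULT_SCHEME = ScoringScheme(1, -1, -10, -0.5)

_CIGAR_RE = re.compile(r"(\d+)([MID])")


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_query: str
    aligned_ref: str
    score: float
    cigar: str

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("gapped strings must have equal length")


@dataclass(frozen=True)
class IndelEvent:
    kind: Literal["insertion", "deletion"]
    ref_interval: tuple[int, int]
    inserted_sequence: str
    read_offset: int

    @property
    def size(self) -> int:
        if self.kind == "deletion":
            return self.ref_interval[1] - self.ref_interval[0]
        return len(self.inserted_sequence)


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            # N is a mismatch against everything, including itself
            matrix[a, b] = scheme.match if (a == b and a != "N") else scheme.mismatch
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def global_align(query: str, reference: str, scheme: ScoringScheme = SANGER_SCHEME) -> PairwiseAlignment:
    """Optimal global alignment of ``query`` against ``reference``.

    Raises ValueError("empty sequence") on empty input.  Traceback is
    deterministic (first optimal alignment of the engine).
    """
    if not query or not reference:
        raise ValueError("empty sequence")
    query = query.upper()
    reference = reference.upper()
    aligner = _make_aligner(scheme)
    aln = aligner.align(query, reference)[0]
    aligned_query, aligned_ref = str(aln[0]), str(aln[1])
    cigar_parts: list[str] = []

    def push(op: str, n: int):
        if n == 0:
            return
        if cigar_parts and cigar_parts[-1][-1] == op:
            prev = cigar_parts.pop()
            n += int(prev[:-1])
        cigar_parts.append(f"{n}{op}")

    for q, r in zip(aligned_query, aligned_ref):
        if q == "-":
            push("D", 1)
        elif r == "-":
            push("I", 1)
        else:
            push("M", 1)
    return PairwiseAlignment(
        aligned_query=aligned_query,
        aligned_ref=aligned_ref,
        score=float(aln.score),
        cigar="".join(cigar_parts),
    )


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def extract_indels(alignment: PairwiseAlignment) -> list[IndelEvent]:
    """One IndelEvent per maximal run of I or D in the alignment."""
    events: list[IndelEvent] = []
    ref_pos = 0
    read_pos = 0
    i = 0
    q, r = alignment.aligned_query, alignment.aligned_ref
    n = len(q)
    while i < n:
        if q[i] == "-":
            j = i
            while j < n and q[j] == "-":
                j += 1
            events.append(
                IndelEvent("deletion", (ref_pos, ref_pos + (j - i)), "", read_pos)
            )
            ref_pos += j - i
            i = j
        elif r[i] == "-":
            j = i
            while j < n and r[j] == "-":
                j += 1
            events.append(
                IndelEvent("insertion", (ref_pos, ref_pos), q[i:j], read_pos)
            )
            read_pos += j - i
            i = j
        else:
            ref_pos += 1
            read_pos += 1
            i += 1
    return events


def reconstruct_read(reference: str, events: list[IndelEvent]) -> str:
    """Apply indel events back onto the reference (mismatches ignored).

    Used as a structural round-trip check: for a read that differs from the
    reference only by the extracted indels, this reproduces the read.
    """
    out: list[str] = []
    ref_pos = 0
    # events must be in alignment order (as produced by extract_indels)
    for ev in events:
        out.append(reference[ref_pos : ev.ref_interval[0]])
        if ev.kind == "insertion":
            out.append(ev.inserted_sequence)
            ref_pos = ev.ref_interval[0]
        else:
            ref_pos = ev.ref_interval[1]
    out.append(reference[ref_pos:])
    return "".join(out)


def filter_primer_end_deletions(
    events: list[IndelEvent], reference: ReferenceAmplicon
) -> tuple[list[IndelEvent], bool]:
    """Flag reads whose deletions reach into a primer footprint.

    Deletions overlapping either primer interval are a hallmark of
    primer-dimer artifacts, so the whole read is excluded rather than the
    event trimmed.  Insertions at the ends are untouched.  Returns
    ``(events, excluded)``: events are passed through unchanged; the caller
    drops the read when ``excluded`` is true.
    """
    for ev in events:
        if ev.kind != "deletion":
            continue
        s, e = ev.ref_interval
        for ps, pe in reference.primer_intervals:
            if s < pe and ps < e:
                return events, True
    return events, False


@dataclass(frozen=True)
class MergePolicy:
    min_overlap: int = 10
    max_mismatch_fraction: float = 0.1
    quality_aware: bool = True

    def __post_init__(self):
        if self.min_overlap < 5:
            raise ValueError("min_overlap must be >= 5")
        if not (0 <= self.max_mismatch_fraction <= 0.5):
            raise ValueError("max_mismatch_fraction must be in [0, 0.5]")


class MergeFailure(ValueError):
    """No admissible ungapped overlap between the mates."""


def merge_pair(
    fwd: str,
    fwd_quals: list[int],
    rev: str,
    rev_quals: list[int],
    policy: MergePolicy = MergePolicy(),
) -> tuple[str, list[int]]:
    """Merge a read pair into a consensus.

    ``rev`` is given in sequencing orientation and is reverse-complemented
    first.  The best ungapped overlap of the forward read's suffix with the
    reverse-complemented read's prefix is scored (+1 match / -1 mismatch);
    an overlap is admissible when it is at least ``min_overlap`` long with
    a mismatch fraction at most ``max_mismatch_fraction``.  At disagreeing
    positions the consensus takes the higher-quality base.
    """
    rc = reverse_complement(rev)
    rc_quals = rev_quals[::-1]
    best: Optional[tuple[float, int]] = None  # (score, overlap)
    max_ov = min(len(fwd), len(rc))
    for ov in range(policy.min_overlap, max_ov + 1):
        a = fwd[len(fwd) - ov :]
        b = rc[:ov]
        mism = sum(1 for x, y in zip(a, b) if x != y)
        if mism / ov > policy.max_mismatch_fraction:
            continue
        score = (ov - mism) - mism
        if best is None or score > best[0] or (score == best[0] and ov > best[1]):
            best = (score, ov)
    if best is None:
        raise MergeFailure("merge failure")
    ov = best[1]
    head = fwd[: len(fwd) - ov]
    head_q = fwd_quals[: len(fwd) - ov]
    tail = rc[ov:]
    tail_q = rc_quals[ov:]
    mid: list[str] = []
    mid_q: list[int] = []
    for i in range(ov):
        fb, fq = fwd[len(fwd) - ov + i], fwd_quals[len(fwd) - ov + i]
        rb, rq = rc[i], rc_quals[i]
        if fb == rb:
            mid.append(fb)
            mid_q.append(max(fq, rq))
        elif policy.quality_aware and rq > fq:
            mid.append(rb)
            mid_q.append(rq)
        else:
            mid.append(fb)
            mid_q.append(fq)
    return head + "".join(mid) + tail, head_q + mid_q + tail_q
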