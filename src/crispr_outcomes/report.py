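"""Per-read outcome categories and per-sample summaries.

Each read receives exactly one category.  Precedence when a read shows
several event types: gene_correction > gene_conversion > insertion >
deletion > unmodified (HDR calls are rarer and more specific than indels,
matching mutually exclusive stacked-bar reporting); an ``ambiguous_template``
HDR event whose support cannot be attributed takes the same precedence
slot as the HDR calls.  A "complex" flag additionally records reads
carrying both an insertion and a deletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment import IndelEvent
from .hdr import HDREvent
from .overhang import TestResult, fisher_exact_2x2
from .reference import OverhangPrediction

CATEGORIES = (
    "unmodified",
    "deletion",
    "insertion",
    "gene_conversion",
    "gene_correction",
    "ambiguous_template",
)

DEFAULT_PRECEDENCE = (
    "gene_correction",
    "gene_conversion",
    "ambiguous_template",
    "insertion",
    "deletion",
    "unmodified",
)


@dataclass(frozen=True)
class ReadOutcome:
    read_id: str
    category: str
    indels: tuple[IndelEvent, ...]
    hdr_events: tuple[HDREvent, ...]
    exclusion_reason: Optional[str] = None
    complex_indels: bool = False

    @property
    def excluded(self) -> bool:
        return self.exclusion_reason is not None


def categorize_read(
    read_id: str,
    indels: Sequence[IndelEvent],
    hdr_events: Sequence[HDREvent],
    exclusion_reason: Optional[str] = None,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> ReadOutcome:
    if exclusion_reason is not None:
        return ReadOutcome(read_id, "excluded", tuple(indels), tuple(hdr_events), exclusion_reason)
    present = set()
    for ev in indels:
        present.add(ev.kind)
    etypes = {e.event_type for e in hdr_events}
    if "gene_correction" in etypes:
        present.add("gene_correction")
    if "gene_conversion" in etypes:
        present.add("gene_conversion")
    if etypes == {"ambiguous_template"} and etypes:
        present.add("ambiguous_template")
    category = "unmodified"
    for cat in precedence:
        if cat in present:
            category = cat
            break
    return ReadOutcome(
        read_id,
        category,
        tuple(indels),
        tuple(hdr_events),
        None,
        complex_indels=("insertion" in present and "deletion" in present),
    )


@dataclass
class OutcomeSummary:
    counts: dict[str, int]
    frequencies: dict[str, float]
    overall_modification_frequency: float
    deletion_sizes: list[int]
    deletion_size_median: Optional[float]
    insertion_lengths: list[int]
    insertion_length_median: Optional[float]
    precise_deletion_fraction: Optional[float]
    n_precise_deletions: int
    n_deletion_reads: int
    n_total: int
    n_excluded: int
    n_complex: int

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "frequencies": self.frequencies,
            "overall_modification_frequency": self.overall_modification_frequency,
            "deletion_size_median": self.deletion_size_median,
            "insertion_length_median": self.insertion_length_median,
            "precise_deletion_fraction": self.precise_deletion_fraction,
            "n_precise_deletions": self.n_precise_deletions,
            "n_deletion_reads": self.n_deletion_reads,
            "n_total": self.n_total,
            "n_excluded": self.n_excluded,
            "n_complex": self.n_complex,
        }


def is_precise_deletion(ev: IndelEvent, overhang: OverhangPrediction) -> bool:
    """A deletion whose reference interval equals the inter-nick interval."""
    return ev.kind == "deletion" and tuple(ev.ref_interval) == tuple(overhang.interval)


def summarize(
    outcomes: Sequence[ReadOutcome], overhang: Optional[OverhangPrediction] = None
) -> OutcomeSummary:
    kept = [o for o in outcomes if not o.excluded]
    n_excluded = len(outcomes) - len(kept)
    if not kept:
        raise ValueError("no analyzable reads")
    counts = {c: 0 for c in CATEGORIES}
    for o in kept:
        counts[o.category] += 1
    n = len(kept)
    freqs = {c: counts[c] / n for c in CATEGORIES}
    del_sizes: list[int] = []
    ins_lens: list[int] = []
    n_del_reads = 0
    n_precise = 0
    for o in kept:
        dels = [e for e in o.indels if e.kind == "deletion"]
        inss = [e for e in o.indels if e.kind == "insertion"]
        del_sizes.extend(e.size for e in dels)
        ins_lens.extend(e.size for e in inss)
        if dels:
            n_del_reads += 1
            if overhang is not None and any(is_precise_deletion(e, overhang) for e in dels):
                n_precise += 1
    return OutcomeSummary(
        counts=counts,
        frequencies=freqs,
        overall_modification_frequency=1.0 - freqs["unmodified"],
        deletion_sizes=del_sizes,
        deletion_size_median=float(np.median(del_sizes)) if del_sizes else None,
        insertion_lengths=ins_lens,
        insertion_length_median=float(np.median(ins_lens)) if ins_lens else None,
        precise_deletion_fraction=(n_precise / n_del_reads) if n_del_reads else None,
        n_precise_deletions=n_precise,
        n_deletion_reads=n_del_reads,
        n_total=len(outcomes),
        n_excluded=n_excluded,
        n_complex=sum(1 for o in kept if o.complex_indels),
    )


@dataclass(frozen=True)
class ConditionComparison:
    category: str
    fold_change: float
    continuity_corrected: bool
    fisher: TestResult


def compare_conditions(a: OutcomeSummary, b: OutcomeSummary, category: str) -> ConditionComparison:
    """Fold change (b over a) of a category frequency, with Fisher test.

    Zero counts are handled with the Haldane-Anscombe add-half correction
    (flagged in the result).  The Fisher table is (category vs rest) x
    (condition a vs b).
    """
    ca, na = a.counts[category], a.n_total - a.n_excluded
    cb, nb = b.counts[category], b.n_total - b.n_excluded
    corrected = ca == 0 or cb == 0
    if corrected:
        fa = (ca + 0.5) / (na + 1)
        fb = (cb + 0.5) / (nb + 1)
    else:
        fa = ca / na
        fb = cb / nb
    fisher = fisher_exact_2x2([[ca, na - ca], [cb, nb - cb]])
    return ConditionComparison(
        category=category,
        fold_change=fb / fa,
        continuity_corrected=corrected,
        fisher=fisher,
    )
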