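"""Amplicon/guide geometry and paired-nickase overhang prediction.

Coordinates are 0-based, half-open, on the reference top strand.  A nick
*position* denotes the phosphodiester bond 5' of that coordinate, i.e. a
nick at position ``p`` separates bases ``p-1`` and ``p``.

SpCas9 cleaves 3 nt 5' of the NGG PAM (measured on the guide's strand);
the HNH domain cuts the target (gRNA-complementary) strand and the RuvC
domain the non-target strand.  The D10A mutant retains only HNH activity,
N863A only RuvC.  Two nicks on opposite strands leave the inter-nick
sequence as a single-stranded overhang whose polarity depends on the
variant and on whether the PAMs face outwards (PAM-out) or towards each
other (PAM-in).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class GuidePlacementError(ValueError):
    """Raised when a spacer cannot be placed uniquely on the reference."""


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A PCR amplicon with primer footprints at both ends."""

    id: str
    sequence: str
    primer_intervals: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 40:
            raise ValueError("amplicon sequence must be at least 40 nt")
        if set(seq) - set("ACGT"):
            raise ValueError("amplicon sequence must be over {A,C,G,T}")
        (s1, e1), (s2, e2) = self.primer_intervals
        if s1 != 0 or e2 != len(seq):
            raise ValueError("primer intervals must be anchored at the amplicon ends")
        if e1 > s2:
            raise ValueError("primer intervals must not overlap")

    @property
    def inter_primer_interval(self) -> tuple[int, int]:
        return (self.primer_intervals[0][1], self.primer_intervals[1][0])


@dataclass(frozen=True)
class Guide:
    id: str
    spacer: str
    strand: Literal["+", "-"]
    protospacer_interval: tuple[int, int]
    pam_interval: tuple[int, int]


@dataclass(frozen=True)
class Cas9Variant:
    name: Literal["WT", "D10A", "N863A"]
    cleaves_target_strand: bool
    cleaves_nontarget_strand: bool

    @classmethod
    def from_name(cls, name: str) -> "Cas9Variant":
        name = name.upper()
        table = {
            "WT": (True, True),
            "D10A": (True, False),   # RuvC dead: HNH nicks the target strand
            "N863A": (False, True),  # HNH dead: RuvC nicks the non-target strand
        }
        if name not in table:
            raise ValueError(f"unknown Cas9 variant {name!r}")
        t, nt = table[name]
        return cls(name=name, cleaves_target_strand=t, cleaves_nontarget_strand=nt)


WT = Cas9Variant.from_name("WT")
D10A = Cas9Variant.from_name("D10A")
N863A = Cas9Variant.from_name("N863A")


@dataclass(frozen=True)
class NickSet:
    """Nicks produced by one guide/variant combination.

    Each nick is ``(position, strand)`` with position the top-strand bond
    coordinate.  ``blunt`` is true when both strands are cut at the same
    coordinate (WT).
    """

    nicks: tuple[tuple[int, str], ...]
    blunt: bool


@dataclass(frozen=True)
class OverhangPrediction:
    interval: tuple[int, int]
    sequence: str
    length: int
    polarity: Literal["five_prime", "three_prime", "blunt", "none"]
    pam_configuration: Literal["PAM_out", "PAM_in", "tandem"]
    strand_separation_expected: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "interval": list(self.interval),
                "sequence": self.sequence,
                "length": self.length,
                "polarity": self.polarity,
                "pam_configuration": self.pam_configuration,
                "strand_separation_expected": self.strand_separation_expected,
            }
        )

    def to_bed(self, amplicon_id: str) -> str:
        """BED line of the inter-nick interval on the amplicon."""
        return f"{amplicon_id}\t{self.interval[0]}\t{self.interval[1]}\toverhang_{self.polarity}\n"


def locate_guide(reference: ReferenceAmplicon, spacer: str, guide_id: str = "guide") -> Guide:
    """Place a spacer on the amplicon, requiring a unique protospacer+NGG hit.

    Both strands are searched with exact matching.  No hit raises
    "guide not found"; multiple hits raise "ambiguous guide placement".
    """
    spacer = spacer.upper()
    if len(spacer) < 16:
        raise ValueError("spacer must be at least 16 nt")
    seq = reference.sequence
    n = len(spacer)
    hits: list[Guide] = []
    # + strand: protospacer then NGG to its right
    start = seq.find(spacer)
    while start != -1:
        pam = seq[start + n : start + n + 3]
        if len(pam) == 3 and pam[1:] == "GG":
            hits.append(
                Guide(guide_id, spacer, "+", (start, start + n), (start + n, start + n + 3))
            )
        start = seq.find(spacer, start + 1)
    # - strand: top strand shows rc(spacer), PAM is rc(NGG)=CCN to its left
    rc = reverse_complement(spacer)
    start = seq.find(rc)
    while start != -1:
        pam = seq[start - 3 : start]
        if start >= 3 and pam[:2] == "CC":
            hits.append(Guide(guide_id, spacer, "-", (start, start + n), (start - 3, start)))
        start = seq.find(rc, start + 1)
    if not hits:
        raise GuidePlacementError("guide not found")
    if len(hits) > 1:
        raise GuidePlacementError("ambiguous guide placement")
    return hits[0]


def cut_position(guide: Guide) -> int:
    """Top-strand bond coordinate of the cut, 3 nt 5' of the PAM start."""
    s, e = guide.protospacer_interval
    if guide.strand == "+":
        return e - 3
    return s + 3


def predict_cut(guide: Guide, variant: Cas9Variant) -> NickSet:
    """Nicks for one guide: between protospacer bases 17 and 18.

    The cut coordinate is identical for all variants; only which strand(s)
    carry a nick differs.  The target strand is the strand opposite the
    protospacer strand (it base-pairs with the gRNA).
    """
    pos = cut_position(guide)
    target_strand = "-" if guide.strand == "+" else "+"
    nontarget_strand = guide.strand
    nicks = []
    if variant.cleaves_target_strand:
        nicks.append((pos, target_strand))
    if variant.cleaves_nontarget_strand:
        nicks.append((pos, nontarget_strand))
    return NickSet(nicks=tuple(sorted(nicks)), blunt=len(nicks) == 2)


def _pam_configuration(left: Guide, right: Guide) -> str:
    # PAM-out: the left guide's PAM lies left of its protospacer (- strand
    # guide) and the right guide's PAM right of its protospacer (+ strand).
    if left.strand == right.strand:
        return "tandem"
    if left.strand == "-" and right.strand == "+":
        return "PAM_out"
    return "PAM_in"


def predict_overhang(
    pair: tuple[Guide, Guide],
    variant: Cas9Variant,
    reference: ReferenceAmplicon,
) -> OverhangPrediction:
    """Predicted inter-nick overhang for a guide pair on opposite strands.

    Polarity: PAM-out pairs give a 5' overhang with D10A and a 3' overhang
    with N863A; PAM-in swaps the two.  WT excises the inter-nick fragment
    as blunt-ended duplex, so no single-stranded polarity is assigned
    (``none`` unless the two cuts coincide, which is ``blunt``).  Strand
    separation is only expected for PAM-out pairs or a WT double cut.
    """
    g1, g2 = pair
    if g1.strand == g2.strand:
        raise ValueError("tandem configuration unsupported for overhang prediction")
    left, right = sorted(pair, key=lambda g: g.protospacer_interval[0])
    p1, p2 = cut_position(left), cut_position(right)
    lo, hi = min(p1, p2), max(p1, p2)
    config = _pam_configuration(left, right)
    length = hi - lo
    if length == 0:
        polarity = "blunt"
    elif variant.name == "WT":
        polarity = "none"
    elif config == "PAM_out":
        polarity = "five_prime" if variant.name == "D10A" else "three_prime"
    else:  # PAM_in
        polarity = "three_prime" if variant.name == "D10A" else "five_prime"
    return OverhangPrediction(
        interval=(lo, hi),
        sequence=reference.sequence[lo:hi],
        length=length,
        polarity=polarity,
        pam_configuration=config,
        strand_separation_expected=(config == "PAM_out") or variant.name == "WT",
    )
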