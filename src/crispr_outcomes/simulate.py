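"""Truth-labeled synthetic amplicon reads.

The generator emulates the statistical structure of amplicon sequencing
after paired-nickase editing: a mixture of unmodified reads, cut-centered
deletions, overhang-derived insertions (nickase-specific signatures),
gene-conversion tracts copying homolog alleles, ssODN-templated
corrections, and per-base substitution error.  Every read carries its true
category and edit events, so pipeline stages can be scored against truth.

The built-in toy locus embeds a 47-nt inter-nick overhang between two
PAM-out protospacers on a ~600-nt amplicon, with a full-length homolog
(6 planted mismatches by default, echoing a paralog like HBD) and a 150-nt
ssODN donor (8 mismatches by default, a "high mismatch" donor).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .reference import (
    Guide,
    OverhangPrediction,
    ReferenceAmplicon,
    locate_guide,
    predict_overhang,
    reverse_complement,
    Cas9Variant,
    D10A,
)

#: The 47-nt inter-nick overhang of the canonical PAM-out guide pair used
#: throughout examples and tests.
CANONICAL_OVERHANG = "TCATCCACGTTCACCTTGCCCCACAGGGCAGTAACGGCAGACTTCTC"

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

# candidate mismatch offsets relative to the overhang start (left nick)
_HOMOLOG_OFFSETS = [-30, -10, 10, 30, 62, 87, -55, 110, -80, 130]
_ODN_OFFSETS = [-45, -35, -20, -2, 5, 20, 40, 55, -50, 70]
_ODN_HALF_SPAN = 75  # ssODN spans overhang midpoint +/- 75 nt

CATEGORY_ORDER = (
    "unmodified",
    "deletion",
    "insertion",
    "gene_conversion",
    "gene_correction",
)


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


@dataclass(frozen=True)
class ToyLocus:
    amplicon: ReferenceAmplicon
    spacer_left: str   # targets the minus strand (left, PAM-out)
    spacer_right: str  # targets the plus strand (right, PAM-out)
    homolog: str
    odn: str
    homolog_positions: tuple[int, ...]
    odn_positions: tuple[int, ...]

    def guides(self) -> tuple[Guide, Guide]:
        return (
            locate_guide(self.amplicon, self.spacer_left, "left"),
            locate_guide(self.amplicon, self.spacer_right, "right"),
        )

    def overhang(self, variant: Cas9Variant = D10A) -> OverhangPrediction:
        return predict_overhang(self.guides(), variant, self.amplicon)


def make_toy_locus(
    n_homolog_mismatches: int = 6,
    n_odn_mismatches: int = 8,
    overhang: str = CANONICAL_OVERHANG,
    length: int = 600,
    primer_length: int = 20,
    locus_seed: int = 20170109,
) -> ToyLocus:
    """Build a synthetic amplicon embedding ``overhang`` between two
    PAM-out protospacers, with planted template mismatches.

    The overhang's outer flanking bases are chosen to differ from the
    overhang's terminal bases so that a nick-to-nick deletion has an
    unambiguous alignment placement.  The locus sequence itself is a fixed
    pseudo-random background (``locus_seed``); the read-simulation seed is
    separate.
    """
    if len(overhang) < 37:
        raise ValueError("overhang must be at least 37 nt (17 + 3 + 17)")
    rng = np.random.default_rng(locus_seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    s = (length - len(overhang)) // 2 - 20  # left protospacer start
    lo = s + 3  # left nick = overhang start
    hi = lo + len(overhang)  # right nick
    s2 = hi - 17  # right protospacer start
    # left guide (- strand): CCN PAM then protospacer on the top strand
    seq[s - 3 : s] = list("CCT")
    left_pad = "CA" + ("G" if overhang[-1] != "G" else "A")
    seq[s : s + 3] = list(left_pad)
    seq[lo:hi] = list(overhang)
    right_pad = ("G" if overhang[0] != "G" else "A") + "AT"
    seq[s2 + 17 : s2 + 20] = list(right_pad)
    seq[s2 + 20 : s2 + 23] = list("TGG")
    sequence = "".join(seq)
    amplicon = ReferenceAmplicon(
        id="toy_amplicon",
        sequence=sequence,
        primer_intervals=((0, primer_length), (length - primer_length, length)),
    )
    spacer_left = reverse_complement(sequence[s : s + 20])
    spacer_right = sequence[s2 : s2 + 20]
    # planted template mismatches (transitions at fixed offsets)
    if n_homolog_mismatches > len(_HOMOLOG_OFFSETS):
        raise ValueError("too many homolog mismatches requested")
    if n_odn_mismatches > len(_ODN_OFFSETS):
        raise ValueError("too many ssODN mismatches requested")
    hom_pos = tuple(sorted(lo + o for o in _HOMOLOG_OFFSETS[:n_homolog_mismatches]))
    odn_pos = tuple(sorted(lo + o for o in _ODN_OFFSETS[:n_odn_mismatches]))
    homolog = list(sequence)
    for p in hom_pos:
        homolog[p] = _TRANSITION[sequence[p]]
    mid = (lo + hi) // 2
    odn_interval = (mid - _ODN_HALF_SPAN, mid + _ODN_HALF_SPAN)
    odn = list(sequence[odn_interval[0] : odn_interval[1]])
    for p in odn_pos:
        odn[p - odn_interval[0]] = _TRANSITION[sequence[p]]
    return ToyLocus(
        amplicon=amplicon,
        spacer_left=spacer_left,
        spacer_right=spacer_right,
        homolog="".join(homolog),
        odn="".join(odn),
        homolog_positions=hom_pos,
        odn_positions=odn_pos,
    )


@dataclass(frozen=True)
class DeletionModel:
    distribution: Literal["geometric", "nbinom"] = "geometric"
    median: float = 3.0
    jitter_sd: float = 4.0
    precise_probability: float = 0.0  # TREX2-style nick-to-nick deletions


@dataclass(frozen=True)
class InsertionModel:
    preset: Literal["D10A", "N863A"] = "D10A"
    full_duplication_probability: float = 0.12
    tandem_probability: float = 0.40      # N863A only
    junction_overlap_range: tuple[int, int] = (2, 8)


@dataclass(frozen=True)
class GCModel:
    extend_probability_left: float = 0.25
    extend_probability_right: float = 0.10
    mean_extension_left: float = 45.0
    mean_extension_right: float = 15.0


@dataclass(frozen=True)
class CorrectionModel:
    full_tract_probability: float = 0.7  # else a central tract


@dataclass(frozen=True)
class SimulationConfig:
    locus: ToyLocus
    mixture: dict[str, float]
    deletion_model: DeletionModel = DeletionModel()
    insertion_model: InsertionModel = InsertionModel()
    gc_model: GCModel = GCModel()
    correction_model: CorrectionModel = CorrectionModel()
    error_rate: float = 0.0
    paired_end: bool = False
    read_length: int = 400
    seed: int = 0

    def __post_init__(self):
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mixture must sum to 1")
        unknown = set(self.mixture) - set(CATEGORY_ORDER)
        if unknown:
            raise ValueError(f"unknown mixture categories: {sorted(unknown)}")
        if not (0 <= self.error_rate < 0.2):
            raise ValueError("error_rate must be in [0, 0.2)")


@dataclass(frozen=True)
class TruthEvent:
    kind: str  # deletion | insertion | substitution_tract
    interval: tuple[int, int]
    sequence: str = ""
    source_interval: Optional[tuple[int, int]] = None
    microhomology: Optional[int] = None
    precise: bool = False


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    truth_category: str
    truth_events: tuple[TruthEvent, ...]
    tract_left_arm: int = 0
    tract_right_arm: int = 0
    # paired-end fragments (sequencing orientation); None in single-end mode
    mate1: Optional[tuple[str, tuple[int, ...]]] = None
    mate2: Optional[tuple[str, tuple[int, ...]]] = None


def apply_truth_events(reference: str, events: tuple[TruthEvent, ...]) -> str:
    """Reconstruct the pre-error read sequence from reference + truth events."""
    seq = reference
    # apply right-to-left so earlier coordinates stay valid
    for ev in sorted(events, key=lambda e: e.interval[0], reverse=True):
        a, b = ev.interval
        if ev.kind == "deletion":
            seq = seq[:a] + seq[b:]
        elif ev.kind == "insertion":
            seq = seq[:a] + ev.sequence + seq[a:]
        elif ev.kind == "substitution_tract":
            seq = seq[:a] + ev.sequence + seq[b:]
        else:
            raise ValueError(f"unknown truth event kind {ev.kind!r}")
    return seq


def _geometric_p_for_median(median: float) -> float:
    return 1.0 - 0.5 ** (1.0 / median)


def _nbinom_p_for_median(median: float, r: float = 2.0) -> float:
    # smallest-error p such that 1 + NB(r, p) has the requested median
    lo_p, hi_p = 1e-4, 0.999
    for _ in range(60):
        p = 0.5 * (lo_p + hi_p)
        if 1 + sp_stats.nbinom.median(r, p) > median:
            lo_p = p
        else:
            hi_p = p
    return 0.5 * (lo_p + hi_p)


class _Simulator:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.locus = config.locus
        self.ref = self.locus.amplicon.sequence
        self.overhang = self.locus.overhang()
        self.lo, self.hi = self.overhang.interval
        self.rng = np.random.default_rng(config.seed)
        dm = config.deletion_model
        if dm.distribution == "geometric":
            self._del_sampler = lambda: int(
                self.rng.geometric(_geometric_p_for_median(dm.median))
            )
        else:
            p = _nbinom_p_for_median(dm.median)
            self._del_sampler = lambda: 1 + int(self.rng.negative_binomial(2.0, p))

    # --- per-category edits ----------------------------------------------

    def _deletion_events(self) -> tuple[TruthEvent, ...]:
        dm = self.cfg.deletion_model
        lo, hi = self.lo, self.hi
        if self.rng.random() < dm.precise_probability:
            return (TruthEvent("deletion", (lo, hi), precise=True),)
        inner = self.locus.amplicon.inter_primer_interval
        for _ in range(100):
            size = self._del_sampler()
            center = (lo + hi) // 2
            jitter = int(round(self.rng.normal(0.0, dm.jitter_sd)))
            start = center - size // 2 + jitter
            end = start + size
            if start <= inner[0] + 2 or end >= inner[1] - 2:
                continue
            if (start, end) == (lo, hi):
                end += 1  # reserve the exact nick-to-nick interval for precise deletions
                if end >= inner[1] - 2:
                    continue
            return (TruthEvent("deletion", (start, end)),)
        raise RuntimeError("could not place deletion inside the amplicon")

    def _insertion_events(self) -> tuple[TruthEvent, ...]:
        im = self.cfg.insertion_model
        O = self.overhang.sequence
        rng = self.rng
        mh: Optional[int] = None
        if im.preset == "D10A":
            if rng.random() < im.full_duplication_probability:
                frag = O
                src = (0, len(O))
            else:
                a = int(rng.integers(0, 12))
                max_len = min(20 - a, 20)
                size = int(rng.integers(3, max_len + 1))
                frag = O[a : a + size]
                src = (a, a + size)
        else:  # N863A: central fragments and tandem repetitions with junction overlap
            u = rng.random()
            if u < im.tandem_probability:
                m_lo, m_hi = im.junction_overlap_range
                m = int(rng.integers(m_lo, m_hi + 1))
                frag = O + O[m:]
                src = (0, len(O))
                mh = m
            elif u < im.tandem_probability + 0.15:
                frag = O
                src = (0, len(O))
            else:
                a = int(rng.integers(10, 26))
                max_len = min(len(O) - a, 30)
                size = int(rng.integers(9, max_len + 1))
                frag = O[a : a + size]
                src = (a, a + size)
        return (
            TruthEvent(
                "insertion", (self.lo, self.lo), sequence=frag,
                source_interval=src, microhomology=mh,
            ),
        )

    def _gc_events(self) -> tuple[tuple[TruthEvent, ...], int, int]:
        gm = self.cfg.gc_model
        rng = self.rng
        left_ext = 0
        right_ext = 0
        if rng.random() < gm.extend_probability_left:
            left_ext = int(rng.geometric(1.0 / gm.mean_extension_left))
        if rng.random() < gm.extend_probability_right:
            right_ext = int(rng.geometric(1.0 / gm.mean_extension_right))
        inner = self.locus.amplicon.inter_primer_interval
        a = max(self.lo - left_ext, inner[0])
        b = min(self.hi + right_ext, inner[1])
        tract = self.locus.homolog[a:b]
        if tract == self.ref[a:b]:  # ensure the tract is observable
            a, b = self.lo, self.hi
            tract = self.locus.homolog[a:b]
        return (
            (TruthEvent("substitution_tract", (a, b), sequence=tract),),
            self.lo - a,
            b - self.hi,
        )

    def _correction_events(self) -> tuple[TruthEvent, ...]:
        cm = self.cfg.correction_model
        mid = (self.lo + self.hi) // 2
        odn_a = mid - _ODN_HALF_SPAN
        odn_b = mid + _ODN_HALF_SPAN
        if self.rng.random() < cm.full_tract_probability:
            a, b = odn_a, odn_b
        else:
            a, b = max(odn_a, self.lo - 25), min(odn_b, self.hi + 45)
        tract = list(self.ref[a:b])
        for p in self.locus.odn_positions:
            if a <= p < b:
                tract[p - a] = self.locus.odn[p - odn_a]
        return (TruthEvent("substitution_tract", (a, b), sequence="".join(tract)),)

    # --- read assembly ----------------------------------------------------

    def make_read(self, index: int) -> SimulatedRead:
        cats = list(self.cfg.mixture.keys())
        probs = np.array([self.cfg.mixture[c] for c in cats])
        category = cats[self.rng.choice(len(cats), p=probs)]
        left_arm = right_arm = 0
        if category == "unmodified":
            events: tuple[TruthEvent, ...] = ()
        elif category == "deletion":
            events = self._deletion_events()
        elif category == "insertion":
            events = self._insertion_events()
        elif category == "gene_conversion":
            events, left_arm, right_arm = self._gc_events()
        elif category == "gene_correction":
            events = self._correction_events()
        else:  # pragma: no cover
            raise ValueError(category)
        seq = apply_truth_events(self.ref, events)
        if self.cfg.error_rate > 0:
            arr = list(seq)
            hits = np.flatnonzero(self.rng.random(len(arr)) < self.cfg.error_rate)
            for i in hits:
                arr[i] = _other_base(arr[i], self.rng)
            seq = "".join(arr)
        quals = tuple([30] * len(seq))
        read = SimulatedRead(
            read_id=f"read{index:06d}",
            sequence=seq,
            qualities=quals,
            truth_category=category,
            truth_events=events,
            tract_left_arm=left_arm,
            tract_right_arm=right_arm,
        )
        if self.cfg.paired_end:
            rl = min(self.cfg.read_length, len(seq))
            fwd = (seq[:rl], quals[:rl])
            rev = (reverse_complement(seq[-rl:]), quals[-rl:])
            read = replace(read, mate1=fwd, mate2=rev)
        return read


def simulate_sample(config: SimulationConfig, n: int) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Draw ``n`` truth-labeled reads i.i.d. from the configured mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sim = _Simulator(config)
    reads = [sim.make_read(i) for i in range(n)]
    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "truth_category": [r.truth_category for r in reads],
            "n_events": [len(r.truth_events) for r in reads],
            "tract_left_arm": [r.tract_left_arm for r in reads],
            "tract_right_arm": [r.tract_right_arm for r in reads],
            "precise_deletion": [
                any(ev.precise for ev in r.truth_events) for r in reads
            ],
        }
    )
    return reads, truth


def preset_config(name: str, seed: int = 0, locus: Optional[ToyLocus] = None) -> SimulationConfig:
    """Named study conditions.

    WT: small cut-site deletions (median 3 nt) dominate, moderate gene
    conversion.  D10A: larger deletions (median ~36), strong gene
    conversion, first-20-nt insertion fragments.  N863A: insertion-rich
    (central-overhang fragments, tandem repeats with junctional
    microhomology), little gene conversion.  *_TREX2 presets enrich
    precise nick-to-nick deletions; *_ssODN presets add gene correction.
    """
    locus = locus or make_toy_locus()
    presets: dict[str, SimulationConfig] = {
        "WT": SimulationConfig(
            locus=locus,
            mixture={
                "unmodified": 0.20,
                "deletion": 0.55,
                "insertion": 0.126,
                "gene_conversion": 0.124,
                "gene_correction": 0.0,
            },
            deletion_model=DeletionModel("geometric", median=3.0),
            insertion_model=InsertionModel("D10A"),
            seed=seed,
        ),
        "D10A": SimulationConfig(
            locus=locus,
            mixture={
                "unmodified": 0.282,
                "deletion": 0.30,
                "insertion": 0.09,
                "gene_conversion": 0.328,
                "gene_correction": 0.0,
            },
            deletion_model=DeletionModel("nbinom", median=36.0),
            insertion_model=InsertionModel("D10A"),
            seed=seed,
        ),
        "N863A": SimulationConfig(
            locus=locus,
            mixture={
                "unmodified": 0.301,
                "deletion": 0.365,
                "insertion": 0.299,
                "gene_conversion": 0.035,
                "gene_correction": 0.0,
            },
            deletion_model=DeletionModel("nbinom", median=28.0),
            insertion_model=InsertionModel("N863A"),
            seed=seed,
        ),
        "N863A_TREX2": SimulationConfig(
            locus=locus,
            mixture={
                "unmodified": 0.25,
                "deletion": 0.65,
                "insertion": 0.065,
                "gene_conversion": 0.035,
                "gene_correction": 0.0,
            },
            deletion_model=DeletionModel("nbinom", median=28.0, precise_probability=0.303),
            insertion_model=InsertionModel("N863A"),
            seed=seed,
        ),
        "D10A_ssODN": SimulationConfig(
            locus=locus,
            mixture={
                "unmodified": 0.242,
                "deletion": 0.27,
                "insertion": 0.09,
                "gene_conversion": 0.16,
                "gene_correction": 0.238,
            },
            deletion_model=DeletionModel("nbinom", median=36.0),
            insertion_model=InsertionModel("D10A"),
            seed=seed,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]
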