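"""HDR template attribution: gene conversion vs gene correction calling.

The amplicon locus has two candidate homology-directed-repair templates: an
endogenous homolog (e.g. a highly similar paralog such as HBD for HBB) and
a supplied ssODN.  Both differ from the amplicon only at a handful of
single-nucleotide *informative positions*.  Each aligned read is encoded as
a 3 x L binary matrix (rows: reference, homolog, ssODN; columns: aligned
read bases; entry = does the read base match that sequence here), and a
3-state hidden Markov model is decoded with the Viterbi algorithm to find
segments of the read copied from a template.  A template segment supported
by two consecutive informative positions is called a gene-conversion
(homolog) or gene-correction (ssODN) event.

States are ordered (REF, HOMOLOG, ODN); ties in the Viterbi argmax resolve
in that order.  All arithmetic is in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .alignment import PairwiseAlignment, ScoringScheme, SANGER_SCHEME, _make_aligner
from .reference import ReferenceAmplicon

STATE_NAMES = ("HBB", "HOMOLOG", "ODN")
REF_STATE, HOMOLOG_STATE, ODN_STATE = 0, 1, 2


class TemplateWarning(UserWarning):
    pass


@dataclass(frozen=True)
class InformativePosition:
    ref_position: int
    template_id: Literal["HOMOLOG", "ODN"]
    ref_base: str
    template_base: str


@dataclass
class TemplateSet:
    """Donor templates aligned to the amplicon.

    ``template_base[t]`` maps amplicon coordinate -> aligned template base
    for every position where template ``t`` has an aligned (non-gap) base;
    coordinates outside the template's homologous span or opposite an
    internal template gap are absent and carry no evidence downstream.
    """

    amplicon: ReferenceAmplicon
    template_base: dict[str, dict[int, str]]
    informative: dict[str, list[InformativePosition]]

    def informative_positions(self, template_id: str) -> list[int]:
        return [ip.ref_position for ip in self.informative[template_id]]

    def is_shared_allele(self, ref_position: int) -> bool:
        """True when homolog and ssODN carry the same non-reference base."""
        h = self.template_base["HOMOLOG"].get(ref_position)
        o = self.template_base["ODN"].get(ref_position)
        if h is None or o is None:
            return False
        return h == o and h != self.amplicon.sequence[ref_position]


def _align_template(template: str, amplicon_seq: str, scheme: ScoringScheme) -> dict[int, str]:
    """Map amplicon coordinate -> template base, end gaps free.

    Templates (in particular the short ssODN) cover only a span of the
    amplicon, so terminal gaps are not penalized.
    """
    aligner = _make_aligner(scheme)
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aln = aligner.align(template.upper(), amplicon_seq)[0]
    q, r = str(aln[0]), str(aln[1])
    mapping: dict[int, str] = {}
    ref_pos = 0
    # trim terminal template gaps: only the aligned span defines bases
    first = next(i for i, c in enumerate(q) if c != "-")
    last = len(q) - next(i for i, c in enumerate(reversed(q)) if c != "-")
    for i, (qc, rc) in enumerate(zip(q, r)):
        if rc != "-":
            if qc != "-" and first <= i < last:
                mapping[ref_pos] = qc
            ref_pos += 1
    return mapping


def build_template_set(
    amplicon: ReferenceAmplicon,
    homolog: str,
    odn: str,
    scheme: ScoringScheme = SANGER_SCHEME,
) -> TemplateSet:
    """Align both donors to the amplicon and derive informative positions.

    A template with zero informative positions cannot be distinguished from
    the reference; a ``TemplateWarning`` is raised for it.
    """
    seq = amplicon.sequence
    template_base: dict[str, dict[int, str]] = {}
    informative: dict[str, list[InformativePosition]] = {}
    for tid, tseq in (("HOMOLOG", homolog), ("ODN", odn)):
        mapping = _align_template(tseq, seq, scheme)
        template_base[tid] = mapping
        infos = [
            InformativePosition(p, tid, seq[p], b)
            for p, b in sorted(mapping.items())
            if b != seq[p]
        ]
        informative[tid] = infos
        if not infos:
            warnings.warn(
                f"template {tid} indistinguishable from reference", TemplateWarning
            )
    return TemplateSet(amplicon=amplicon, template_base=template_base, informative=informative)


@dataclass
class ReadMatchMatrix:
    """3 x L binary encoding of one aligned read.

    ``matrix[s, j]`` is 1 iff the read base in column j equals sequence s
    there; ``defined[s, j]`` is False where template s has no aligned base
    (those cells carry no evidence).  Columns exist only for read bases
    with 'M' status; read deletions remove columns.
    """

    matrix: np.ndarray  # (3, L) int8
    defined: np.ndarray  # (3, L) bool
    column_ref_positions: np.ndarray  # (L,) int

    @property
    def L(self) -> int:
        return self.matrix.shape[1]


def encode_read(read_alignment: PairwiseAlignment, tset: TemplateSet) -> ReadMatchMatrix:
    seq = tset.amplicon.sequence
    cols_pos: list[int] = []
    cols_match: list[tuple[int, int, int]] = []
    cols_def: list[tuple[bool, bool, bool]] = []
    ref_pos = 0
    for qc, rc in zip(read_alignment.aligned_query, read_alignment.aligned_ref):
        if rc == "-":
            continue
        if qc != "-":
            row = [1 if qc == seq[ref_pos] else 0, 0, 0]
            dfn = [True, False, False]
            for k, tid in ((1, "HOMOLOG"), (2, "ODN")):
                b = tset.template_base[tid].get(ref_pos)
                if b is not None:
                    dfn[k] = True
                    row[k] = 1 if qc == b else 0
            cols_pos.append(ref_pos)
            cols_match.append(tuple(row))
            cols_def.append(tuple(dfn))
        ref_pos += 1
    if cols_pos:
        matrix = np.array(cols_match, dtype=np.int8).T
        defined = np.array(cols_def, dtype=bool).T
        positions = np.array(cols_pos, dtype=np.int64)
    else:
        matrix = np.zeros((3, 0), dtype=np.int8)
        defined = np.zeros((3, 0), dtype=bool)
        positions = np.zeros(0, dtype=np.int64)
    return ReadMatchMatrix(matrix=matrix, defined=defined, column_ref_positions=positions)


@dataclass(frozen=True)
class ViterbiParams:
    """3-state HMM parameters.

    epsilon is the per-base probability that a read base mismatches its
    true template (sequencing/PCR substitution error); tau the per-column
    probability of switching template.  The defaults are tuned so the
    two-consecutive-informative-base calling rule is an emergent property
    of the decoder: a template switch pays 2*log((1-2*tau)/tau) in log
    odds while each supporting informative column contributes
    log((1-epsilon)/epsilon), so with epsilon=0.01 any tau between
    exp(-4.6)=0.010 and exp(-2.3)=0.100 makes exactly two consecutive
    supporting columns sufficient and one insufficient; tau=0.03 sits
    centrally in that window.
    """

    epsilon: float = 0.01
    tau: float = 0.03
    priors: tuple[float, float, float] = (0.98, 0.01, 0.01)

    def __post_init__(self):
        if not (0 < self.epsilon < 0.5):
            raise ValueError("epsilon must be in (0, 0.5)")
        if not (0 < self.tau < 0.5):
            raise ValueError("tau must be in (0, 0.5)")
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")


DEFAULT_VITERBI_PARAMS = ViterbiParams()


@dataclass(frozen=True)
class HDREvent:
    event_type: Literal["gene_conversion", "gene_correction", "ambiguous_template"]
    template_id: Literal["HOMOLOG", "ODN"]
    interval: tuple[int, int]  # amplicon coords, first..last supporting position
    n_supporting: int


@dataclass
class Segmentation:
    state_path: np.ndarray  # (L,) int, values in {0,1,2}
    segments: list[tuple[int, tuple[int, int], tuple[int, int]]]
    # each: (state, column interval half-open, amplicon interval half-open)
    matrix: ReadMatchMatrix
    events: list[HDREvent] = field(default_factory=list)


def emission_log_likelihoods(matrix: ReadMatchMatrix, params: ViterbiParams) -> np.ndarray:
    """(3, L) log emission terms.

    A defined matching cell emits log(1-epsilon), a defined mismatching
    cell log(epsilon), an undefined cell 0 (likelihood 1: no evidence).
    """
    log_match = np.log1p(-params.epsilon)
    log_mismatch = np.log(params.epsilon)
    em = np.where(matrix.matrix == 1, log_match, log_mismatch)
    return np.where(matrix.defined, em, 0.0)


def viterbi_segment(matrix: ReadMatchMatrix, params: ViterbiParams = DEFAULT_VITERBI_PARAMS) -> Segmentation:
    """Maximum-a-posteriori state path of the 3-state model.

    Transitions: stay with probability 1-2*tau, switch to each other state
    with tau.  The prior is applied at both ends of the read (amplicon
    reads begin and end in primer-anchored reference sequence, so a
    template segment must pay its way back out); ties resolve to the
    lowest state index (REF first).
    """
    L = matrix.L
    if L < 1:
        raise ValueError("matrix must have at least one column")
    em = emission_log_likelihoods(matrix, params)
    # tie-break between equal-likelihood paths: prefer the one spending the
    # fewest columns in a template state, so segment boundaries sit at the
    # first/last supporting column rather than drifting across the
    # emission-neutral columns in between
    em = em - 1e-9 * np.array([[0.0], [1.0], [1.0]])
    log_stay = np.log1p(-2 * params.tau)
    log_switch = np.log(params.tau)
    trans = np.full((3, 3), log_switch)
    np.fill_diagonal(trans, log_stay)
    delta = np.log(np.asarray(params.priors)) + em[:, 0]
    back = np.zeros((L, 3), dtype=np.int8)
    for j in range(1, L):
        cand = delta[:, None] + trans  # cand[prev, cur]
        best_prev = np.argmax(cand, axis=0)  # lowest index wins ties
        delta = cand[best_prev, np.arange(3)] + em[:, j]
        back[j] = best_prev
    path = np.empty(L, dtype=np.int8)
    path[-1] = int(np.argmax(delta + np.log(np.asarray(params.priors))))
    for j in range(L - 1, 0, -1):
        path[j - 1] = back[j, path[j]]
    segments = []
    start = 0
    for j in range(1, L + 1):
        if j == L or path[j] != path[start]:
            amp = (
                int(matrix.column_ref_positions[start]),
                int(matrix.column_ref_positions[j - 1]) + 1,
            )
            segments.append((int(path[start]), (start, j), amp))
            start = j
    return Segmentation(state_path=path, segments=segments, matrix=matrix)


def call_events(segmentation: Segmentation, tset: TemplateSet) -> list[HDREvent]:
    """Call HDR events from template segments.

    A segment in a template state is an event when it contains at least two
    *consecutive* informative positions of that template (consecutive in
    the ordered list of that template's informative positions present in
    the read) at which the read carries the template allele.  Events whose
    entire support is shared between the two templates are labeled
    ``ambiguous_template`` instead of being attributed.
    """
    m = segmentation.matrix
    pos = m.column_ref_positions
    events: list[HDREvent] = []
    for state, (c0, c1), _ in segmentation.segments:
        if state == REF_STATE:
            continue
        tid = STATE_NAMES[state]
        info_set = set(tset.informative_positions(tid))
        # informative-for-tid columns anywhere in the read, ordered
        info_cols = [j for j in range(m.L) if int(pos[j]) in info_set]
        supporting = [
            j
            for j in info_cols
            if c0 <= j < c1 and m.matrix[state, j] == 1 and m.matrix[REF_STATE, j] == 0
        ]
        if len(supporting) < 2:
            continue
        sup_set = set(supporting)
        has_consecutive = any(
            a in sup_set and b in sup_set for a, b in zip(info_cols, info_cols[1:])
        )
        if not has_consecutive:
            continue
        all_shared = all(tset.is_shared_allele(int(pos[j])) for j in supporting)
        if all_shared:
            etype = "ambiguous_template"
        else:
            etype = "gene_conversion" if tid == "HOMOLOG" else "gene_correction"
        events.append(
            HDREvent(
                event_type=etype,
                template_id=tid,
                interval=(int(pos[supporting[0]]), int(pos[supporting[-1]]) + 1),
                n_supporting=len(supporting),
            )
        )
    segmentation.events = events
    return events


@dataclass
class ConversionTractProfile:
    positions: np.ndarray
    frequency: np.ndarray
    n_reads: np.ndarray


def tract_profile(segmentations: list[Segmentation], amplicon_length: int) -> ConversionTractProfile:
    """Per-position fraction of covering reads decoded as HOMOLOG.

    This is the conversion-tract profile: with asymmetric tracts the
    profile mass is skewed towards the preferentially converted arm.
    """
    if not segmentations:
        raise ValueError("no reads")
    cover = np.zeros(amplicon_length, dtype=np.int64)
    hom = np.zeros(amplicon_length, dtype=np.int64)
    for seg in segmentations:
        p = seg.matrix.column_ref_positions
        cover[p] += 1
        hom[p[seg.state_path == HOMOLOG_STATE]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(cover > 0, hom / np.maximum(cover, 1), 0.0)
    return ConversionTractProfile(
        positions=np.arange(amplicon_length), frequency=freq, n_reads=cover
    )
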