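"""End-to-end orchestration: reads -> alignments -> outcome tables.

``analyze_reads`` is the in-memory core used by tests and examples;
``run_pipeline`` wraps it with file I/O, a run log and deterministic
outputs for the CLI.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .alignment import (
    MergePolicy,
    SANGER_SCHEME,
    ScoringScheme,
    extract_indels,
    filter_primer_end_deletions,
    global_align,
    merge_pair,
    MergeFailure,
)
from .hdr import (
    DEFAULT_VITERBI_PARAMS,
    Segmentation,
    TemplateSet,
    ViterbiParams,
    build_template_set,
    call_events,
    encode_read,
    tract_profile,
    viterbi_segment,
)
from .io import (
    read_fasta,
    read_fastq,
    read_guides_tsv,
    write_insertion_annotations_tsv,
    write_kmer_histogram_tsv,
    write_outcomes_tsv,
    write_summary_json,
    write_tract_profile_tsv,
)
from .overhang import classify_insertion_match, kmer_position_histogram
from .reference import (
    Cas9Variant,
    OverhangPrediction,
    ReferenceAmplicon,
    locate_guide,
    predict_overhang,
)
from .report import OutcomeSummary, ReadOutcome, categorize_read, summarize

MIN_ALIGNED_FRACTION = 0.5  # of the inter-primer region


@dataclass
class SampleResult:
    outcomes: list[ReadOutcome]
    segmentations: list[Segmentation]
    summary: OutcomeSummary
    insertion_annotations: list[tuple[str, str, object]]
    overhang: Optional[OverhangPrediction]
    template_set: TemplateSet


def analyze_read(
    read_id: str,
    sequence: str,
    reference: ReferenceAmplicon,
    tset: TemplateSet,
    scheme: ScoringScheme = SANGER_SCHEME,
    viterbi_params: ViterbiParams = DEFAULT_VITERBI_PARAMS,
) -> tuple[ReadOutcome, Optional[Segmentation]]:
    """Full per-read analysis: align, call indels, attribute HDR templates."""
    aln = global_align(sequence, reference.sequence, scheme)
    indels = extract_indels(aln)
    indels, excluded = filter_primer_end_deletions(indels, reference)
    if excluded:
        return (
            categorize_read(read_id, indels, (), exclusion_reason="primer_end_deletion"),
            None,
        )
    matrix = encode_read(aln, tset)
    a, b = reference.inter_primer_interval
    n_inner = int(
        ((matrix.column_ref_positions >= a) & (matrix.column_ref_positions < b)).sum()
    )
    if n_inner < MIN_ALIGNED_FRACTION * (b - a):
        return (
            categorize_read(read_id, indels, (), exclusion_reason="poor_alignment"),
            None,
        )
    seg = viterbi_segment(matrix, viterbi_params)
    events = call_events(seg, tset)
    return categorize_read(read_id, indels, events), seg


def analyze_reads(
    reads: Sequence[tuple[str, str]],
    reference: ReferenceAmplicon,
    tset: TemplateSet,
    overhang: Optional[OverhangPrediction] = None,
    scheme: ScoringScheme = SANGER_SCHEME,
    viterbi_params: ViterbiParams = DEFAULT_VITERBI_PARAMS,
) -> SampleResult:
    outcomes: list[ReadOutcome] = []
    segmentations: list[Segmentation] = []
    annotations = []
    for read_id, sequence in reads:
        outcome, seg = analyze_read(read_id, sequence, reference, tset, scheme, viterbi_params)
        outcomes.append(outcome)
        if seg is not None:
            segmentations.append(seg)
        if overhang is not None and not outcome.excluded:
            for ev in outcome.indels:
                if ev.kind == "insertion":
                    annotations.append(
                        (read_id, ev.inserted_sequence, classify_insertion_match(ev.inserted_sequence, overhang.sequence))
                    )
    summary = summarize(outcomes, overhang)
    return SampleResult(
        outcomes=outcomes,
        segmentations=segmentations,
        summary=summary,
        insertion_annotations=annotations,
        overhang=overhang,
        template_set=tset,
    )


@dataclass
class RunConfig:
    reference_fasta: str
    guides_tsv: str
    templates_fasta: str
    reads_fastq: str
    output_dir: str
    reads_fastq2: Optional[str] = None
    variant: str = "D10A"
    primer_length: int = 20
    scheme: ScoringScheme = SANGER_SCHEME
    viterbi_params: ViterbiParams = DEFAULT_VITERBI_PARAMS
    merge_policy: MergePolicy = field(default_factory=MergePolicy)
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "reference_fasta": self.reference_fasta,
                "guides_tsv": self.guides_tsv,
                "templates_fasta": self.templates_fasta,
                "reads_fastq": self.reads_fastq,
                "reads_fastq2": self.reads_fastq2,
                "variant": self.variant,
                "primer_length": self.primer_length,
                "scheme": [self.scheme.match, self.scheme.mismatch, self.scheme.gap_open, self.scheme.gap_extend],
                "viterbi": [self.viterbi_params.epsilon, self.viterbi_params.tau, list(self.viterbi_params.priors)],
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and write the output bundle; returns the output dir.

    Outputs: per-read outcome TSV, summary JSON, insertion annotation TSV,
    4-mer position histogram TSV, conversion-tract profile TSV, overhang
    BED/JSON and a run log.  Outputs are deterministic for a fixed config.
    """
    for p in (config.reference_fasta, config.guides_tsv, config.templates_fasta, config.reads_fastq):
        if not Path(p).exists():
            raise PipelineError(f"input not found: {p}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = read_fasta(config.reference_fasta)
    if not fasta:
        raise PipelineError("reference FASTA is empty")
    ref_id, ref_seq = fasta[0]
    n = len(ref_seq)
    reference = ReferenceAmplicon(
        id=ref_id,
        sequence=ref_seq,
        primer_intervals=((0, config.primer_length), (n - config.primer_length, n)),
    )
    templates = dict(read_fasta(config.templates_fasta))
    if not {"HOMOLOG", "ODN"} <= set(templates):
        raise PipelineError("templates FASTA must contain records 'HOMOLOG' and 'ODN'")
    tset = build_template_set(reference, templates["HOMOLOG"], templates["ODN"], config.scheme)
    guides = [locate_guide(reference, spacer, gid) for gid, spacer in read_guides_tsv(config.guides_tsv)]
    variant = Cas9Variant.from_name(config.variant)
    overhang = None
    if len(guides) == 2:
        overhang = predict_overhang((guides[0], guides[1]), variant, reference)
    raw = read_fastq(config.reads_fastq)
    n_merge_failures = 0
    if config.reads_fastq2:
        raw2 = read_fastq(config.reads_fastq2)
        merged = []
        for (rid, s1, q1), (_, s2, q2) in zip(raw, raw2):
            try:
                seq, _ = merge_pair(s1, q1, s2, q2, config.merge_policy)
            except MergeFailure:
                n_merge_failures += 1
                continue
            merged.append((rid, seq))
        reads = merged
    else:
        reads = [(rid, seq) for rid, seq, _ in raw]
    if not reads:
        raise PipelineError("no analyzable reads")
    try:
        result = analyze_reads(reads, reference, tset, overhang, config.scheme, config.viterbi_params)
    except ValueError as exc:
        raise PipelineError(str(exc)) from exc
    chash = config.config_hash()
    write_outcomes_tsv(out / "outcomes.tsv", result.outcomes)
    write_summary_json(
        out / "summary.json",
        result.summary,
        extra={"config_hash": chash, "n_merge_failures": n_merge_failures},
    )
    write_insertion_annotations_tsv(out / "insertions.tsv", result.insertion_annotations)
    if overhang is not None:
        hist = kmer_position_histogram(
            [seq for _, seq, _ in result.insertion_annotations], overhang.sequence, k=4
        )
        write_kmer_histogram_tsv(out / "kmer_histogram.tsv", hist)
        (out / "overhang.json").write_text(overhang.to_json() + "\n")
        (out / "overhang.bed").write_text(overhang.to_bed(reference.id))
    if result.segmentations:
        profile = tract_profile(result.segmentations, len(ref_seq))
        write_tract_profile_tsv(out / "tract_profile.tsv", profile)
    log = {
        "package_version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "variant": config.variant,
        "n_reads_in": len(raw),
        "n_reads_analyzed": len(reads),
        "n_merge_failures": n_merge_failures,
        "n_excluded": result.summary.n_excluded,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return out
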