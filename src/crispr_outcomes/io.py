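"""File I/O: FASTA/FASTQ via Biopython, guide TSVs, result tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hdr import ConversionTractProfile
from .overhang import InsertionAnnotation, KmerPositionHistogram
from .report import OutcomeSummary, ReadOutcome


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
        str(path),
        "fasta",
    )


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            (rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"]))
        )
    return out


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, list[int]]]) -> None:
    records = []
    for rid, seq, quals in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_sam(
    path: str | Path,
    reference_id: str,
    reference_length: int,
    alignments: Iterable[tuple[str, str, str]],  # (read_id, read sequence, CIGAR)
) -> None:
    """Minimal SAM-flavored output of global read alignments.

    Every read is a forward-mapped primary alignment starting at position
    1 of the amplicon (alignments are global).  Readable with pysam or
    samtools for downstream inspection.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{reference_id}\tLN:{reference_length}\n")
        for read_id, seq, cigar in alignments:
            fh.write(f"{read_id}\t0\t{reference_id}\t1\t255\t{cigar}\t*\t0\t0\t{seq}\t*\n")


def read_guides_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Guide table: columns ``id`` and ``spacer``."""
    df = pd.read_csv(path, sep="\t")
    if not {"id", "spacer"} <= set(df.columns):
        raise ValueError("guides TSV must have 'id' and 'spacer' columns")
    return list(zip(df["id"].astype(str), df["spacer"].str.upper()))


def write_outcomes_tsv(path: str | Path, outcomes: list[ReadOutcome]) -> None:
    rows = []
    for o in outcomes:
        rows.append(
            {
                "read_id": o.read_id,
                "category": o.category,
                "n_insertions": sum(1 for e in o.indels if e.kind == "insertion"),
                "n_deletions": sum(1 for e in o.indels if e.kind == "deletion"),
                "hdr_events": ";".join(
                    f"{e.event_type}:{e.interval[0]}-{e.interval[1]}:{e.n_supporting}"
                    for e in o.hdr_events
                ),
                "complex": o.complex_indels,
                "exclusion_reason": o.exclusion_reason or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_json(path: str | Path, summary: OutcomeSummary, extra: Optional[dict] = None) -> None:
    payload = summary.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_insertion_annotations_tsv(
    path: str | Path, annotations: list[tuple[str, str, InsertionAnnotation]]
) -> None:
    rows = [
        {
            "read_id": rid,
            "insertion": seq,
            "length": len(seq),
            "match_class": ann.match_class,
            "overhang_copies": ann.overhang_copy_count,
            "microhomology": "" if ann.microhomology_length is None else ann.microhomology_length,
            "full_duplication": ann.full_duplication,
        }
        for rid, seq, ann in annotations
    ]
    pd.DataFrame(
        rows,
        columns=[
            "read_id", "insertion", "length", "match_class",
            "overhang_copies", "microhomology", "full_duplication",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_kmer_histogram_tsv(path: str | Path, hist: KmerPositionHistogram) -> None:
    pd.DataFrame(
        {"overhang_position": range(len(hist.counts)), "count": hist.counts}
    ).to_csv(path, sep="\t", index=False)


def write_tract_profile_tsv(path: str | Path, profile: ConversionTractProfile) -> None:
    pd.DataFrame(
        {
            "position": profile.positions,
            "gc_frequency": profile.frequency,
            "n_reads": profile.n_reads,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
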