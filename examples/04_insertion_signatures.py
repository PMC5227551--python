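"""Overhang-derived insertion signatures of the two nickase pairs.

Simulates insertion-only samples under the D10A preset (fragments of the
first 20 overhang nt, occasional complete duplications without junction
overlap) and the N863A preset (central fragments plus tandem overhang
repetitions joined through 2-8 nt microhomology), then classifies every
insertion against the predicted 47-nt overhang and tests the difference.
"""

from dataclasses import replace

from crispr_outcomes import (
    classify_insertion_match,
    fisher_exact_2x2,
    kmer_position_histogram,
)
from crispr_outcomes.simulate import make_toy_locus, preset_config, simulate_sample

locus = make_toy_locus()
overhang = locus.overhang().sequence
n = 300

stats = {}
for preset in ("D10A", "N863A"):
    cfg = replace(
        preset_config(preset, seed=7, locus=locus),
        mixture={"unmodified": 0.0, "deletion": 0.0, "insertion": 1.0,
                 "gene_conversion": 0.0, "gene_correction": 0.0},
    )
    reads, _ = simulate_sample(cfg, n)
    seqs = [ev.sequence for r in reads for ev in r.truth_events if ev.kind == "insertion"]
    anns = [classify_insertion_match(s, overhang) for s in seqs]
    matched = sum(a.match_class in ("partial", "full") for a in anns)
    dups = sum(a.full_duplication for a in anns)
    mh = [a.microhomology_length for a in anns if a.microhomology_length]
    stats[preset] = matched
    hist = kmer_position_histogram(seqs, overhang, k=4)
    peak = int(hist.counts.argmax())
    print(f"{preset}: {matched}/{n} insertions match the overhang "
          f"({100*matched/n:.1f}%), {dups} full duplications, "
          f"{len(mh)} with junctional microhomology "
          f"(median {sorted(mh)[len(mh)//2] if mh else 0} nt)")
    print(f"  4-mer histogram peak at overhang position {peak} "
          f"(D10A-type insertions pile up near the 5' end, N863A centrally)")

res = fisher_exact_2x2([[stats["N863A"], n - stats["N863A"]],
                        [stats["D10A"], n - stats["D10A"]]])
print(f"\nFisher test, overhang-match rate N863A vs D10A: p = {res.p_value:.3g}")
# A small p confirms the two lesion types leave distinguishable insertion
# signatures; junctional microhomology is the MMEJ hallmark of 3' overhangs.
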