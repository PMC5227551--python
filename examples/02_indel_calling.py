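"""Align edited reads to the amplicon and call indels.

Constructs three reads by hand — one with a clean cut-site deletion, one
with an overhang-derived insertion, and one primer-dimer-like artifact —
and shows the alignment CIGARs, the extracted events, and the primer-end
exclusion rule in action.
"""

from crispr_outcomes import (
    SANGER_SCHEME,
    extract_indels,
    filter_primer_end_deletions,
    global_align,
)
from crispr_outcomes.simulate import make_toy_locus

locus = make_toy_locus()
ref = locus.amplicon.sequence
lo, hi = locus.overhang().interval

reads = {
    "clean_deletion": ref[:lo] + ref[hi:],                       # nick-to-nick
    "overhang_insertion": ref[:lo] + ref[lo:hi][:15] + ref[lo:],  # 15-nt copy
    "primer_artifact": ref[:10] + ref[60:],                      # eats the primer
}

for name, read in reads.items():
    aln = global_align(read, ref, SANGER_SCHEME)
    events = extract_indels(aln)
    _, excluded = filter_primer_end_deletions(events, locus.amplicon)
    print(f"{name}: score={aln.score:.0f}")
    print(f"  cigar: {aln.cigar}")
    for ev in events:
        detail = ev.inserted_sequence if ev.kind == "insertion" else f"{ev.size} nt"
        print(f"  {ev.kind} at ref {ev.ref_interval}: {detail}")
    print(f"  read excluded (primer-end deletion): {excluded}")

# The scoring scheme (match 2, mismatch -1, gap open -50, gap extend -1)
# strongly favors one contiguous gap over scattered single-base gaps, so
# a repair product appears as a single indel event at the cut.
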