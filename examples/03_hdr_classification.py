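"""Attribute reads to HDR templates with the 3-state Viterbi decoder.

The toy locus has a homolog differing from the amplicon at 6 informative
positions and a 150-nt ssODN donor differing at 8.  Reads carrying two or
more consecutive template alleles are called gene conversion (homolog) or
gene correction (ssODN); a single isolated template allele is not called
(it is indistinguishable from sequencing error).
"""

from crispr_outcomes import (
    SANGER_SCHEME,
    build_template_set,
    call_events,
    encode_read,
    global_align,
    viterbi_segment,
)
from crispr_outcomes.simulate import make_toy_locus

locus = make_toy_locus()
tset = build_template_set(locus.amplicon, locus.homolog, locus.odn)
ref = locus.amplicon.sequence

print("informative positions")
print("  homolog:", tset.informative_positions("HOMOLOG"))
print("  ssODN:  ", tset.informative_positions("ODN"))

def analyze(name, read):
    aln = global_align(read, ref, SANGER_SCHEME)
    seg = viterbi_segment(encode_read(aln, tset))
    events = call_events(seg, tset)
    print(f"{name}: {len(events)} event(s)")
    for ev in events:
        print(f"  {ev.event_type} via {ev.template_id}, tract {ev.interval}, "
              f"{ev.n_supporting} supporting positions")

# a conversion tract copying three homolog alleles around the cut
tract = list(ref)
for p in locus.homolog_positions[1:4]:
    tract[p] = locus.homolog[p]
analyze("conversion_tract", "".join(tract))

# a single isolated homolog allele: not called
single = list(ref)
p = locus.homolog_positions[2]
single[p] = locus.homolog[p]
analyze("isolated_allele", "".join(single))

# an ssODN-templated correction copying the whole donor span
odn_start = min(tset.template_base["ODN"])
corrected = list(ref)
for p in locus.odn_positions:
    corrected[p] = locus.odn[p - odn_start]
analyze("ssodn_correction", "".join(corrected))
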