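"""Predict nick positions and the inter-nick overhang for a guide pair.

Builds the packaged toy locus (a ~600-nt amplicon with two PAM-out
protospacers 47 nt apart), places both guides, and prints the predicted
cut geometry for each Cas9 variant.  The D10A nickase pair leaves a 5'
overhang, N863A a 3' overhang, and WT excises the fragment blunt-ended.
"""

from crispr_outcomes import D10A, N863A, WT, predict_cut
from crispr_outcomes.simulate import make_toy_locus

locus = make_toy_locus()
left, right = locus.guides()

print(f"amplicon: {locus.amplicon.id}, {len(locus.amplicon.sequence)} nt")
for g in (left, right):
    print(f"guide {g.id}: strand {g.strand}, protospacer {g.protospacer_interval}, "
          f"PAM {g.pam_interval}")
    for variant in (WT, D10A, N863A):
        ns = predict_cut(g, variant)
        print(f"  {variant.name:6s} nicks: {ns.nicks} blunt={ns.blunt}")

for variant in (D10A, N863A, WT):
    ov = locus.overhang(variant)
    print(f"\n{variant.name}: {ov.polarity} overhang, {ov.length} nt, "
          f"{ov.pam_configuration}, strand separation expected: "
          f"{ov.strand_separation_expected}")
    print(f"  sequence: {ov.sequence}")

# The 47-nt inter-nick sequence is the substrate for the insertion
# signatures analyzed in example 04; its length equals the distance
# between the two predicted nicks (3 nt 5' of each PAM).
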