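# Methods

## Coordinate conventions

All coordinates are 0-based, half-open, on the amplicon top strand. A
nick *position* names the phosphodiester bond 5′ of that coordinate, so a
nick at `p` separates bases `p−1` and `p`, and a deletion interval
`(a, b)` removes exactly the bases a read would lose between two nicks at
`a` and `b`. This makes overhang length, deletion width and the
precise-deletion test pure interval arithmetic.

## Cut-site and overhang model

The cleavage rule is a single offset: the cut lies 3 nt 5′ of the NGG PAM
start, measured on the guide's strand, i.e. between protospacer bases 17
and 18 of a 20-nt spacer. The same offset is applied to both the HNH nick
(target strand — the strand base-paired with the gRNA) and the RuvC nick
(non-target strand), so a wild-type cut is blunt. The RuvC offset is a
modeling choice — in vitro it can wander — but a single rule keeps the
two nickase variants exactly mirror-symmetric, which is what the
polarity table expresses:

| variant | PAM-out | PAM-in |
|---------|---------|--------|
| D10A    | 5′ overhang | 3′ overhang |
| N863A   | 3′ overhang | 5′ overhang |
| WT      | blunt ends (no polarity) | blunt ends |

PAM-in pairs still get a predicted overhang interval (needed for
precise-deletion bookkeeping) but `strand_separation_expected=False`: the
double-stranded PAMs sit between the two R-loops and are thought to act
as a topological barrier, and empirically PAM-in pairs modify the locus
poorly. A wild-type pair with distinct cuts excises a blunt duplex
fragment, so its polarity is reported as `none` rather than `blunt`;
`blunt` is reserved for a zero-width inter-nick interval.

Spacer placement is exact-match only (both strands, NGG only). Off-target
and mismatch-tolerant search is out of scope.

## Alignment

Reads are aligned globally (Needleman–Wunsch) with affine gaps under
match 2, mismatch −1, gap open −50, gap extend −1; the first base of a
gap is charged the open penalty, each further base the extend penalty.
The dominant gap-open penalty makes a contiguous cut-site indel strongly
preferred over scattered gaps, which is the correct prior for repair
products. The engine is Biopython's `PairwiseAligner`; tests validate its
scores against an independent full-matrix Gotoh DP on random instances.
An EMBOSS-needle-like scheme (1/−1/−10/−0.5) is selectable.

Two caveats follow from optimal alignment rather than from this
implementation: (i) an indel inside a repeat has ambiguous placement (the
engine's deterministic traceback picks one); the toy locus deliberately
breaks this ambiguity at the nick boundaries so nick-to-nick deletions
are recovered at their exact interval; (ii) two nearby opposite-sign
indels can be collapsed into one indel plus mismatches when that scores
better — the round-trip tests therefore check reconstruction up to
substitution columns.

Reads whose deletions overlap a primer footprint are excluded wholesale
(primer-dimer artifacts); insertions at the ends are untouched. Reads
aligning over less than 50% of the inter-primer region are dropped with a
counted reason. Paired-end mates are merged by best ungapped overlap
(≥ 10 nt, mismatch fraction ≤ 0.1, higher-quality base wins
disagreements); this is a deliberately simple consensus merger, not a
reimplementation of any particular published merger.

## HDR template attribution

Donor templates are aligned to the amplicon with free end gaps (the ssODN
covers only a 150-nt span). A position is *informative* for a template
where the aligned bases differ by a substitution; positions opposite
template gaps carry no evidence. Each read becomes a 3 × L binary matrix
over states (REF, HOMOLOG, ODN) with a defined-mask for template
coverage.

The decoder is a 3-state HMM Viterbi pass in log space:

- emission: `1−ε` where the read matches the state's base, `ε` where it
  mismatches, 1 (no evidence) where the state has no aligned base. A read
  base matching none of the three sequences is an all-mismatch column
  (emission ε in every state) — it penalizes all states equally except
  through the defined-mask.
- transitions: stay `1−2τ`, switch `τ` to each other state.
- the prior (REF 0.98, others 0.01) is applied at *both* ends of the
  read: amplicon reads begin and end in primer-anchored reference
  sequence, so a template segment must pay a switch on the way out too.
  Without the terminal prior the decoded segment would trail to the read
  end once past the last informative site.

**Parameter choice.** ε = 0.01 approximates amplicon-sequencing
substitution error. τ controls the calling threshold: a switch costs
`2·log((1−2τ)/τ)` in log odds while each supporting informative column
contributes `log((1−ε)/ε)` ≈ 4.6. Any τ in (e⁻⁴·⁶, e⁻²·³) ≈
(0.010, 0.100) makes exactly two consecutive supporting columns flip the
path and one insufficient; the default τ = 0.03 sits centrally in that
window, making the two-consecutive-informative-base calling rule an
emergent property of the decoder rather than a bolted-on filter. Both
parameters are exposed.

Equal-likelihood paths are disambiguated twice: argmax ties prefer the
lower state index (REF first), and an infinitesimal (1e-9) per-column
penalty on template states trims segments to their first-to-last
supporting column, so reported tract bounds are the supporting span
rather than drifting across emission-neutral columns.

Event calling requires a template segment to contain ≥ 2 *consecutive*
informative positions (consecutive in that template's informative-position
order as present in the read) where the read carries the template allele
and not the reference allele. Events whose entire support is shared
between homolog and ssODN (same non-reference allele at the same
coordinates) are labeled `ambiguous_template` rather than guessed.

Per-read categories are mutually exclusive with precedence
gene_correction > gene_conversion > ambiguous_template > insertion >
deletion > unmodified — HDR calls are rarer and more specific than
indels. Reads with both an insertion and a deletion count once under the
precedence but are also reported in a `complex` column.

## Insertion and overhang analytics

- match classes: `full` (complete overhang contained), `partial` (≥ 1
  shared exact 9-mer), `none`. Matching is exact, case-insensitive, top
  strand (a reverse-complement flag exists for exploration).
- overhang copies are counted by leftmost non-overlapping scanning.
- junctional microhomology: two tandem copies sharing an m-nt junction
  appear as `overhang + overhang[m:]`. The *smallest* m whose pattern
  occurs is reported — it corresponds to the longest double-copy block
  physically present, and keeps an exact tandem (m = 0) from being
  misread through the overhang's own suffix/prefix self-overlap (the
  canonical 47-mer ends and begins with `TC`).
- `full_duplication` means a complete copy sits flush at an insertion
  end, i.e. inserting it at a nick reconstitutes a tandem copy at the
  locus.
- 4-mer position histograms count every insertion k-mer occurrence that
  matches the overhang at exactly one position; k-mers occurring more
  than once in the overhang are excluded as unmappable.
- Fisher's exact test is two-sided by the point-probability method
  (scipy); the permutation test uses difference of means, exhaustive when
  C(na+nb, na) ≤ 20 000 and otherwise 10 000 seeded Monte-Carlo draws
  with the observed split included.

## Synthetic data

The toy locus is a fixed pseudo-random 600-nt amplicon (20-nt primer
footprints) embedding the canonical 47-nt overhang between a minus-strand
and a plus-strand protospacer in PAM-out orientation. The homolog is a
full-length copy with 6 planted transition mismatches (two left of the
nicks, two inside the overhang, two right — echoing a paralog whose
differences straddle the cut); the ssODN is a 150-nt window centered on
the cut with 8 planted mismatches at positions disjoint from the
homolog's. Both counts are configurable; the overhang's outer flanking
bases are chosen to differ from its terminal bases so nick-to-nick
deletions align unambiguously.

Reads are drawn i.i.d. from a category mixture; every read carries truth
labels that reconstruct it exactly before error injection.

- deletions: geometric sizes (median 3 nt, the small-indel regime of a
  blunt DSB) or a shifted negative binomial (median ≈ 28–36 nt for
  dual-nick presets), centered on the cut with Gaussian jitter (σ = 4);
  an exact nick-to-nick deletion is emitted with the preset's
  `precise_probability` (0.303 in the TREX2-style preset, 0 otherwise),
  and jittered deletions never collide with the exact interval.
- insertions at the left nick: the D10A preset draws fragments uniformly
  from the first 20 overhang nt (3–20 nt long) with a 12% chance of a
  complete duplication; the N863A preset draws central fragments
  (9–30 nt, start ≥ 10) with 40% tandem repetitions joined through a
  2–8 nt junction overlap and 15% single full copies. Source offsets are
  uniform within their regions, a deliberate simplification.
- gene conversion always copies the homolog across the inter-nick
  interval and extends beyond the left/right nick with probability
  0.25/0.10 (geometric extensions, means 45/15 nt) — about 32% of tracts
  extend beyond a nick, and the left arm converts farther than the right
  (asymmetric homology search).
- gene correction copies the ssODN alleles over its span (70% full span,
  30% central tract).
- sequencing error is i.i.d. per-base substitution (default 0; presets
  are exercised at 0.005 in tests); qualities are constant Q30 — quality
  modeling is not the point of this artifact.

Condition presets package the frequency structure of the three Cas9
variants (small-deletion-dominated WT with moderate conversion;
conversion-rich D10A; insertion-rich N863A), plus TREX2-style
precise-deletion enrichment and an ssODN condition.

**What passing tests show — and don't.** Mixture recovery at n = 5000
(error-free within per-category exact binomial 99% intervals; ≤ 0.02
absolute at error 0.005) demonstrates that the pipeline inverts its own
generative model essentially without bias. It does not demonstrate
robustness to PCR chimeras, sequencer-specific error profiles,
context-dependent indel artifacts, heteroduplex or large structural
products — none of which the generator emulates. Real-data frequency
tables are population measurements and are not reproducible from
synthetic reads; what is reproducible is the machinery: geometry rules,
oracle-checked algorithms, signature direction and enrichment logic.

## Numerical and testing choices

- All HMM arithmetic is in log space; alignment scores are exact floats.
- Every stochastic component takes an explicit integer seed; identical
  config + seed reproduces outputs byte-for-byte (hashed in tests).
- Oracles: alignment scores vs a full-matrix Gotoh DP (lengths ≤ 40);
  Viterbi vs exhaustive 3^L path enumeration (L ≤ 12, with terminal
  priors); Fisher p vs exact rational hypergeometric enumeration (all
  tables N ≤ 40, agreement to 1e-12); permutation p vs explicit split
  enumeration. Problem sizes for the simulation-based checks (n = 2000
  per condition, n = 5000 for mixture recovery, 300 insertions per
  signature arm) were chosen to make the binomial intervals tight enough
  to be informative while keeping the default suite quick to run.

## Known limitations

- The two-template (3-state) model does not generalize to > 2 donors.
- Viterbi only: no posterior (forward–backward) probabilities.
- Insertions are only matched against the predicted overhang, not
  searched genome-wide for templated sources.
- The merger is overlap-based and ungapped; indels inside the overlap of
  a read pair will fail the mismatch threshold rather than be resolved.
- Replicate-level statistics (error bars across biological replicates)
  are out of scope; summaries are per-sample.
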