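"""Template attribution: informative positions, matrix encoding, Viterbi."""

import warnings

import numpy as np
import pytest
from scipy import stats

from crispr_outcomes.alignment import SANGER_SCHEME, global_align
from crispr_outcomes.hdr import (
    DEFAULT_VITERBI_PARAMS,
    HOMOLOG_STATE,
    ODN_STATE,
    REF_STATE,
    ReadMatchMatrix,
    TemplateWarning,
    ViterbiParams,
    build_template_set,
    call_events,
    emission_log_likelihoods,
    encode_read,
    tract_profile,
    viterbi_segment,
)
from crispr_outcomes.pipeline import analyze_reads
from crispr_outcomes.simulate import SimulationConfig, make_toy_locus, simulate_sample

from oracles import enumerate_viterbi


class TestBuildTemplateSet:
    def test_planted_homolog_mismatches_recovered(self, locus, template_set):
        assert tuple(template_set.informative_positions("HOMOLOG")) == locus.homolog_positions
        for ip in template_set.informative["HOMOLOG"]:
            assert ip.ref_base != ip.template_base

    def test_planted_odn_mismatches_recovered(self, locus, template_set):
        assert tuple(template_set.informative_positions("ODN")) == locus.odn_positions

    def test_identical_template_warns(self, locus):
        with pytest.warns(TemplateWarning, match="indistinguishable"):
            build_template_set(locus.amplicon, locus.homolog, locus.amplicon.sequence)

    def test_template_internal_deletion_excludes_positions(self, locus):
        seq = locus.amplicon.sequence
        homolog = seq[:300] + seq[310:]  # 10-nt gap opposite amplicon 300..310
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tset = build_template_set(locus.amplicon, homolog, locus.odn)
        gap_positions = set(range(300, 310))
        assert not gap_positions & set(tset.template_base["HOMOLOG"])
        assert not gap_positions & set(tset.informative_positions("HOMOLOG"))

    def test_odn_defined_only_over_its_span(self, locus, template_set):
        covered = sorted(template_set.template_base["ODN"])
        assert covered[-1] - covered[0] + 1 == len(locus.odn)
        assert len(covered) == len(locus.odn)


class TestEncodeRead:
    def test_reference_read_matches_ref_row(self, locus, template_set):
        ref = locus.amplicon.sequence
        aln = global_align(ref, ref, SANGER_SCHEME)
        m = encode_read(aln, template_set)
        assert m.L == len(ref)
        assert (m.matrix[REF_STATE] == 1).all()
        hom_cols = np.isin(m.column_ref_positions, locus.homolog_positions)
        assert (m.matrix[HOMOLOG_STATE, hom_cols] == 0).all()
        assert not m.defined[ODN_STATE, 0]  # outside the ssODN span

    def test_homolog_allele_flips_column(self, locus, template_set):
        ref = locus.amplicon.sequence
        p = locus.homolog_positions[0]
        read = ref[:p] + locus.homolog[p] + ref[p + 1 :]
        m = encode_read(global_align(read, ref, SANGER_SCHEME), template_set)
        col = int(np.flatnonzero(m.column_ref_positions == p)[0])
        assert m.matrix[REF_STATE, col] == 0
        assert m.matrix[HOMOLOG_STATE, col] == 1

    def test_deletion_removes_columns(self, locus, template_set):
        ref = locus.amplicon.sequence
        p1, p2 = locus.homolog_positions[2], locus.homolog_positions[3]
        read = ref[: p1 - 2] + ref[p2 + 3 :]
        m = encode_read(global_align(read, ref, SANGER_SCHEME), template_set)
        assert m.L == len(read)
        assert not np.isin([p1, p2], m.column_ref_positions).any()

    def test_error_base_matching_nothing_gives_zero_column(self, locus, template_set):
        ref = locus.amplicon.sequence
        p = locus.homolog_positions[1]
        wrong = next(b for b in "ACGT" if b not in (ref[p], locus.homolog[p]))
        read = ref[:p] + wrong + ref[p + 1 :]
        m = encode_read(global_align(read, ref, SANGER_SCHEME), template_set)
        col = int(np.flatnonzero(m.column_ref_positions == p)[0])
        assert m.matrix[REF_STATE, col] == 0 and m.matrix[HOMOLOG_STATE, col] == 0


def _matrix(cols, defined=None, positions=None):
    arr = np.array(cols, dtype=np.int8).T
    L = arr.shape[1]
    dfn = np.ones_like(arr, dtype=bool) if defined is None else np.array(defined, dtype=bool).T
    pos = np.arange(L) if positions is None else np.asarray(positions)
    return ReadMatchMatrix(matrix=arr, defined=dfn, column_ref_positions=pos)


REFCOL = (1, 0, 0)
ODNCOL = (0, 0, 1)
HOMCOL = (0, 1, 0)


class TestViterbi:
    def test_all_reference_matrix_stays_reference(self):
        m = _matrix([REFCOL] * 8)
        seg = viterbi_segment(m)
        assert (seg.state_path == REF_STATE).all()
        assert len(seg.segments) == 1

    def test_odn_block_is_decoded(self):
        cols = [REFCOL] * 4 + [ODNCOL] * 3 + [REFCOL] * 3
        seg = viterbi_segment(_matrix(cols))
        assert list(seg.state_path) == [0] * 4 + [2] * 3 + [0] * 3

    def test_single_isolated_column_not_switched(self):
        cols = [REFCOL] * 5 + [HOMCOL] + [REFCOL] * 5
        seg = viterbi_segment(_matrix(cols))
        assert (seg.state_path == REF_STATE).all()

    def test_two_consecutive_columns_switch(self):
        cols = [REFCOL] * 4 + [HOMCOL] * 2 + [REFCOL] * 4
        seg = viterbi_segment(_matrix(cols))
        assert (seg.state_path[4:6] == HOMOLOG_STATE).all()
        assert (seg.state_path[:4] == REF_STATE).all()
        assert (seg.state_path[6:] == REF_STATE).all()

    def test_oracle_equivalence_random_matrices(self):
        """Viterbi path matches exhaustive 3^L enumeration on 500 random
        matrices with L <= 12 (score always; path when the optimum is
        unique)."""
        rng = np.random.default_rng(77)
        params = DEFAULT_VITERBI_PARAMS
        trans = np.full((3, 3), np.log(params.tau))
        np.fill_diagonal(trans, np.log1p(-2 * params.tau))
        log_priors = np.log(np.asarray(params.priors))
        for _ in range(500):
            L = int(rng.integers(1, 13))
            mat = rng.integers(0, 2, size=(3, L)).astype(np.int8)
            dfn = rng.random((3, L)) < 0.8
            dfn[0] = True
            m = ReadMatchMatrix(matrix=mat, defined=dfn, column_ref_positions=np.arange(L))
            seg = viterbi_segment(m, params)
            em = emission_log_likelihoods(m, params)
            best, path, unique = enumerate_viterbi(em, log_priors, trans)
            got = log_priors[seg.state_path[0]] + em[seg.state_path[0], 0]
            for j in range(1, L):
                got += trans[seg.state_path[j - 1], seg.state_path[j]] + em[seg.state_path[j], j]
            got += log_priors[seg.state_path[-1]]
            assert got == pytest.approx(best, abs=1e-9)
            if unique:
                assert list(seg.state_path) == list(path)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ViterbiParams(epsilon=0.7)
        with pytest.raises(ValueError):
            ViterbiParams(priors=(0.5, 0.1, 0.1))
        with pytest.raises(ValueError):
            viterbi_segment(ReadMatchMatrix(
                matrix=np.zeros((3, 0), dtype=np.int8),
                defined=np.zeros((3, 0), dtype=bool),
                column_ref_positions=np.zeros(0, dtype=int),
            ))


class TestCallEvents:
    def _run(self, locus, tset, read):
        aln = global_align(read, locus.amplicon.sequence, SANGER_SCHEME)
        seg = viterbi_segment(encode_read(aln, tset))
        return call_events(seg, tset)

    def test_three_consecutive_homolog_positions_called(self, locus, template_set):
        ref = locus.amplicon.sequence
        read = list(ref)
        for p in locus.homolog_positions[1:4]:
            read[p] = locus.homolog[p]
        events = self._run(locus, template_set, "".join(read))
        assert [e.event_type for e in events] == ["gene_conversion"]
        assert events[0].n_supporting == 3
        assert events[0].interval == (locus.homolog_positions[1], locus.homolog_positions[3] + 1)

    def test_single_position_not_called(self, locus, template_set):
        ref = locus.amplicon.sequence
        p = locus.homolog_positions[2]
        read = ref[:p] + locus.homolog[p] + ref[p + 1 :]
        assert self._run(locus, template_set, read) == []

    def test_two_consecutive_positions_called_one_not(self, locus, template_set):
        """The two-consecutive-informative-base rule as an emergent
        property of the decoder under default parameters."""
        ref = locus.amplicon.sequence
        read = list(ref)
        for p in locus.homolog_positions[2:4]:
            read[p] = locus.homolog[p]
        events = self._run(locus, template_set, "".join(read))
        assert [e.event_type for e in events] == ["gene_conversion"]

    def test_nonconsecutive_positions_not_called(self, locus, template_set):
        ref = locus.amplicon.sequence
        read = list(ref)
        # positions 1 and 3: informative but with an intervening reference-
        # matching informative position 2
        for p in (locus.homolog_positions[1], locus.homolog_positions[3]):
            read[p] = locus.homolog[p]
        events = self._run(locus, template_set, "".join(read))
        assert events == []

    def test_both_templates_emit_separate_events(self, locus, template_set):
        ref = locus.amplicon.sequence
        read = list(ref)
        for p in locus.homolog_positions[4:6]:   # right of the ssODN span
            read[p] = locus.homolog[p]
        odn_a = min(template_set.template_base["ODN"])
        for p in locus.odn_positions[:2]:
            read[p] = locus.odn[p - odn_a]
        events = self._run(locus, template_set, "".join(read))
        assert sorted(e.event_type for e in events) == ["gene_conversion", "gene_correction"]

    def test_shared_allele_support_is_ambiguous(self, locus, template_set):
        """An event supported only by alleles common to both templates
        cannot be attributed."""
        ref = list(locus.amplicon.sequence)
        # construct a template set where two ODN positions carry the same
        # alleles as the homolog at the same coordinates
        p1, p2 = locus.homolog_positions[2], locus.homolog_positions[3]
        mid = (locus.overhang().interval[0] + locus.overhang().interval[1]) // 2
        odn_a = mid - 75
        odn = list(locus.amplicon.sequence[odn_a : odn_a + 150])
        odn[p1 - odn_a] = locus.homolog[p1]
        odn[p2 - odn_a] = locus.homolog[p2]
        tset = build_template_set(locus.amplicon, locus.homolog, "".join(odn))
        read = list(locus.amplicon.sequence)
        read[p1] = locus.homolog[p1]
        read[p2] = locus.homolog[p2]
        events = self._run(locus, tset, "".join(read))
        assert len(events) == 1
        assert events[0].event_type == "ambiguous_template"

    def test_added_consecutive_support_never_removes_event(self, locus, template_set):
        ref = locus.amplicon.sequence
        read = list(ref)
        for p in locus.homolog_positions[2:4]:
            read[p] = locus.homolog[p]
        assert len(self._run(locus, template_set, "".join(read))) == 1
        for p in locus.homolog_positions[1:2]:
            read[p] = locus.homolog[p]
        events = self._run(locus, template_set, "".join(read))
        assert len(events) == 1 and events[0].n_supporting == 3


class TestTractProfile:
    def test_all_reference_reads_zero_profile(self, locus, template_set):
        ref = locus.amplicon.sequence
        aln = global_align(ref, ref, SANGER_SCHEME)
        segs = [viterbi_segment(encode_read(aln, template_set)) for _ in range(5)]
        prof = tract_profile(segs, len(ref))
        assert (prof.frequency == 0).all()
        assert (prof.n_reads == 5).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no reads"):
            tract_profile([], 100)

    def test_planted_tract_fraction_recovered(self, locus, template_set):
        """30% of reads carry a homolog tract: the profile sits near 0.3
        inside the tract and near 0 outside."""
        ref = locus.amplicon.sequence
        a, b = locus.homolog_positions[1], locus.homolog_positions[3]
        converted = list(ref)
        for p in locus.homolog_positions[1:4]:
            converted[p] = locus.homolog[p]
        converted = "".join(converted)
        segs = []
        for i in range(100):
            read = converted if i < 30 else ref
            aln = global_align(read, ref, SANGER_SCHEME)
            segs.append(viterbi_segment(encode_read(aln, template_set)))
        prof = tract_profile(segs, len(ref))
        inside = prof.frequency[(prof.positions >= a) & (prof.positions <= b)]
        outside_left = prof.frequency[prof.positions < locus.homolog_positions[0]]
        assert inside.mean() == pytest.approx(0.3, abs=0.02)
        assert outside_left.max() == 0.0

    def test_asymmetric_tracts_skew_profile_left(self, locus, template_set, overhang):
        """Simulated conversion tracts with a longer left arm put more
        profile mass left of the nicks than right of them."""
        cfg = SimulationConfig(
            locus=locus,
            mixture={"unmodified": 0.3, "gene_conversion": 0.7},
            seed=5,
        )
        reads, truth = simulate_sample(cfg, 400)
        gc = truth[truth.truth_category == "gene_conversion"]
        assert gc.tract_left_arm.mean() > gc.tract_right_arm.mean()
        res = analyze_reads(
            [(r.read_id, r.sequence) for r in reads], locus.amplicon, template_set, overhang
        )
        prof = tract_profile(res.segmentations, len(locus.amplicon.sequence))
        lo, hi = overhang.interval
        left_mass = prof.frequency[:lo].sum()
        right_mass = prof.frequency[hi:].sum()
        assert left_mass > right_mass


class TestGCFractionRecovery:
    @pytest.mark.parametrize("p", [0.05, 0.15, 0.30])
    def test_called_fraction_within_binomial_99ci(self, locus, template_set, overhang, p):
        """Planted gene-conversion fractions are recovered by the full
        pipeline within the exact binomial 99% interval (error-free reads,
        n=2000)."""
        n = 2000
        cfg = SimulationConfig(
            locus=locus,
            mixture={"unmodified": 1.0 - p, "gene_conversion": p},
            error_rate=0.0,
            seed=int(p * 1000),
        )
        reads, _ = simulate_sample(cfg, n)
        res = analyze_reads(
            [(r.read_id, r.sequence) for r in reads], locus.amplicon, template_set, overhang
        )
        called = res.summary.counts["gene_conversion"]
        lo, hi = stats.binom.interval(0.99, n, p)
        assert lo <= called <= hi
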