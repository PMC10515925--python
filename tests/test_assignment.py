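import numpy as np
import pytest

from biasbench.assignment import (
    AllelicContext,
    Call,
    assign_reads,
    build_all_contexts,
    build_context,
    cohort_assign,
    context_assign,
    naive_assign,
)
from biasbench.core import Alignment
from biasbench.fixtures import (
    TruthTable,
    build_diploid_consensus,
    plant_tandem_repeat,
    random_reference,
    simulate_reads,
    perfect_align,
)
from biasbench.variants import PhasedVariant, build_cohorts


def mk_read(pos, seq, cigar=None, read_id="r", mate=1, mapq=42):
    return Alignment(read_id, mate, "chrS", pos, cigar or [("M", len(seq))], seq, mapq)


class TestNaiveAssign:
    def setup_method(self):
        _, self.ref = random_reference(1000, seed=3)

    def test_snv_alt_base(self):
        ref_b = self.ref[500]
        alt_b = "G" if ref_b != "G" else "A"
        v = PhasedVariant("chrS", 501, ref_b, alt_b, (0, 1))
        seq = self.ref[480:500] + alt_b + self.ref[501:520]
        assert naive_assign(mk_read(480, seq), v).call == Call.ALT

    def test_snv_ref_base(self):
        ref_b = self.ref[500]
        alt_b = "G" if ref_b != "G" else "A"
        v = PhasedVariant("chrS", 501, ref_b, alt_b, (0, 1))
        assert naive_assign(mk_read(480, self.ref[480:520]), v).call == Call.REF

    def test_snv_error_base_other(self):
        ref_b = self.ref[500]
        others = [b for b in "ACGT" if b != ref_b]
        v = PhasedVariant("chrS", 501, ref_b, others[0], (0, 1))
        seq = self.ref[480:500] + others[1] + self.ref[501:520]
        assert naive_assign(mk_read(480, seq), v).call == Call.OTHER

    def test_shifted_deletion_gap_miscounts(self):
        """Gap placement differing from the VCF defeats the naive method: a
        partially shifted gap yields OTHER, and in a perfect tandem repeat a
        fully shifted gap even makes the ALT read look like REF."""
        ref = "AAAT" + "ATTC" * 7 + "GCCA" * 4
        v = PhasedVariant("chrS", 4, ref[3 : 3 + 5], ref[3], (0, 1))  # del one unit
        # gap shifted right by 2: deletes ref[6:10], straddling the footprint
        seq = ref[0:6] + ref[10:30]
        partial = mk_read(0, seq, [("M", 6), ("D", 4), ("M", len(seq) - 6)])
        assert naive_assign(partial, v).call == Call.OTHER
        # gap shifted fully out of the footprint (deletes ref[8:12]): the
        # footprint reads as REF even though the read carries the deletion
        seq2 = ref[0:8] + ref[12:30]
        full = mk_read(0, seq2, [("M", 8), ("D", 4), ("M", len(seq2) - 8)])
        assert naive_assign(full, v).call == Call.REF

    def test_non_overlapping_read_raises(self):
        v = PhasedVariant("chrS", 501, self.ref[500], "G", (0, 1))
        with pytest.raises(ValueError):
            naive_assign(mk_read(0, self.ref[0:100]), v)


class TestBuildContext:
    def test_isolated_snv_minimal_span(self):
        _, ref = random_reference(1000, seed=4)
        b = ref[500]
        alt = "G" if b != "G" else "A"
        v = PhasedVariant("chrS", 501, b, alt, (0, 1))
        ctx = build_context(v, ref)
        assert ctx.span == (500, 501)
        assert not ctx.extended and not ctx.disregarded
        assert len(ctx.ref_context) == 11
        assert ctx.ref_context[5] == b and ctx.alt_context[5] == alt

    def test_tandem_repeat_extends_over_tract(self):
        _, ref = random_reference(1000, seed=4)
        ref, (ts, te) = plant_tandem_repeat(ref, 500, "ATTC", 7)
        v = PhasedVariant("chrS", ts, ref[ts - 1 : ts + 4], ref[ts - 1], (0, 1))
        ctx = build_context(v, ref)
        assert ctx.extended and not ctx.disregarded
        s, e = ctx.span
        assert s <= ts - 1 and e >= te  # covers the whole repeat tract
        assert ctx.ref_core not in ctx.alt_core and ctx.alt_core not in ctx.ref_core

    def test_long_repeat_disregarded_past_cap(self):
        _, ref = random_reference(1000, seed=4)
        ref, (ts, te) = plant_tandem_repeat(ref, 500, "ATTC", 20)  # 80 bp tract
        v = PhasedVariant("chrS", ts, ref[ts - 1 : ts + 4], ref[ts - 1], (0, 1))
        ctx = build_context(v, ref)
        assert ctx.disregarded

    def test_contig_end_disregarded(self):
        ref = "ATTC" * 10  # repeat runs to both contig ends
        v = PhasedVariant("chrS", 1, "ATTCA", "A", (0, 1))
        ctx = build_context(v, ref)
        assert ctx.disregarded

    def test_contexts_not_substrings_of_each_other(self, world, world_contexts):
        for ctx in world_contexts.values():
            if ctx.disregarded:
                continue
            assert ctx.ref_context != ctx.alt_context
            shorter, longer = sorted(
                [ctx.ref_context, ctx.alt_context], key=len
            )
            assert shorter not in longer

    def test_phased_neighbor_in_flank(self):
        """A phased SNV within 5 bp appears, phased, in the neighbor flank."""
        _, ref = random_reference(1000, seed=4)
        b1, b2 = ref[500], ref[503]
        a1 = "G" if b1 != "G" else "A"
        a2 = "T" if b2 != "T" else "C"
        v1 = PhasedVariant("chrS", 501, b1, a1, (0, 1))
        v2 = PhasedVariant("chrS", 504, b2, a2, (0, 1))  # same phase: hap2
        ctx = build_context(v1, ref, [v2])
        # ALT context (hap2) carries v2's ALT in the right flank
        assert ctx.alt_context[5 + 3] == a2
        assert ctx.ref_context[5 + 3] == b2

    def test_hom_variant_rejected(self):
        _, ref = random_reference(100, seed=4)
        v = PhasedVariant("chrS", 50, ref[49], "G" if ref[49] != "G" else "A", (1, 1))
        with pytest.raises(ValueError):
            build_context(v, ref)


class TestContextAssign:
    def _snv_world(self):
        _, ref = random_reference(1000, seed=6)
        b = ref[500]
        alt = "G" if b != "G" else "A"
        v = PhasedVariant("chrS", 501, b, alt, (0, 1))
        ctx = build_context(v, ref)
        return ref, v, ctx, alt

    def test_spanning_reads_follow_haplotype(self):
        ref, v, ctx, alt = self._snv_world()
        ref_read = mk_read(470, ref[470:530])
        alt_read = mk_read(470, ref[470:500] + alt + ref[501:530])
        assert context_assign(ref_read, ctx).call == Call.REF
        assert context_assign(alt_read, ctx).call == Call.ALT

    def test_left_anchor_prefix_suffices(self):
        """Read ending 2 bp into the right flank still resolves via the left
        anchor."""
        ref, v, ctx, alt = self._snv_world()
        read = mk_read(470, ref[470:500] + alt + ref[501:503])
        ra = context_assign(read, ctx)
        assert ra.call == Call.ALT and ra.anchor == "left"

    def test_right_anchor_used_when_left_unavailable(self):
        ref, v, ctx, alt = self._snv_world()
        read = mk_read(500, alt + ref[501:550])
        ra = context_assign(read, ctx)
        assert ra.call == Call.ALT

    def test_sequencing_error_in_window_is_other(self):
        ref, v, ctx, alt = self._snv_world()
        third = next(b for b in "ACGT" if b not in (v.ref, v.alt))
        read = mk_read(470, ref[470:500] + third + ref[501:530])
        assert context_assign(read, ctx).call == Call.OTHER

    def test_n_base_in_window_is_other(self):
        ref, v, ctx, alt = self._snv_world()
        read = mk_read(470, ref[470:500] + "N" + ref[501:530])
        assert context_assign(read, ctx).call == Call.OTHER

    def test_partial_repeat_coverage_is_both(self):
        """A read covering only part of a repeat-extended variant is BOTH."""
        _, ref = random_reference(1000, seed=6)
        ref, (ts, te) = plant_tandem_repeat(ref, 500, "ATTC", 7)
        v = PhasedVariant("chrS", ts, ref[ts - 1 : ts + 4], ref[ts - 1], (0, 1))
        ctx = build_context(v, ref)
        assert ctx.extended
        # read stops 5 units into the 7-unit tract
        read = mk_read(ts - 20, ref[ts - 20 : ts + 20])
        assert context_assign(read, ctx).call == Call.BOTH

    def test_disregarded_context_raises(self):
        _, ref = random_reference(1000, seed=6)
        ref, (ts, te) = plant_tandem_repeat(ref, 500, "ATTC", 20)
        v = PhasedVariant("chrS", ts, ref[ts - 1 : ts + 4], ref[ts - 1], (0, 1))
        ctx = build_context(v, ref)
        with pytest.raises(ValueError):
            context_assign(mk_read(ts - 50, ref[ts - 50 : ts + 100]), ctx)


class TestCohortAssign:
    def _cohort_world(self):
        _, ref = random_reference(1000, seed=8)
        picks = []
        for pos0 in (500, 508, 517):
            b = ref[pos0]
            alt = "G" if b != "G" else "A"
            picks.append(PhasedVariant("chrS", pos0 + 1, b, alt, (0, 1)))
        cohorts = build_cohorts(picks, distance=25)
        assert len(cohorts) == 1
        contexts = {v.footprint: build_context(v, ref, picks) for v in picks}
        return ref, picks, cohorts[0], contexts

    def _hap2_seq(self, ref, variants, lo, hi):
        out, cur = [], lo
        for v in variants:
            if v.start < lo or v.end > hi:
                continue
            out.append(ref[cur : v.start])
            out.append(v.alt)
            cur = v.end
        out.append(ref[cur:hi])
        return "".join(out)

    def test_whole_cohort_match_tallies_all_members(self):
        ref, picks, cohort, contexts = self._cohort_world()
        seq = self._hap2_seq(ref, picks, 470, 560)
        read = mk_read(470, seq)
        out = cohort_assign(read, cohort, contexts, ref)
        assert len(out) == 3
        assert all(ra.call == Call.ALT and ra.anchor == "cohort" for _, ra in out)

    def test_read_overlapping_one_member_falls_back(self):
        ref, picks, cohort, contexts = self._cohort_world()
        read = mk_read(517, ref[517:560])  # covers only the last member
        out = cohort_assign(read, cohort, contexts, ref)
        assert len(out) == 1
        assert out[0][0] is picks[-1] and out[0][1].call == Call.REF

    def test_error_in_cohort_string_rescued_by_fallback(self):
        """One error inside the cohort span defeats the whole-string match but
        per-variant contexts still rescue the clean members."""
        ref, picks, cohort, contexts = self._cohort_world()
        seq = list(self._hap2_seq(ref, picks, 470, 560))
        err_at = 505 - 470  # between member 1 and 2, inside the cohort span
        seq[err_at] = "A" if seq[err_at] != "A" else "C"
        read = mk_read(470, "".join(seq))
        out = cohort_assign(read, cohort, contexts, ref)
        assert len(out) == 3
        calls = {v.pos: ra.call for v, ra in out}
        # members away from the error keep their true ALT call
        assert calls[picks[2].pos] == Call.ALT

    def test_matches_exhaustive_substring_oracle(self):
        """Fallback calls agree with scanning the read for each variant's
        full context by brute force."""
        ref, picks, cohort, contexts = self._cohort_world()
        rng = np.random.default_rng(0)
        for start in rng.integers(440, 520, 20):
            start = int(start)
            seq = self._hap2_seq(ref, picks, start, start + 70)
            read = mk_read(start, seq, [("M", 70)])  # span approximation
            # oracle: exhaustive substring search of full contexts
            for v, ra in cohort_assign(read, cohort, contexts, ref):
                ctx = contexts[v.footprint]
                in_ref = ctx.ref_context in seq
                in_alt = ctx.alt_context in seq
                if in_alt and not in_ref:
                    assert ra.call == Call.ALT
                elif in_ref and not in_alt:
                    assert ra.call == Call.REF


class TestProperties:
    def test_oracle_equivalence_on_perfect_alignments(self, world, world_assignments, world_contexts):
        """Every error-free read fully spanning its effective variant is
        called with its truth haplotype's allele."""
        ctx_asg, _ = world_assignments
        n_checked = 0
        for v in world.variants:
            if not v.is_het:
                continue
            ctx = world_contexts[v.footprint]
            if ctx.disregarded:
                continue
            s, e = ctx.span
            truth_by_key = {}
            for t in world.truth.overlapping(world.chrom, s, e):
                truth_by_key[(t.read_id, t.mate)] = t
            for ra in ctx_asg[v.footprint]:
                t = truth_by_key.get((ra.read_id, ra.mate))
                if t is None or not (t.ref_start <= s and t.ref_end >= e):
                    continue
                expected = Call.REF if t.hap_id == v.ref_hap else Call.ALT
                assert ra.call == expected, (v, ra)
                n_checked += 1
        assert n_checked > 1000

    def test_symmetry_ref_alt_swap(self):
        """Mirror world: swap which allele the reference carries; calls swap."""
        _, ref = random_reference(1000, seed=12)
        b = ref[500]
        alt = "G" if b != "G" else "A"
        v = PhasedVariant("chrS", 501, b, alt, (0, 1))
        ctx = build_context(v, ref)
        mirror_ref = ref[:500] + alt + ref[501:]
        mv = PhasedVariant("chrS", 501, alt, b, (1, 0))
        mctx = build_context(mv, mirror_ref)
        for start in (460, 480, 496, 500):
            for carried in (b, alt):
                seq = ref[start:500] + carried + ref[501 : start + 60]
                call = context_assign(mk_read(start, seq), ctx).call
                mcall = context_assign(mk_read(start, seq), mctx).call
                swap = {Call.REF: Call.ALT, Call.ALT: Call.REF, Call.BOTH: Call.BOTH, Call.OTHER: Call.OTHER}
                assert mcall == swap[call]

    def test_every_overlapping_read_gets_exactly_one_call(self, world, world_assignments):
        ctx_asg, naive_asg = world_assignments
        for v in world.variants:
            if not v.is_het:
                continue
            over = {a.key for a in world.index.overlapping(world.chrom, v.start, v.end)}
            for result in (ctx_asg, naive_asg):
                keys = [(ra.read_id, ra.mate) for ra in result[v.footprint]]
                assert len(keys) == len(set(keys))
                assert set(keys) == over
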