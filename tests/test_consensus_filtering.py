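"""Hard filters, universal mask, indel normalisation, caller consensus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest

from trioaudit.consensus_filtering import (
    FilterThresholds,
    apply_universal_mask,
    build_universal_mask,
    genotype_filter,
    intersect_callers,
    normalize_variant,
    site_filter,
)
from trioaudit.io_formats import GenotypeCall, MaskIntervals, VariantRecord


def _record(qd=12.0, mq=60.0, ad=(22, 18), strands=None, chrom="chr1", start=100):
    dp = sum(ad)
    if strands is None:
        strands = (ad[0] // 2, ad[0] - ad[0] // 2, ad[1] // 2, ad[1] - ad[1] // 2)
    return VariantRecord(
        chrom=chrom,
        start=start,
        ref="A",
        alts=("G",),
        qd=qd,
        mq=mq,
        strand_counts=strands,
        calls=(GenotypeCall(sample="S1", gt=(0, 1), dp=dp, gq=99, ad=ad),),
    )


class TestSiteFilter:
    def test_boundary_values_fail_strictly(self):
        assert "QD" in site_filter(_record(qd=2.0)).reasons
        assert "MQ" in site_filter(_record(mq=30.0)).reasons

    def test_clean_record_passes(self):
        v = site_filter(_record())
        assert v.passed and not v.reasons

    def test_allele_bias_fires_on_extreme_imbalance(self):
        # AB = 2/40 = 0.05 <= 0.1 and two-sided binomial p(2; 40, 0.5) tiny
        v = site_filter(_record(ad=(38, 2), strands=(19, 19, 1, 1)))
        assert "AB" in v.reasons
        assert binomtest(2, 40, 0.5).pvalue < 0.05  # oracle for the rule input

    def test_allele_bias_needs_both_conditions(self):
        # AB = 2/6 > 0.1: balance bound not crossed, rule must not fire
        v = site_filter(_record(ad=(4, 2), strands=(2, 2, 1, 1)))
        assert "AB" not in v.reasons

    def test_missing_annotation_is_unevaluable_not_failed(self):
        v = site_filter(_record(qd=None))
        assert "QD" in v.unevaluable and "QD" not in v.reasons

    def test_strand_bias_fisher(self):
        # all ref reads forward, all alt reads reverse: maximal strand bias
        v = site_filter(_record(ad=(20, 20), strands=(20, 0, 0, 20)))
        assert "SB" in v.reasons


class TestGenotypeFilter:
    @pytest.mark.parametrize(
        "dp,gq,passed",
        [(15, 99, False), (16, 31, True), (100, 99, False), (40, 30, False), (40, 31, True)],
    )
    def test_strict_bounds(self, dp, gq, passed):
        call = GenotypeCall(sample="S1", gt=(0, 1), dp=dp, gq=gq, ad=(dp // 2, dp - dp // 2))
        assert genotype_filter(call).passed is passed

    def test_missing_depth_unevaluable(self):
        call = GenotypeCall(sample="S1", gt=(0, 1), dp=None, gq=99)
        v = genotype_filter(call)
        assert "DP" in v.unevaluable and v.passed


class TestUniversalMask:
    def test_snv_inside_mask_removed(self):
        mask = MaskIntervals.from_tuples([("chr1", 10, 20)])
        inside = _record(start=14)
        outside = _record(start=20)  # half-open: 20 is first unmasked base
        assert apply_universal_mask([inside, outside], mask) == [outside]

    def test_empty_mask_is_identity(self):
        recs = [_record(start=s) for s in (0, 5, 100)]
        assert apply_universal_mask(recs, MaskIntervals()) == recs

    def test_random_records_vs_brute_force(self, rng):
        tuples = [
            ("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 900, 30), rng.integers(1, 40, 30))
        ]
        mask = MaskIntervals.from_tuples(tuples)
        recs = [_record(start=int(s)) for s in rng.integers(0, 1000, 200)]
        got = apply_universal_mask(recs, mask)
        expected = [
            r
            for r in recs
            if not any(r.start < e and r.end > s for _, s, e in tuples)
        ]
        assert got == expected

    def test_build_mask_merges_and_is_idempotent(self):
        a = MaskIntervals.from_tuples([("chr1", 0, 10)], "mappability")
        b = MaskIntervals.from_tuples([("chr1", 5, 20)], "repeat")
        c = MaskIntervals.from_tuples([("chr2", 3, 4)], "low-complexity")
        merged = build_universal_mask([a, b, c])
        assert merged.intervals == {"chr1": [(0, 20)], "chr2": [(3, 4)]}
        assert build_universal_mask([merged]).intervals == merged.intervals


class TestNormalize:
    def test_snv_unchanged(self):
        ref = {"chr1": "GCAAAT"}
        rec = VariantRecord(chrom="chr1", start=2, ref="A", alts=("T",))
        assert normalize_variant(rec, ref) == rec

    def test_deletion_left_aligns_through_repeat(self):
        # deleting one A of the run in GCAAAT can be written many ways;
        # canonical form anchors at the preceding C
        ref = {"chr1": "GCAAAT"}
        rec = VariantRecord(chrom="chr1", start=3, ref="AA", alts=("A",))
        out = normalize_variant(rec, ref)
        assert (out.start, out.ref, out.alts) == (1, "CA", ("C",))

    def test_ref_mismatch_raises(self):
        ref = {"chr1": "GCAAAT"}
        rec = VariantRecord(chrom="chr1", start=0, ref="T", alts=("A",))
        with pytest.raises(ValueError):
            normalize_variant(rec, ref)

    def test_idempotent_and_matches_leftmost_minimal_oracle(self, rng):
        """Compare with brute force: enumerate all equivalent representations
        of a random indel (same edited haplotype) and pick the leftmost,
        shortest one."""
        bases = "ACGT"
        for _ in range(50):
            seq = "".join(rng.choice(list(bases), size=30))
            start = int(rng.integers(1, 25))
            if rng.random() < 0.5:  # deletion
                dlen = int(rng.integers(1, 4))
                ref_a = seq[start : start + dlen + 1]
                alt_a = seq[start]
            else:  # insertion
                ins = "".join(rng.choice(list(bases), size=int(rng.integers(1, 4))))
                ref_a = seq[start]
                alt_a = seq[start] + ins
            rec = VariantRecord(chrom="c", start=start, ref=ref_a, alts=(alt_a,))
            out = normalize_variant(rec, {"c": seq})
            assert normalize_variant(out, {"c": seq}) == out  # idempotent
            edited = seq[:start] + alt_a + seq[start + len(ref_a) :]
            candidates = set()
            for s in range(len(seq)):
                for rl in range(1, 7):
                    if s + rl > len(seq):
                        break
                    for al in range(1, 7):
                        a_str = edited[s : s + al]
                        if len(a_str) < al:
                            break
                        if seq[:s] + a_str + seq[s + rl :] == edited:
                            candidates.add((s, seq[s : s + rl], a_str))
            # most parsimonious representation, leftmost among ties
            best = min(candidates, key=lambda t: (len(t[1]) + len(t[2]), t[0]))
            assert (out.start, out.ref, out.alts[0]) == best


class TestConsensus:
    def _rec(self, start, ref="A", alt="G"):
        return VariantRecord(chrom="chr1", start=start, ref=ref, alts=(alt,))

    def test_membership_requires_all_callers(self):
        shared = self._rec(10)
        only3 = self._rec(20)
        sets = [[shared, only3], [shared, only3], [shared, only3], [shared]]
        out = intersect_callers(sets)
        assert [r.key() for r in out] == [shared.key()]

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            intersect_callers([[self._rec(1)]])

    def test_output_subset_and_order_invariance(self, rng):
        pool = [self._rec(int(s)) for s in rng.choice(500, size=60, replace=False)]
        sets = [list(rng.choice(pool, size=40, replace=False)) for _ in range(4)]
        out_keys = {r.key() for r in intersect_callers(sets)}
        for s in sets:
            assert out_keys <= {r.key() for r in s}
        assert out_keys == {r.key() for r in intersect_callers(sets[::-1])}

    def test_differently_aligned_deletion_matches_after_normalization(self):
        # one A deleted from the AAA run, written at both run ends
        ref = {"chr1": "GCAAAT"}
        left = VariantRecord(chrom="chr1", start=1, ref="CA", alts=("C",))
        right = VariantRecord(chrom="chr1", start=3, ref="AA", alts=("A",))
        out = intersect_callers([[left], [right]], reference=ref)
        assert len(out) == 1
        assert not intersect_callers([[left], [right]])  # no reference, no match


@settings(max_examples=40, derandomize=True)
@given(
    qd=st.floats(0, 40, allow_nan=False),
    mq=st.floats(0, 80, allow_nan=False),
    bump=st.floats(0.1, 10),
)
def test_site_filter_monotone_in_thresholds(qd, mq, bump):
    """Raising a *_min threshold can only turn passes into failures."""
    rec = _record(qd=qd, mq=mq)
    loose = FilterThresholds()
    tight = FilterThresholds(qd_min=loose.qd_min + bump, mq_min=loose.mq_min + bump)
    if site_filter(rec, tight).passed:
        assert site_filter(rec, loose).passed


def test_filter_order_commutes(rng, sim_result):
    """SF, GF and UM are independent predicates: any application order
    leaves the same surviving set."""
    from trioaudit.consensus_filtering import FilterThresholds, genotype_filter, site_filter

    t = FilterThresholds()
    records = sim_result.caller_views["caller1"][:300]
    mask = sim_result.mask

    def sf(rs):
        return [r for r in rs if site_filter(r, t).passed]

    def gf(rs):
        return [
            r
            for r in rs
            if all(
                c.gt is not None and genotype_filter(c, t, r.is_snv()).passed for c in r.calls
            )
        ]

    def um(rs):
        return apply_universal_mask(rs, mask)

    orders = [(sf, gf, um), (um, gf, sf), (gf, um, sf)]
    results = []
    for fns in orders:
        rs = records
        for fn in fns:
            rs = fn(rs)
        results.append({r.key() for r in rs})
    assert results[0] == results[1] == results[2]
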