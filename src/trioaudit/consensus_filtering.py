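"""Site/genotype hard filters, universal mask, and multi-caller consensus.

The high-confidence variant set is built by (1) site filtering (SF) on
QD, MQ, allele bias and strand bias; (2) genotype filtering (GF) on DP and
GQ; (3) removing variants inside the universal mask (UM: mappability +
low-complexity + repeat regions); and (4) keeping only variants reported by
every caller.  All threshold comparisons are strict, so a value sitting
exactly on a cutoff fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest, fisher_exact

from trioaudit.io_formats import GenotypeCall, MaskIntervals, VariantRecord

__all__ = [
    "FilterThresholds",
    "FilterVerdict",
    "site_filter",
    "genotype_filter",
    "apply_universal_mask",
    "build_universal_mask",
    "intersect_callers",
    "normalize_variant",
    "filter_funnel",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter cutoffs for SF and GF.

    The allele-bias rule fires only when BOTH the allele balance is at or
    below ``ab_min`` AND the two-sided binomial test against 0.5 is
    significant; ``ab_require_pval=False`` switches to the balance bound
    alone.  DP bounds for indels default to the SNV bounds.
    """

    qd_min: float = 2.0
    mq_min: float = 30.0
    ab_min: float = 0.10
    ab_pval: float = 0.05
    strand_pval: float = 0.05
    dp_min: int = 15
    dp_max: int = 100
    gq_min: int = 30
    indel_dp_min: int | None = None
    indel_dp_max: int | None = None
    ab_require_pval: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.ab_min <= 0.5:
            raise ValueError(f"ab_min must be in [0, 0.5], got {self.ab_min}")
        if self.dp_min >= self.dp_max:
            raise ValueError("dp_min must be < dp_max")

    def dp_bounds(self, is_snv: bool = True) -> tuple[int, int]:
        if is_snv:
            return self.dp_min, self.dp_max
        return (
            self.indel_dp_min if self.indel_dp_min is not None else self.dp_min,
            self.indel_dp_max if self.indel_dp_max is not None else self.dp_max,
        )


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of a filter: pass/fail plus the reasons and anything
    that could not be evaluated because its annotation was missing."""

    passed: bool
    reasons: tuple[str, ...] = ()
    unevaluable: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed and self.reasons:
            raise ValueError("a passing verdict cannot carry failure reasons")

    def __bool__(self) -> bool:
        return self.passed


def _verdict(reasons: list[str], unevaluable: list[str]) -> FilterVerdict:
    return FilterVerdict(passed=not reasons, reasons=tuple(reasons), unevaluable=tuple(unevaluable))


def site_filter(record: VariantRecord, t: FilterThresholds | None = None) -> FilterVerdict:
    """Site-level filter (SF): QD, MQ, allele bias, strand bias.

    ``record`` must be biallelic.  Allele balance is computed from the AD
    of het calls (alt reads / (ref+alt reads)); the strand-bias test is a
    two-sided Fisher exact test on the ref/alt x fwd/rev strand counts.
    Missing annotations are reported as unevaluable, not failed.
    """
    t = t or FilterThresholds()
    if len(record.alts) != 1:
        raise ValueError("site_filter requires a biallelic record; split first")
    reasons: list[str] = []
    unevaluable: list[str] = []

    if record.qd is None:
        unevaluable.append("QD")
    elif not record.qd > t.qd_min:
        reasons.append("QD")
    if record.mq is None:
        unevaluable.append("MQ")
    elif not record.mq > t.mq_min:
        reasons.append("MQ")

    # Allele bias: evaluated on het calls carrying AD; the most extreme
    # (lowest) alt fraction is tested.
    het_ads = [c.ad for c in record.calls if c.is_het() and c.ad is not None and sum(c.ad) > 0]
    if not het_ads:
        unevaluable.append("AB")
    else:
        worst = min(het_ads, key=lambda ad: ad[1] / (ad[0] + ad[1]))
        ref_n, alt_n = worst[0], worst[1]
        ab = alt_n / (ref_n + alt_n)
        if ab <= t.ab_min:
            if not t.ab_require_pval:
                reasons.append("AB")
            else:
                p = binomtest(alt_n, ref_n + alt_n, 0.5).pvalue
                if p < t.ab_pval:
                    reasons.append("AB")

    if record.strand_counts is None:
        unevaluable.append("SB")
    else:
        rf, rr, af, ar = record.strand_counts
        _, p = fisher_exact([[rf, rr], [af, ar]])
        if p < t.strand_pval:
            reasons.append("SB")

    return _verdict(reasons, unevaluable)


def genotype_filter(
    call: GenotypeCall, t: FilterThresholds | None = None, is_snv: bool = True
) -> FilterVerdict:
    """Genotype-level filter (GF): dp_min < DP < dp_max and GQ > gq_min."""
    t = t or FilterThresholds()
    if call.gt is None:
        raise ValueError(f"genotype_filter requires a called genotype for {call.sample}")
    reasons: list[str] = []
    unevaluable: list[str] = []
    lo, hi = t.dp_bounds(is_snv)
    if call.dp is None:
        unevaluable.append("DP")
    elif not lo < call.dp < hi:
        reasons.append("DP")
    if call.gq is None:
        unevaluable.append("GQ")
    elif not call.gq > t.gq_min:
        reasons.append("GQ")
    return _verdict(reasons, unevaluable)


def build_universal_mask(components: Sequence[MaskIntervals]) -> MaskIntervals:
    """Union-merge mask components (mappability, low-complexity, repeats)."""
    if not components:
        return MaskIntervals(label="merged")
    return components[0].union(*components[1:], label="merged")


def apply_universal_mask(
    records: Iterable[VariantRecord], mask: MaskIntervals
) -> list[VariantRecord]:
    """Drop records whose REF span intersects any mask interval."""
    return [r for r in records if not mask.overlaps(r.chrom, r.start, r.end)]


def normalize_variant(record: VariantRecord, reference: Mapping[str, str]) -> VariantRecord:
    """Left-align and parsimony-trim a biallelic variant against the reference.

    SNVs are returned unchanged.  Raises if the record's REF disagrees with
    the reference sequence.
    """
    seq = reference.get(record.chrom)
    if seq is None:
        raise ValueError(f"chromosome {record.chrom!r} not in reference")
    if seq[record.start : record.end] != record.ref:
        raise ValueError(
            f"REF mismatch at {record.chrom}:{record.pos}: "
            f"record says {record.ref!r}, reference has {seq[record.start:record.end]!r}"
        )
    if len(record.alts) != 1:
        raise ValueError("normalize_variant requires a biallelic record")
    ref, alt, start = record.ref, record.alts[0], record.start
    if len(ref) == 1 and len(alt) == 1:
        return record
    # Left-align/trim: while alleles share their last base, drop it; if an
    # allele empties, extend both leftwards with the preceding reference
    # base.  Then trim any shared leading bases.
    while ref and alt and ref[-1] == alt[-1]:
        last = ref[-1]
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if start == 0:
                # cannot extend past the contig start: undo the trim
                ref, alt = ref + last, alt + last
                break
            start -= 1
            base = seq[start]
            ref, alt = base + ref, base + alt
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start += 1
    if (ref, alt, start) == (record.ref, record.alts[0], record.start):
        return record
    return replace(record, start=start, ref=ref, alts=(alt,))


def intersect_callers(
    per_caller_sets: Sequence[Sequence[VariantRecord]],
    reference: Mapping[str, str] | None = None,
    primary: int = 0,
) -> list[VariantRecord]:
    """Keep variants present (by chrom, pos, ref, alt) in every caller set.

    Records are normalised first when a reference is supplied, so the same
    indel written left- and right-aligned by different callers still
    matches.  Annotations of kept variants come from the ``primary`` caller.
    """
    if len(per_caller_sets) < 2:
        raise ValueError("caller intersection needs at least 2 call sets")

    def norm_key(rec: VariantRecord) -> tuple[str, int, str, str]:
        if reference is not None:
            rec = normalize_variant(rec, reference)
        return rec.key()

    keysets = [{norm_key(r) for r in s} for s in per_caller_sets]
    consensus_keys = set.intersection(*keysets)
    out, seen = [], set()
    for rec in per_caller_sets[primary]:
        k = norm_key(rec)
        if k in consensus_keys and k not in seen:
            seen.add(k)
            out.append(rec)
    return out


def filter_caller_set(
    records: Sequence[VariantRecord],
    mask: MaskIntervals,
    thresholds: FilterThresholds | None = None,
    trio_samples: Sequence[str] | None = None,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Run SF -> GF -> UM on one caller's call set.

    Multi-allelic records are split first.  GF failure (or a missing
    genotype) in any trio member removes the site: a trio DNM call needs
    all three genotypes.  Returns the surviving records and the per-stage
    funnel counts (raw / SF / GF / UM).
    """
    thresholds = thresholds or FilterThresholds()
    split = [b for r in records for b in r.split_multiallelic()]
    counts = {"raw": len(split)}
    sf = [r for r in split if site_filter(r, thresholds).passed]
    counts["SF"] = len(sf)
    gf = []
    for r in sf:
        samples = trio_samples if trio_samples is not None else r.samples
        ok = True
        for s in samples:
            try:
                c = r.call(s)
            except KeyError:
                ok = False
                break
            if c.gt is None or not genotype_filter(c, thresholds, r.is_snv()).passed:
                ok = False
                break
        if ok:
            gf.append(r)
    counts["GF"] = len(gf)
    um = apply_universal_mask(gf, mask)
    counts["UM"] = len(um)
    return um, counts


def filter_funnel(
    per_caller_records: Sequence[Sequence[VariantRecord]],
    mask: MaskIntervals,
    thresholds: FilterThresholds | None = None,
    trio_samples: Sequence[str] | None = None,
    reference: Mapping[str, str] | None = None,
) -> tuple[list[VariantRecord], list[dict[str, int]]]:
    """SF -> GF -> UM per caller, then the caller intersection.

    Returns the high-confidence consensus set and per-caller funnel counts.
    """
    filtered_sets: list[list[VariantRecord]] = []
    funnel: list[dict[str, int]] = []
    for records in per_caller_records:
        um, counts = filter_caller_set(records, mask, thresholds, trio_samples)
        filtered_sets.append(um)
        funnel.append(counts)
    consensus = intersect_callers(filtered_sets, reference=reference)
    for counts in funnel:
        counts["consensus"] = len(consensus)
    return consensus, funnel
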