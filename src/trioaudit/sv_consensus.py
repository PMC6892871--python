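"""Structural-variant filtering and de novo SV discovery in trios.

Short-read call sets (two callers) are hard-filtered (PASS, precise
breakpoints, supporting reads, length band) and intersected by 50%
reciprocal overlap; long-read call sets are filtered by a minimum calling
read count plus a depth-relative support fraction.  De novo SVs are the
offspring calls left after removing everything reciprocally overlapping a
parental SV, a known-database SV, or a sibling SV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from trioaudit.consensus_filtering import FilterVerdict

__all__ = [
    "SvRecord",
    "SvFilterConfig",
    "filter_sv_shortread",
    "filter_sv_longread",
    "reciprocal_overlap",
    "intersect_sv_callers",
    "de_novo_sv_filter",
]

SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA")


@dataclass(frozen=True)
class SvRecord:
    """An interval-typed structural variant call.

    ``start``/``end`` are 0-based half-open; for insertions the interval is
    the breakpoint and ``ins_length`` carries the stated inserted length.
    """

    chrom: str
    start: int
    end: int
    svtype: str
    support: int
    precise: bool = True
    filter_label: str = "PASS"
    sample: str = ""
    ins_length: int | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")
        if self.svtype != "INS" and self.start >= self.end:
            raise ValueError(f"start must be < end for {self.svtype} ({self.start} >= {self.end})")
        if self.support < 0:
            raise ValueError("support must be >= 0")

    @property
    def length(self) -> int:
        if self.svtype == "INS":
            return self.ins_length if self.ins_length is not None else self.end - self.start
        return self.end - self.start


@dataclass(frozen=True)
class SvFilterConfig:
    """Filter cutoffs for short-read and long-read SV call sets."""

    min_support: int = 10          # short-read: strict >
    min_len: int = 50
    max_len: int = 2_000_000
    require_pass: bool = True
    require_precise: bool = True
    min_support_fraction: float = 0.05  # long-read: strict > fraction of depth
    min_calling_reads: int = 10         # long-read: >= ("at least ten")
    reciprocal_threshold: float = 0.5   # strict >
    ins_breakpoint_tol: int = 100
    match_ins_by_breakpoint: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.reciprocal_threshold <= 1:
            raise ValueError("reciprocal_threshold must be in (0, 1]")


def filter_sv_shortread(sv: SvRecord, cfg: SvFilterConfig | None = None) -> FilterVerdict:
    """Short-read SV hard filter: PASS, precise, support > 10, 50 bp–2 Mb.

    Over-length SVs fail with a distinct ``length_gt_max`` tag (the manual
    review such calls would get is out of scope here).
    """
    cfg = cfg or SvFilterConfig()
    reasons = []
    if cfg.require_pass and sv.filter_label != "PASS":
        reasons.append("not_pass")
    if cfg.require_precise and not sv.precise:
        reasons.append("imprecise")
    if not sv.support > cfg.min_support:
        reasons.append("support")
    if sv.length < cfg.min_len:
        reasons.append("length_lt_min")
    elif sv.length > cfg.max_len:
        reasons.append("length_gt_max")
    return FilterVerdict(passed=not reasons, reasons=tuple(reasons))


def filter_sv_longread(
    sv: SvRecord, region_depth: float, cfg: SvFilterConfig | None = None
) -> FilterVerdict:
    """Long-read SV filter: PASS, precise, >=10 calling reads, and support
    strictly above ``min_support_fraction`` of the whole-region depth."""
    cfg = cfg or SvFilterConfig()
    if region_depth <= 0:
        raise ValueError(f"region depth must be positive, got {region_depth}")
    reasons = []
    if cfg.require_pass and sv.filter_label != "PASS":
        reasons.append("not_pass")
    if cfg.require_precise and not sv.precise:
        reasons.append("imprecise")
    if sv.support < cfg.min_calling_reads:
        reasons.append("calling_reads")
    if not sv.support > cfg.min_support_fraction * region_depth:
        reasons.append("support_fraction")
    return FilterVerdict(passed=not reasons, reasons=tuple(reasons))


def _interval_overlap(a: SvRecord, b: SvRecord) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(
    a: SvRecord, b: SvRecord, threshold: float = 0.5, cfg: SvFilterConfig | None = None
) -> bool:
    """True iff the overlap exceeds ``threshold`` of BOTH SV lengths (strict).

    Requires matching chrom and svtype.  Insertions, which have no interval
    extent, are matched by breakpoint distance and length ratio when the
    config enables it.
    """
    if a.chrom != b.chrom or a.svtype != b.svtype:
        return False
    if a.svtype == "INS":
        cfg = cfg or SvFilterConfig()
        if not cfg.match_ins_by_breakpoint:
            return False
        if abs(a.start - b.start) > cfg.ins_breakpoint_tol:
            return False
        la, lb = a.length, b.length
        if la == 0 or lb == 0:
            return False
        return min(la, lb) / max(la, lb) > threshold
    ov = _interval_overlap(a, b)
    return ov > threshold * a.length and ov > threshold * b.length


def _overlap_fraction(a: SvRecord, b: SvRecord) -> float:
    ov = _interval_overlap(a, b)
    return min(ov / a.length, ov / b.length) if a.length and b.length else 0.0


def intersect_sv_callers(
    set_a: Sequence[SvRecord],
    set_b: Sequence[SvRecord],
    threshold: float = 0.5,
    cfg: SvFilterConfig | None = None,
) -> list[SvRecord]:
    """Consensus of two SV call sets by reciprocal overlap.

    An SV from ``set_a`` is kept iff some ``set_b`` SV of the same chrom
    and type reciprocally overlaps it; coordinates are reported from
    ``set_a``.  When several partners overlap, the best (largest minimum
    overlap fraction) is associated greedily, which only affects pairing
    metadata, not membership.
    """
    kept = []
    for a in set_a:
        partners = [b for b in set_b if reciprocal_overlap(a, b, threshold, cfg)]
        if partners:
            kept.append(a)
    return kept


def de_novo_sv_filter(
    offspring_set: Sequence[SvRecord],
    parent_sets: Sequence[Sequence[SvRecord]],
    known_db: Sequence[SvRecord] = (),
    sibling_sets: Sequence[Sequence[SvRecord]] = (),
    threshold: float = 0.5,
    cfg: SvFilterConfig | None = None,
) -> list[SvRecord]:
    """De novo SVs: offspring calls matching no parental, known, or sibling SV.

    Matching is reciprocal overlap at ``threshold``.  The remainder after
    removing parent-inherited, database-known and sibling-shared calls is
    the de novo set.
    """
    exclusion: list[SvRecord] = [sv for s in parent_sets for sv in s]
    exclusion += list(known_db)
    exclusion += [sv for s in sibling_sets for sv in s]
    return [
        sv
        for sv in offspring_set
        if not any(reciprocal_overlap(sv, other, threshold, cfg) for other in exclusion)
    ]
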