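"""Trio de novo mutation discovery and the staged filtration cascade.

Candidates are Mendelian violations: offspring genotypes that cannot be
assembled from one allele of each parent.  The cascade then applies

* caller overlap      (Raw -> noStrict): keep candidates every caller saw;
* allele filtering    (noStrict -> AF): keep candidates carrying an allele
  absent from BOTH parents — this removes the dominant artifact class,
  violations whose alleles all exist in the parents (e.g. parents A/A and
  G/G with an offspring called G/G instead of the expected A/G);
* known-variant filtering (AF -> dbSNPF): drop candidates present in a
  public variant database;
* cross filtering     (dbSNPF -> CF): drop candidates shared between
  offspring of the same parents — shared "de novo" calls are systematic
  artifacts, since independent identical DNMs are vanishingly unlikely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from trioaudit.io_formats import VariantRecord

__all__ = [
    "DnmCandidate",
    "KnownVariantDb",
    "detect_candidates",
    "overlap_candidates",
    "allele_filter",
    "dbsnp_filter",
    "cross_filter",
    "summarize_dnms",
    "score_against_truth",
    "STAGES",
]

STAGES = ("Raw", "noStrict", "AF", "dbSNPF", "CF")

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class DnmCandidate:
    """A putative offspring-specific variant with filter provenance."""

    chrom: str
    start: int
    ref: str
    alt: str
    offspring_gt: tuple[int, int]
    father_gt: tuple[int, int]
    mother_gt: tuple[int, int]
    offspring: str
    callers: frozenset[str] = frozenset()
    stages: tuple[str, ...] = ("Raw",)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.start, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def advanced(self, stage: str) -> "DnmCandidate":
        return replace(self, stages=(*self.stages, stage))


@dataclass
class KnownVariantDb:
    """Exact-key lookup of known variants.

    Keys are (chrom, 0-based pos, alt); ``match_alt=False`` switches to
    position-only matching.
    """

    keys: set[tuple[str, int, str]] = field(default_factory=set)
    build: str = ""
    match_alt: bool = True

    @classmethod
    def from_records(cls, records: Iterable[VariantRecord], build: str = "") -> "KnownVariantDb":
        keys = set()
        for rec in records:
            for b in rec.split_multiallelic():
                keys.add((b.chrom, b.start, b.alts[0]))
        return cls(keys=keys, build=build)

    def __contains__(self, key: VariantKey) -> bool:
        chrom, start, _ref, alt = key
        if self.match_alt:
            return (chrom, start, alt) in self.keys
        return any(k[0] == chrom and k[1] == start for k in self.keys)


def _mendelian_consistent(
    off: tuple[int, ...], father: tuple[int, ...], mother: tuple[int, ...]
) -> bool:
    a, b = off
    return (a in father and b in mother) or (b in father and a in mother)


def detect_candidates(
    records: Iterable[VariantRecord],
    father: str,
    mother: str,
    offspring: str,
    caller: str = "caller",
) -> list[DnmCandidate]:
    """Flag sites where the offspring genotype violates Mendelian inheritance.

    This is a permissive genotype-configuration detector: a site is a
    candidate iff the offspring genotype cannot be formed by drawing one
    allele from each parent.  Sites with a missing genotype in any trio
    member are skipped (and counted via a warning if any were seen).
    Records must be biallelic.
    """
    out: list[DnmCandidate] = []
    skipped = 0
    for rec in records:
        if len(rec.alts) != 1:
            raise ValueError(f"detect_candidates needs biallelic records ({rec.chrom}:{rec.pos})")
        try:
            fo, mo, of = rec.call(father), rec.call(mother), rec.call(offspring)
        except KeyError:
            skipped += 1
            continue
        if fo.gt is None or mo.gt is None or of.gt is None:
            skipped += 1
            continue
        if not _mendelian_consistent(of.gt, fo.gt, mo.gt):
            out.append(
                DnmCandidate(
                    chrom=rec.chrom,
                    start=rec.start,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    offspring_gt=tuple(sorted(of.gt)),  # type: ignore[arg-type]
                    father_gt=tuple(sorted(fo.gt)),  # type: ignore[arg-type]
                    mother_gt=tuple(sorted(mo.gt)),  # type: ignore[arg-type]
                    offspring=offspring,
                    callers=frozenset({caller}),
                )
            )
    if skipped:
        warnings.warn(f"{skipped} sites skipped for missing trio genotypes")
    return out


def overlap_candidates(per_caller: Sequence[Sequence[DnmCandidate]]) -> list[DnmCandidate]:
    """Intersect candidate lists across callers by variant key (noStrict set)."""
    if not per_caller:
        return []
    keysets = [{c.key for c in lst} for lst in per_caller]
    shared = set.intersection(*keysets)
    merged: dict[VariantKey, DnmCandidate] = {}
    for lst in per_caller:
        for c in lst:
            if c.key not in shared:
                continue
            if c.key in merged:
                prev = merged[c.key]
                merged[c.key] = replace(prev, callers=prev.callers | c.callers)
            else:
                merged[c.key] = c
    return [c.advanced("noStrict") for c in merged.values()]


def allele_filter(candidates: Iterable[DnmCandidate]) -> list[DnmCandidate]:
    """Keep candidates carrying at least one allele absent from both parents.

    The offspring allele indices are mapped to allele strings (0 = REF,
    1 = ALT); a candidate survives iff some offspring allele appears in
    neither parent's genotype.  Multi-allelic offspring genotypes survive
    if either allele is novel.
    """
    out = []
    for c in candidates:
        parental = set(c.father_gt) | set(c.mother_gt)
        if any(a not in parental for a in c.offspring_gt):
            out.append(c.advanced("AF"))
    return out


def dbsnp_filter(candidates: Iterable[DnmCandidate], db: KnownVariantDb) -> list[DnmCandidate]:
    """Drop candidates whose key is present in the known-variant database."""
    return [c.advanced("dbSNPF") for c in candidates if c.key not in db]


def cross_filter(
    per_offspring: Mapping[str, Sequence[DnmCandidate]]
) -> dict[str, list[DnmCandidate]]:
    """Remove candidates whose variant key appears in >=2 offspring.

    A true DNM is private to one offspring; keys recurring across siblings
    of the same parents are systematic artifacts.  With a single offspring
    this is the identity (with a warning).
    """
    if len(per_offspring) < 2:
        warnings.warn("cross filtering needs >=2 offspring; returning input unchanged")
        return {k: [c.advanced("CF") for c in v] for k, v in per_offspring.items()}
    counts: dict[VariantKey, int] = {}
    for cands in per_offspring.values():
        for key in {c.key for c in cands}:
            counts[key] = counts.get(key, 0) + 1
    return {
        off: [c.advanced("CF") for c in cands if counts[c.key] < 2]
        for off, cands in per_offspring.items()
    }


def summarize_dnms(
    final_sets: Mapping[str, Sequence[DnmCandidate]],
    funnels: Mapping[str, Mapping[str, int]] | None = None,
) -> "pd.DataFrame":
    """Per-offspring SNV / INDEL / total counts, plus funnel stages if given."""
    import pandas as pd

    rows = []
    for off, cands in final_sets.items():
        n_snv = sum(c.is_snv for c in cands)
        row = {
            "offspring": off,
            "final_snvs": n_snv,
            "final_indels": len(cands) - n_snv,
            "final_total": len(cands),
        }
        if funnels and off in funnels:
            for stage, n in funnels[off].items():
                row[stage] = n
        rows.append(row)
    return pd.DataFrame(rows)


def score_against_truth(
    final_sets: Mapping[str, Sequence[DnmCandidate]],
    truth_keys: Mapping[str, set[VariantKey]],
    artifact_classes: Mapping[str, Mapping[VariantKey, str]] | None = None,
) -> dict[str, dict[str, float]]:
    """Precision/recall of final DNM calls against simulator truth.

    ``truth_keys`` maps offspring -> set of true-DNM variant keys;
    ``artifact_classes`` (optional) maps offspring -> {key: class label}
    for leakage accounting.  Exact-key matching throughout.
    """
    if truth_keys is None:
        raise ValueError("truth required for scoring")
    out: dict[str, dict[str, float]] = {}
    for off, cands in final_sets.items():
        truth = truth_keys.get(off, set())
        called = {c.key for c in cands}
        tp = len(called & truth)
        precision = tp / len(called) if called else (1.0 if not truth else 0.0)
        recall = tp / len(truth) if truth else 1.0
        row: dict[str, float] = {
            "precision": precision,
            "recall": recall,
            "tp": float(tp),
            "fp": float(len(called - truth)),
            "fn": float(len(truth - called)),
        }
        if artifact_classes and off in artifact_classes:
            leaked: dict[str, int] = {}
            for key in called - truth:
                cls = artifact_classes[off].get(key, "unknown")
                leaked[cls] = leaked.get(cls, 0) + 1
            for cls, n in leaked.items():
                row[f"leaked_{cls}"] = float(n)
        out[off] = row
    return out
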