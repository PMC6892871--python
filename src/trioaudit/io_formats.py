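"""Minimal VCF / BED / FASTA I/O with fixed coordinate conventions.

All internal coordinates are 0-based half-open; the 1-based VCF convention
is converted at the file boundary.  The VCF dialect modelled here is the
subset the trio pipeline consumes: site annotations ``QD``, ``MQ`` and a
4-field strand-count vector ``SB`` in INFO, and ``GT``/``DP``/``GQ``/``AD``
per genotype.  Missing annotations stay missing (``None``) — they are never
silently coerced to zero, so downstream filters can distinguish "failed"
from "unevaluable".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenotypeCall",
    "VariantRecord",
    "MaskIntervals",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
]

_BASES = set("ACGT")

#: INFO-key mappings per caller dialect.  The four callers the audit
#: consumes emit site annotations under different INFO keys; each dialect
#: maps the modelled names onto the caller's own.  ``generic`` is the
#: identity mapping used for simulator output.
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {"QD": "QD", "MQ": "MQ", "SB": "SB"},
    "gatk": {"QD": "QD", "MQ": "MQ", "SB": "SB"},
    "platypus": {"QD": "QD", "MQ": "MQ", "SB": "SB"},
    "freebayes": {"QD": "QD", "MQ": "MQ", "SB": "SB"},
    "samtools": {"QD": "QD", "MQ": "MQ", "SB": "SB"},
}


class VcfParseError(ValueError):
    """Raised when a VCF body cannot be parsed into the modelled dialect."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site.

    ``gt`` is an unordered pair of allele indices (0 = REF) or ``None`` when
    the genotype is missing; ``ad`` holds per-allele read depths in allele
    order (REF first).
    """

    sample: str
    gt: tuple[int, int] | None
    dp: int | None = None
    gq: int | None = None
    ad: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.gq is not None and self.gq < 0:
            raise ValueError(f"GQ must be >= 0, got {self.gq}")
        if self.dp is not None and self.ad is not None and sum(self.ad) > self.dp:
            raise ValueError(
                f"sum(AD)={sum(self.ad)} exceeds DP={self.dp} for sample {self.sample}"
            )

    @property
    def alleles(self) -> tuple[int, ...]:
        return () if self.gt is None else tuple(sorted(self.gt))

    def is_het(self) -> bool:
        return self.gt is not None and self.gt[0] != self.gt[1]


@dataclass(frozen=True)
class VariantRecord:
    """One variant site with per-sample calls.

    ``start`` is 0-based; ``pos`` exposes the 1-based VCF position.
    ``strand_counts`` is (ref-fwd, ref-rev, alt-fwd, alt-rev).
    """

    chrom: str
    start: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    qd: float | None = None
    mq: float | None = None
    strand_counts: tuple[int, int, int, int] | None = None
    calls: tuple[GenotypeCall, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if not self.ref or not self.alts:
            raise ValueError("ref and alts must be non-empty")
        for allele in (self.ref, *self.alts):
            if not (set(allele) <= _BASES or allele.startswith("<")):
                raise ValueError(f"invalid allele {allele!r}")
        if self.strand_counts is not None:
            if len(self.strand_counts) != 4 or any(c < 0 for c in self.strand_counts):
                raise ValueError(f"bad strand counts {self.strand_counts}")
        n_alleles = 1 + len(self.alts)
        for call in self.calls:
            if call.gt is not None and any(a >= n_alleles or a < 0 for a in call.gt):
                raise ValueError(
                    f"allele index out of range in GT {call.gt} for {self.chrom}:{self.pos}"
                )

    @property
    def pos(self) -> int:
        """1-based position of the first REF base."""
        return self.start + 1

    @property
    def end(self) -> int:
        """0-based half-open end of the REF span."""
        return self.start + len(self.ref)

    def call(self, sample: str) -> GenotypeCall:
        for c in self.calls:
            if c.sample == sample:
                return c
        raise KeyError(f"no call for sample {sample!r} at {self.chrom}:{self.pos}")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(c.sample for c in self.calls)

    def key(self) -> tuple[str, int, str, str]:
        """Allele-specific variant key (biallelic records only)."""
        if len(self.alts) != 1:
            raise ValueError("variant key requires a biallelic record")
        return (self.chrom, self.start, self.ref, self.alts[0])

    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def split_multiallelic(self) -> list["VariantRecord"]:
        """Split into per-ALT biallelic records.

        AD vectors collapse to (ref, that alt); genotypes are re-expressed
        against the two retained alleles, with calls carrying a different
        alt becoming ref-calls for the retained pair.
        """
        if len(self.alts) == 1:
            return [self]
        out = []
        for ai, alt in enumerate(self.alts, start=1):
            calls = []
            for c in self.calls:
                gt = None
                if c.gt is not None:
                    gt = tuple(1 if a == ai else 0 for a in c.gt)  # type: ignore[assignment]
                ad = None
                if c.ad is not None and len(c.ad) > ai:
                    ad = (c.ad[0], c.ad[ai])
                calls.append(replace(c, gt=gt, ad=ad))
            out.append(replace(self, alts=(alt,), calls=tuple(calls)))
        return out


# ---------------------------------------------------------------------------
# VCF


def _build_header(samples: Sequence[str], contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("QD", number=1, type="Float", description="Variant confidence / quality by depth")
    header.info.add("MQ", number=1, type="Float", description="RMS mapping quality")
    header.info.add("SB", number=4, type="Integer", description="Strand counts: ref-fwd,ref-rev,alt-fwd,alt-rev")
    header.formats.add("GT", number=1, type="String", description="Genotype")
    header.formats.add("DP", number=1, type="Integer", description="Read depth")
    header.formats.add("GQ", number=1, type="Integer", description="Genotype quality")
    header.formats.add("AD", number="R", type="Integer", description="Per-allele read depths")
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write records as an uncompressed minimal VCF.

    ``contigs`` maps contig name to length; when omitted, lengths are taken
    as the maximum record end per contig (sufficient for round-trips).
    Records may only reference declared samples.
    """
    records = list(records)
    declared = set(samples)
    for rec in records:
        extra = set(rec.samples) - declared
        if extra:
            raise ValueError(f"record {rec.chrom}:{rec.pos} references undeclared samples {sorted(extra)}")
    if contigs is None:
        contigs = {}
        for rec in records:
            contigs[rec.chrom] = max(contigs.get(rec.chrom, 0), rec.end + 1)
        if not contigs:
            contigs = {"chr1": 1}
    header = _build_header(samples, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.chrom, r.start)):
            row = out.new_record(
                contig=rec.chrom,
                start=rec.start,
                alleles=(rec.ref, *rec.alts),
            )
            row.qual = rec.qual
            if rec.qd is not None:
                row.info["QD"] = rec.qd
            if rec.mq is not None:
                row.info["MQ"] = rec.mq
            if rec.strand_counts is not None:
                row.info["SB"] = rec.strand_counts
            by_sample = {c.sample: c for c in rec.calls}
            for s in samples:
                call = by_sample.get(s)
                if call is None:
                    row.samples[s]["GT"] = (None, None)
                    continue
                row.samples[s]["GT"] = call.gt if call.gt is not None else (None, None)
                if call.dp is not None:
                    row.samples[s]["DP"] = call.dp
                if call.gq is not None:
                    row.samples[s]["GQ"] = call.gq
                if call.ad is not None:
                    row.samples[s]["AD"] = call.ad
            out.write(row)


_MODELED_FORMAT = {"GT", "DP", "GQ", "AD"}


def read_vcf(path: str | Path, dialect: str = "generic") -> list[VariantRecord]:
    """Read a minimal-dialect VCF into :class:`VariantRecord` objects.

    ``dialect`` selects the caller-specific INFO-key mapping (see
    :data:`DIALECTS`).  Multi-allelic lines are preserved as single records;
    FORMAT keys outside the modelled set are ignored with a warning.
    """
    keymap = DIALECTS.get(dialect)
    if keymap is None:
        raise ValueError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    records: list[VariantRecord] = []
    warned_keys: set[str] = set()
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    declared_info = set(vf.header.info.keys())

    def info_get(rec, key):
        return rec.info.get(key) if key in declared_info else None

    with vf:
        try:
            for rec in vf:
                extra = set(rec.format.keys()) - _MODELED_FORMAT - warned_keys
                for k in extra:
                    warnings.warn(f"ignoring unmodelled FORMAT key {k!r} in {path}")
                    warned_keys.add(k)
                sb = info_get(rec, keymap["SB"])
                calls = []
                for s in rec.samples.values():
                    gt = s.get("GT")
                    if gt is None or any(a is None for a in gt):
                        gt = None
                    ad = s.get("AD")
                    if ad is not None and any(a is None for a in ad):
                        ad = None
                    calls.append(
                        GenotypeCall(
                            sample=s.name,
                            gt=tuple(gt) if gt is not None else None,
                            dp=s.get("DP"),
                            gq=s.get("GQ"),
                            ad=tuple(ad) if ad is not None else None,
                        )
                    )
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        start=rec.start,
                        ref=rec.ref,
                        alts=tuple(rec.alts or ()),
                        qual=rec.qual,
                        qd=info_get(rec, keymap["QD"]),
                        mq=info_get(rec, keymap["MQ"]),
                        strand_counts=tuple(sb) if sb is not None else None,
                        calls=tuple(calls),
                    )
                )
        except (OSError, ValueError) as exc:
            raise VcfParseError(f"malformed VCF body in {path}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# BED / mask intervals


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class MaskIntervals:
    """Per-chromosome sorted, merged, disjoint half-open intervals.

    Coordinates are 0-based half-open.  ``label`` names the mask component
    (mappability | low-complexity | repeat | merged).
    """

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    label: str = "merged"

    @classmethod
    def from_tuples(
        cls, tuples: Iterable[tuple[str, int, int]], label: str = "merged"
    ) -> "MaskIntervals":
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            if start < 0:
                raise ValueError(f"negative start {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end))
        return cls({c: _merge_intervals(iv) for c, iv in per_chrom.items()}, label)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self.intervals):
            for start, end in self.intervals[chrom]:
                yield chrom, start, end

    def __len__(self) -> int:
        return sum(len(iv) for iv in self.intervals.values())

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) intersects any mask interval on chrom."""
        import bisect

        iv = self.intervals.get(chrom)
        if not iv:
            return False
        i = bisect.bisect_right([s for s, _ in iv], start)
        if i > 0 and iv[i - 1][1] > start:
            return True
        return i < len(iv) and iv[i][0] < end

    def union(self, *others: "MaskIntervals", label: str = "merged") -> "MaskIntervals":
        tuples = list(self)
        for o in others:
            tuples.extend(o)
        return MaskIntervals.from_tuples(tuples, label) if tuples else MaskIntervals(label=label)


def read_bed(path: str | Path, label: str = "merged") -> MaskIntervals:
    """Read a 3-column BED (0-based half-open) into merged mask intervals."""
    tuples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            tuples.append((chrom, start, end))
    if not tuples:
        return MaskIntervals(label=label)
    return MaskIntervals.from_tuples(tuples, label)


def write_bed(mask: MaskIntervals, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in mask:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# SV records (BED-like TSV dialect)


def read_sv_tsv(path: str | Path) -> list:
    """Read SV calls from a TSV: chrom, start, end, svtype, support,
    precise(0/1), filter, sample[, ins_length]."""
    from trioaudit.sv_consensus import SvRecord

    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "chrom")):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected >=8 SV columns")
            records.append(
                SvRecord(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    svtype=fields[3],
                    support=int(fields[4]),
                    precise=bool(int(fields[5])),
                    filter_label=fields[6],
                    sample=fields[7],
                    ins_length=int(fields[8]) if len(fields) > 8 and fields[8] else None,
                )
            )
    return records


def write_sv_tsv(records, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsvtype\tsupport\tprecise\tfilter\tsample\tins_length\n")
        for r in records:
            ins = r.ins_length if r.ins_length is not None else ""
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.svtype}\t{r.support}"
                f"\t{int(r.precise)}\t{r.filter_label}\t{r.sample}\t{ins}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}; names to first whitespace."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
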