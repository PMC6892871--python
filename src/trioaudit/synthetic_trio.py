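"""Synthetic trio generator with recorded ground truth.

Builds a small random reference genome carrying a planted sgRNA target
site and off-target sites, then a father/mother/offspring family with

* independent parental heterozygous variants inherited Mendelianly,
* true de novo mutations (germline fraction 0.5 or mosaic fractions),
* Mendelian-violation artifacts whose alleles exist in the parents — the
  dominant genotyping-error class in real trio data (e.g. parents A/A and
  G/G with the offspring read as G/G),
* sibling-shared artifact calls, database-known artifact calls, and
  caller-specific false positives / dropouts,
* a universal mask (random "mappability"/"repeat" intervals plus real
  homopolymer runs), a known-variant database drawn from parental
  variants, target-window reads with cut-site deletions, and inherited /
  shared / de novo structural variants.

Every artifact class is constructed to be removable by exactly one
pipeline stage, so class-filter correspondence is checkable.  All
randomness flows from ``SimulationConfig.seed`` through per-purpose
streams: the same config is byte-identical on re-run, and adding a new
simulation feature does not perturb existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from trioaudit.dnm_pipeline import KnownVariantDb
from trioaudit.io_formats import GenotypeCall, MaskIntervals, VariantRecord
from trioaudit.offtarget_scan import (
    PROTOSPACER_LEN,
    SITE_LEN,
    OffTargetSite,
    Protospacer,
    TargetReadRecord,
    cut_site_of,
    revcomp,
)
from trioaudit.power_stats import min_supporting_reads
from trioaudit.sv_consensus import SvRecord

__all__ = ["SimulationConfig", "SimVariant", "TruthSet", "TrioSimulator"]

_BASES = "ACGT"

# variant classes and the pipeline stage responsible for removing them
CLASS_FILTER = {
    "dnm": None,  # must survive
    "parental_het": None,  # not a candidate at all (Mendelian-consistent)
    "artifact_parental": "AF",
    "artifact_other": "AF",
    "artifact_shared": "CF",
    "artifact_db": "dbSNPF",
    "artifact_caller": "noStrict",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic trio.

    Defaults describe an error-free 1-Mb family sequenced at uniform 40x:
    parental heterozygosity 1 per kb, 20 true DNMs per offspring (drawn
    from germline and two-cell mosaic fractions), 200 parental-allele
    artifacts plus 5 sibling-shared and 3 database-known artifacts per
    offspring, no caller dropout or false positives, and 5% of the genome
    masked.  ``condition_detectable`` keeps true-DNM alt-read draws at or
    above the calling threshold, which is what "error-free annotations"
    means for read sampling; switch it off for power studies.
    """

    genome_length: int = 1_000_000
    n_chroms: int = 2
    seed: int = 0
    parental_het_rate: float = 1e-3
    dnm_count: int = 20
    mosaic_fraction_options: tuple[float, ...] = (0.5, 0.25)
    artifact_count: int = 200
    other_violation_fraction: float = 0.05
    shared_artifact_count: int = 5
    db_artifact_count: int = 3
    caller_dropout: float = 0.0
    caller_fp_rate: float = 0.0
    sf_violation_rate: float = 0.0
    gf_violation_rate: float = 0.0
    known_db_fraction: float = 0.5
    mask_fraction: float = 0.05
    depth_mean: int = 40
    depth_sd: float = 0.0
    gq_high: int = 99
    gq_low: int = 20
    min_af: float = 0.10
    #: allele-balance pass bound the error-free regime must clear (matches
    #: the default site-filter ab_min)
    min_pass_fraction: float = 0.10
    condition_detectable: bool = True
    #: 0 = exactly balanced strand counts (error-free); >0 = binomial split
    strand_noise: float = 0.0
    n_offspring: int = 2
    n_callers: int = 4
    sgRNA: str = "CCTATGTTGAAGTGTGGTCA"
    planted_offtarget_mismatches: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    on_target_ratio: float = 0.435
    n_target_reads: int = 1000
    n_inherited_svs: int = 5
    n_shared_svs: int = 2
    n_known_svs: int = 3
    n_denovo_svs: int = 0

    def __post_init__(self) -> None:
        for name in (
            "parental_het_rate",
            "caller_dropout",
            "caller_fp_rate",
            "sf_violation_rate",
            "gf_violation_rate",
            "known_db_fraction",
            "mask_fraction",
            "other_violation_fraction",
            "on_target_ratio",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1 kb")
        if self.n_offspring < 1 or self.n_chroms < 1 or self.n_callers < 2:
            raise ValueError("need >=1 offspring, >=1 chromosome, >=2 callers")

    @property
    def samples(self) -> tuple[str, ...]:
        return ("F", "M", *self.offspring)

    @property
    def offspring(self) -> tuple[str, ...]:
        return tuple(f"O{i + 1}" for i in range(self.n_offspring))


@dataclass(frozen=True)
class SimVariant:
    """A true (or erroneously observed) small variant with per-sample truth.

    ``gts`` holds the genotypes the callers will report; for artifacts the
    offspring entry is the erroneous call.  ``fractions`` gives per-sample
    alt-allele fractions for read sampling.  ``cls`` is the variant class
    and ``owner`` the offspring an offspring-specific event belongs to
    (empty for family-wide variants).
    """

    chrom: str
    start: int
    ref: str
    alt: str
    gts: dict[str, tuple[int, int]]
    fractions: dict[str, float]
    cls: str
    owner: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.start, self.ref, self.alt)


@dataclass
class TruthSet:
    """Ground truth of one simulated family, for scoring pipeline output."""

    variants: list[SimVariant]
    true_dnm_keys: dict[str, set[tuple[str, int, str, str]]]
    artifact_classes: dict[str, dict[tuple[str, int, str, str], str]]
    known_db: KnownVariantDb
    on_target: OffTargetSite | None = None
    cut_site: int | None = None
    planted_offtargets: list[OffTargetSite] = field(default_factory=list)
    sv_truth: dict[str, list[SvRecord]] = field(default_factory=dict)
    dnm_fractions: dict[tuple[str, str, int], float] = field(default_factory=dict)


class TrioSimulator:
    """Deterministic generator for one synthetic family and its call sets."""

    def __init__(self, config: SimulationConfig | None = None):
        self.config = config or SimulationConfig()
        self._occupied: dict[str, list[tuple[int, int]]] = {}

    # -- random streams ---------------------------------------------------

    def _rng(self, label: str) -> np.random.Generator:
        return np.random.default_rng([self.config.seed, zlib.crc32(label.encode())])

    # -- reference and planted sites --------------------------------------

    def _reserve(self, chrom: str, start: int, end: int) -> bool:
        """Reserve [start, end) if free; returns False on collision."""
        for s, e in self._occupied.get(chrom, ()):
            if start < e and end > s:
                return False
        self._occupied.setdefault(chrom, []).append((start, end))
        return True

    def simulate_reference(self) -> tuple[dict[str, str], OffTargetSite]:
        """Uniform-random genome with the on-target site planted once."""
        cfg = self.config
        rng = self._rng("reference")
        per_chrom = cfg.genome_length // cfg.n_chroms
        if per_chrom < 200:
            raise ValueError("chromosomes too short to host planted sites")
        seqs = {
            f"chr{i + 1}": "".join(rng.choice(list(_BASES), size=per_chrom))
            for i in range(cfg.n_chroms)
        }
        ps = Protospacer(cfg.sgRNA)
        pos = int(rng.integers(100, per_chrom - 100 - SITE_LEN))
        site_seq = ps.seq + "TGG"
        chrom = "chr1"
        seqs[chrom] = seqs[chrom][:pos] + site_seq + seqs[chrom][pos + SITE_LEN :]
        self._reserve(chrom, pos - 5, pos + SITE_LEN + 5)
        on_target = OffTargetSite(
            chrom=chrom, start=pos, strand="+", mismatches=0, pam_observed="TGG", is_on_target=True
        )
        return seqs, on_target

    def plant_offtargets(
        self, reference: dict[str, str], k_list: Sequence[int] | None = None
    ) -> tuple[dict[str, str], list[OffTargetSite]]:
        """Plant one off-target site per mismatch count in ``k_list``."""
        cfg = self.config
        rng = self._rng("offtargets")
        k_list = tuple(k_list) if k_list is not None else cfg.planted_offtarget_mismatches
        ps = Protospacer(cfg.sgRNA)
        seqs = dict(reference)
        chroms = sorted(seqs)
        planted: list[OffTargetSite] = []
        for k in k_list:
            if not 0 <= k <= PROTOSPACER_LEN:
                raise ValueError(f"mismatch count {k} out of range")
            proto = list(ps.seq)
            mm_pos = rng.choice(PROTOSPACER_LEN, size=k, replace=False)
            for j in mm_pos:
                choices = [b for b in _BASES if b != proto[j]]
                proto[j] = choices[int(rng.integers(3))]
            pam = rng.choice(list(_BASES)) + ("GG" if rng.random() < 0.5 else "AG")
            site_plus = "".join(proto) + pam
            strand = "+" if rng.random() < 0.5 else "-"
            insert = site_plus if strand == "+" else revcomp(site_plus)
            for _ in range(1000):  # redraw on collision
                chrom = chroms[int(rng.integers(len(chroms)))]
                L = len(seqs[chrom])
                pos = int(rng.integers(100, L - 100 - SITE_LEN))
                if self._reserve(chrom, pos - 5, pos + SITE_LEN + 5):
                    break
            else:
                raise RuntimeError("could not place planted off-target site")
            seqs[chrom] = seqs[chrom][:pos] + insert + seqs[chrom][pos + SITE_LEN :]
            planted.append(
                OffTargetSite(
                    chrom=chrom,
                    start=pos,
                    strand=strand,
                    mismatches=int(k),
                    pam_observed=pam,
                    is_on_target=False,
                )
            )
        return seqs, planted

    # -- masks -------------------------------------------------------------

    def simulate_masks(self, reference: dict[str, str]) -> list[MaskIntervals]:
        """Mappability + repeat random components plus homopolymer runs."""
        cfg = self.config
        rng = self._rng("masks")
        total = sum(len(s) for s in reference.values())
        target = cfg.mask_fraction * total
        components: dict[str, list[tuple[str, int, int]]] = {"mappability": [], "repeat": []}
        budget = {"mappability": 0.6 * target, "repeat": 0.4 * target}
        chroms = sorted(reference)
        for label, quota in budget.items():
            covered = 0.0
            guard = 0
            while covered < quota and guard < 100_000:
                guard += 1
                chrom = chroms[int(rng.integers(len(chroms)))]
                L = len(reference[chrom])
                # clip to the remaining quota so coverage lands on target
                length = min(int(rng.integers(200, 2000)), max(50, int(quota - covered)))
                start = int(rng.integers(0, max(1, L - length)))
                # keep planted guide sites out of the mask
                if any(
                    start < e and start + length > s
                    for s, e in self._occupied.get(chrom, ())
                ):
                    continue
                components[label].append((chrom, start, start + length))
                covered += length
        homopolymers = []
        for chrom in chroms:
            seq = reference[chrom]
            i = 0
            L = len(seq)
            while i < L:
                j = i + 1
                while j < L and seq[j] == seq[i]:
                    j += 1
                if j - i >= 10:
                    homopolymers.append((chrom, i, j))
                i = j
        out = []
        for label, tuples in components.items():
            out.append(
                MaskIntervals.from_tuples(tuples, label)
                if tuples
                else MaskIntervals(label=label)
            )
        out.append(
            MaskIntervals.from_tuples(homopolymers, "low-complexity")
            if homopolymers
            else MaskIntervals(label="low-complexity")
        )
        return out

    # -- family variants ---------------------------------------------------

    def _free_positions(
        self,
        reference: dict[str, str],
        mask: MaskIntervals,
        used: set[tuple[str, int]],
        n: int,
        rng: np.random.Generator,
    ) -> list[tuple[str, int]]:
        chroms = sorted(reference)
        out: list[tuple[str, int]] = []
        guard = 0
        while len(out) < n:
            guard += 1
            if guard > 200 * n + 10_000:
                raise RuntimeError("not enough free positions for requested variants")
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = len(reference[chrom])
            pos = int(rng.integers(10, L - 10))
            if (chrom, pos) in used:
                continue
            if mask.overlaps(chrom, pos, pos + 1):
                continue
            if any(pos < e and pos + 1 > s for s, e in self._occupied.get(chrom, ())):
                continue
            used.add((chrom, pos))
            out.append((chrom, pos))
        return out

    def _alt_base(self, ref_base: str, rng: np.random.Generator) -> str:
        choices = [b for b in _BASES if b != ref_base]
        return choices[int(rng.integers(3))]

    def simulate_trio(
        self, reference: dict[str, str], mask: MaskIntervals
    ) -> TruthSet:
        """Generate family genotype truth: inherited variants, DNMs, artifacts."""
        cfg = self.config
        rng = self._rng("trio")
        total = sum(len(s) for s in reference.values())
        used: set[tuple[str, int]] = set()
        variants: list[SimVariant] = []
        offspring = cfg.offspring

        def hom_ref_others(gts: dict[str, tuple[int, int]]) -> dict[str, tuple[int, int]]:
            for s in cfg.samples:
                gts.setdefault(s, (0, 0))
            return gts

        def fractions_from_gts(gts: dict[str, tuple[int, int]]) -> dict[str, float]:
            return {s: sum(g) / 2 for s, g in gts.items()}

        # parental heterozygous variants, independent per parent
        for parent in ("F", "M"):
            n_het = int(rng.binomial(total, cfg.parental_het_rate))
            for chrom, pos in self._free_positions(reference, mask, used, n_het, rng):
                ref_base = reference[chrom][pos]
                alt = self._alt_base(ref_base, rng)
                gts: dict[str, tuple[int, int]] = {parent: (0, 1)}
                for off in offspring:
                    transmitted = int(rng.integers(2))  # one allele from the het parent
                    gts[off] = (0, transmitted)
                hom_ref_others(gts)
                gts = {s: tuple(sorted(g)) for s, g in gts.items()}  # type: ignore[misc]
                variants.append(
                    SimVariant(
                        chrom, pos, ref_base, alt, gts, fractions_from_gts(gts), "parental_het"
                    )
                )

        # true DNMs, positions free of parental variants and distinct per sibling
        true_dnm_keys: dict[str, set] = {o: set() for o in offspring}
        dnm_fractions: dict[tuple[str, str, int], float] = {}
        for off in offspring:
            for chrom, pos in self._free_positions(reference, mask, used, cfg.dnm_count, rng):
                ref_base = reference[chrom][pos]
                alt = self._alt_base(ref_base, rng)
                frac = float(
                    cfg.mosaic_fraction_options[
                        int(rng.integers(len(cfg.mosaic_fraction_options)))
                    ]
                )
                gts = hom_ref_others({off: (0, 1)})
                fr = fractions_from_gts(gts)
                fr[off] = frac
                v = SimVariant(chrom, pos, ref_base, alt, gts, fr, "dnm", owner=off)
                variants.append(v)
                true_dnm_keys[off].add(v.key)
                dnm_fractions[(off, chrom, pos)] = frac

        artifact_classes: dict[str, dict] = {o: {} for o in offspring}

        # parental-allele Mendelian violations (dominant artifact class):
        # parents homozygous for different alleles; offspring erroneously
        # read as homozygous for one of them instead of het.
        n_other = int(round(cfg.other_violation_fraction * cfg.artifact_count))
        n_parental = cfg.artifact_count - n_other
        for off in offspring:
            for chrom, pos in self._free_positions(reference, mask, used, n_parental, rng):
                ref_base = reference[chrom][pos]
                alt = self._alt_base(ref_base, rng)
                if rng.random() < 0.5:
                    gts = {"F": (0, 0), "M": (1, 1), off: (1, 1) if rng.random() < 0.5 else (0, 0)}
                else:
                    gts = {"F": (1, 1), "M": (0, 0), off: (1, 1) if rng.random() < 0.5 else (0, 0)}
                hom_ref_others(gts)
                v = SimVariant(
                    chrom, pos, ref_base, alt, gts, fractions_from_gts(gts),
                    "artifact_parental", owner=off,
                )
                variants.append(v)
                artifact_classes[off][v.key] = "artifact_parental"
            # other violations: alleles still present in parents
            for chrom, pos in self._free_positions(reference, mask, used, n_other, rng):
                ref_base = reference[chrom][pos]
                alt = self._alt_base(ref_base, rng)
                gts = hom_ref_others({"F": (0, 1), "M": (0, 0), off: (1, 1)})
                v = SimVariant(
                    chrom, pos, ref_base, alt, gts, fractions_from_gts(gts),
                    "artifact_other", owner=off,
                )
                variants.append(v)
                artifact_classes[off][v.key] = "artifact_other"

        # sibling-shared artifacts: novel allele, same key in every offspring
        for chrom, pos in self._free_positions(
            reference, mask, used, cfg.shared_artifact_count, rng
        ):
            ref_base = reference[chrom][pos]
            alt = self._alt_base(ref_base, rng)
            gts = hom_ref_others({off: (0, 1) for off in offspring})
            fr = fractions_from_gts(gts)
            v = SimVariant(chrom, pos, ref_base, alt, gts, fr, "artifact_shared")
            variants.append(v)
            for off in offspring:
                artifact_classes[off][v.key] = "artifact_shared"

        # database-known artifacts: novel allele, private, but in the known DB
        db_artifact_keys = []
        for off in offspring:
            for chrom, pos in self._free_positions(
                reference, mask, used, cfg.db_artifact_count, rng
            ):
                ref_base = reference[chrom][pos]
                alt = self._alt_base(ref_base, rng)
                gts = hom_ref_others({off: (0, 1)})
                v = SimVariant(
                    chrom, pos, ref_base, alt, gts, fractions_from_gts(gts),
                    "artifact_db", owner=off,
                )
                variants.append(v)
                artifact_classes[off][v.key] = "artifact_db"
                db_artifact_keys.append((chrom, pos, alt))

        # known-variant database: a fraction of parental variants + DB artifacts
        db_rng = self._rng("known_db")
        db_keys = set()
        for v in variants:
            if v.cls == "parental_het" and db_rng.random() < cfg.known_db_fraction:
                db_keys.add((v.chrom, v.start, v.alt))
        db_keys.update(db_artifact_keys)
        known_db = KnownVariantDb(keys=db_keys, build="synthetic-150")

        return TruthSet(
            variants=variants,
            true_dnm_keys=true_dnm_keys,
            artifact_classes=artifact_classes,
            known_db=known_db,
            dnm_fractions=dnm_fractions,
        )

    # -- caller views ------------------------------------------------------

    def render_caller_views(
        self,
        truth: TruthSet,
        reference: dict[str, str],
        mask: MaskIntervals | None = None,
    ) -> dict[str, list[VariantRecord]]:
        """Per-caller multi-sample call sets with sampled annotations.

        Depth is drawn around ``depth_mean`` and AD binomially at each
        sample's true allele fraction, once per variant-sample: the read
        pile-up is a property of the sample, so every caller sees the same
        AD.  Offspring calls at true-DNM sites follow the detection rule
        (het iff alt reads reach the minimum allele-frequency threshold).
        Caller-specific dropouts and false positives, plus configurable
        SF/GF-violating annotation fractions, are injected per caller.
        """
        cfg = self.config
        views: dict[str, list[VariantRecord]] = {}
        used_fp: set[tuple[str, int]] = {(v.chrom, v.start) for v in truth.variants}
        reads_rng = self._rng("reads")
        ad_map = {
            v.key: self._sample_reads(v, reads_rng) for v in truth.variants
        }
        for ci in range(cfg.n_callers):
            caller = f"caller{ci + 1}"
            rng = self._rng(f"view-{caller}")
            records: list[VariantRecord] = []
            for v in truth.variants:
                if cfg.caller_dropout > 0 and rng.random() < cfg.caller_dropout:
                    continue
                records.append(self._render_record(v, rng, ad_map[v.key]))
            # caller-specific false positives (removed by caller overlap)
            if cfg.caller_fp_rate > 0:
                n_fp = int(rng.poisson(cfg.caller_fp_rate * max(1, len(truth.variants))))
                chroms = sorted(reference)
                for _ in range(n_fp):
                    chrom = chroms[int(rng.integers(len(chroms)))]
                    pos = int(rng.integers(10, len(reference[chrom]) - 10))
                    if (chrom, pos) in used_fp:
                        continue
                    if mask is not None and mask.overlaps(chrom, pos, pos + 1):
                        continue
                    used_fp.add((chrom, pos))
                    ref_base = reference[chrom][pos]
                    alt = self._alt_base(ref_base, rng)
                    off = cfg.offspring[int(rng.integers(len(cfg.offspring)))]
                    gts = {s: (0, 0) for s in cfg.samples}
                    gts[off] = (0, 1)
                    fr = {s: sum(g) / 2 for s, g in gts.items()}
                    fp = SimVariant(chrom, pos, ref_base, alt, gts, fr, "artifact_caller", owner=off)
                    records.append(self._render_record(fp, rng, self._sample_reads(fp, rng)))
            records.sort(key=lambda r: (r.chrom, r.start))
            views[caller] = records
        return views

    def _sample_reads(
        self, v: SimVariant, rng: np.random.Generator
    ) -> dict[str, tuple[int, int]]:
        """Draw (depth, alt reads) per sample for one variant — once, since
        the pile-up is shared by all callers."""
        cfg = self.config
        out: dict[str, tuple[int, int]] = {}
        for s in cfg.samples:
            frac = v.fractions.get(s, 0.0)
            if cfg.depth_sd > 0:
                dp = max(1, int(round(rng.normal(cfg.depth_mean, cfg.depth_sd))))
            else:
                dp = cfg.depth_mean
            alt_reads = int(rng.binomial(dp, frac)) if frac > 0 else 0
            if v.cls == "dnm" and s == v.owner and cfg.condition_detectable:
                # error-free regime: the draw must both meet the calling
                # rule and clear the allele-balance pass bound
                m_needed = min_supporting_reads(dp, cfg.min_af)
                floor_needed = max(m_needed, int(cfg.min_pass_fraction * dp) + 1)
                guard = 0
                while alt_reads < floor_needed and guard < 10_000:
                    alt_reads = int(rng.binomial(dp, frac))
                    guard += 1
                if alt_reads < floor_needed:
                    alt_reads = floor_needed
            out[s] = (dp, alt_reads)
        return out

    def _render_record(
        self,
        v: SimVariant,
        rng: np.random.Generator,
        reads: dict[str, tuple[int, int]],
    ) -> VariantRecord:
        cfg = self.config
        calls = []
        for s in cfg.samples:
            gt = v.gts.get(s, (0, 0))
            dp, alt_reads = reads[s]
            if v.cls == "dnm" and s == v.owner:
                # detection rule: the caller reports the variant genotype
                # only when enough mutant reads were sampled
                m_needed = min_supporting_reads(dp, cfg.min_af)
                gt = (0, 1) if alt_reads >= m_needed else (0, 0)
            gq = cfg.gq_high
            if cfg.gf_violation_rate > 0 and v.cls == "parental_het":
                if rng.random() < cfg.gf_violation_rate:
                    gq = cfg.gq_low
            calls.append(GenotypeCall(sample=s, gt=gt, dp=dp, gq=gq, ad=(dp - alt_reads, alt_reads)))
        # site annotations drawn in the passing range; a configurable
        # fraction of inherited sites violates SF thresholds
        qd = float(rng.uniform(10, 30))
        mq = float(rng.uniform(40, 60))
        if cfg.sf_violation_rate > 0 and v.cls == "parental_het":
            if rng.random() < cfg.sf_violation_rate:
                qd = 1.0
        ref_total = sum(c.ad[0] for c in calls)
        alt_total = sum(c.ad[1] for c in calls)
        if cfg.strand_noise > 0:
            rf = int(rng.binomial(ref_total, 0.5)) if ref_total else 0
            af_ = int(rng.binomial(alt_total, 0.5)) if alt_total else 0
        else:
            rf, af_ = ref_total // 2, alt_total // 2
        return VariantRecord(
            chrom=v.chrom,
            start=v.start,
            ref=v.ref,
            alts=(v.alt,),
            qual=100.0,
            qd=qd,
            mq=mq,
            strand_counts=(rf, ref_total - rf, af_, alt_total - af_),
            calls=tuple(calls),
        )

    # -- target-region reads ----------------------------------------------

    def simulate_target_reads(
        self,
        cut_site: int,
        on_target_ratio: float | None = None,
        n_reads: int | None = None,
    ) -> list[TargetReadRecord]:
        """Reads spanning the cut site; an exact count carries a deletion there."""
        cfg = self.config
        ratio = cfg.on_target_ratio if on_target_ratio is None else on_target_ratio
        n = cfg.n_target_reads if n_reads is None else n_reads
        if n <= 0:
            raise ValueError("n_reads must be positive")
        rng = self._rng("target-reads")
        n_del = int(round(ratio * n))
        reads = []
        for i in range(n):
            left = cut_site - int(rng.integers(40, 100))
            right = cut_site + int(rng.integers(40, 100))
            deletions: tuple[tuple[int, int], ...] = ()
            if i < n_del:
                d_left = cut_site - int(rng.integers(1, 10))
                d_right = cut_site + int(rng.integers(1, 10))
                deletions = ((d_left, d_right),)
            reads.append(TargetReadRecord(read_id=f"read{i}", span=(left, right), deletions=deletions))
        return reads

    # -- structural variants ----------------------------------------------

    def simulate_svs(
        self,
    ) -> tuple[dict[str, dict[str, list[SvRecord]]], list[SvRecord], dict[str, list[SvRecord]]]:
        """Per-sample, per-caller SV call sets plus a known-SV database.

        Returns (call_sets[sample][caller], known_db, truth_by_class) where
        truth classes are inherited / shared / known / denovo.
        """
        cfg = self.config
        rng = self._rng("svs")
        chrom = "chr1"
        svtypes = ("DEL", "DUP", "INV")
        call_sets: dict[str, dict[str, list[SvRecord]]] = {
            s: {"svcallerA": [], "svcallerB": []} for s in cfg.samples
        }
        known: list[SvRecord] = []
        truth: dict[str, list[SvRecord]] = {"inherited": [], "shared": [], "known": [], "denovo": []}
        cursor = 10_000

        def new_event(length_lo: int = 100, length_hi: int = 5000) -> tuple[int, int, str]:
            nonlocal cursor
            length = int(rng.integers(length_lo, length_hi))
            start = cursor + int(rng.integers(0, 2000))
            cursor = start + length + 10_000
            return start, start + length, svtypes[int(rng.integers(len(svtypes)))]

        def emit(sample: str, start: int, end: int, svtype: str) -> SvRecord:
            base = SvRecord(
                chrom=chrom,
                start=start,
                end=end,
                svtype=svtype,
                support=int(rng.integers(12, 40)),
                precise=True,
                filter_label="PASS",
                sample=sample,
            )
            # second caller re-reports with small breakpoint jitter
            jitter = int(rng.integers(-10, 11))
            alt = SvRecord(
                chrom=chrom,
                start=max(0, start + jitter),
                end=end + jitter,
                svtype=svtype,
                support=int(rng.integers(12, 40)),
                precise=True,
                filter_label="PASS",
                sample=sample,
            )
            call_sets[sample]["svcallerA"].append(base)
            call_sets[sample]["svcallerB"].append(alt)
            return base

        for _ in range(cfg.n_inherited_svs):
            start, end, svtype = new_event()
            parent = "F" if rng.random() < 0.5 else "M"
            emit(parent, start, end, svtype)
            off = cfg.offspring[int(rng.integers(len(cfg.offspring)))]
            truth["inherited"].append(emit(off, start, end, svtype))
        for _ in range(cfg.n_shared_svs):
            start, end, svtype = new_event()
            for off in cfg.offspring:
                rec = emit(off, start, end, svtype)
                if off == cfg.offspring[0]:
                    truth["shared"].append(rec)
        for _ in range(cfg.n_known_svs):
            start, end, svtype = new_event()
            off = cfg.offspring[int(rng.integers(len(cfg.offspring)))]
            truth["known"].append(emit(off, start, end, svtype))
            known.append(
                SvRecord(chrom=chrom, start=start, end=end, svtype=svtype, support=99, sample="db")
            )
        for _ in range(cfg.n_denovo_svs):
            start, end, svtype = new_event(length_lo=200, length_hi=2000)
            off = cfg.offspring[int(rng.integers(len(cfg.offspring)))]
            truth["denovo"].append(emit(off, start, end, svtype))
        return call_sets, known, truth

    # -- everything --------------------------------------------------------

    def run(self) -> "SimulationResult":
        """Generate the full family: reference, masks, truth, call sets."""
        reference, on_target = self.simulate_reference()
        reference, planted = self.plant_offtargets(reference)
        components = self.simulate_masks(reference)
        from trioaudit.consensus_filtering import build_universal_mask

        mask = build_universal_mask(components)
        truth = self.simulate_trio(reference, mask)
        truth.on_target = on_target
        truth.cut_site = cut_site_of(on_target)
        truth.planted_offtargets = planted
        views = self.render_caller_views(truth, reference, mask)
        sv_sets, sv_known, sv_truth = self.simulate_svs()
        truth.sv_truth = sv_truth
        reads = self.simulate_target_reads(truth.cut_site)
        return SimulationResult(
            config=self.config,
            reference=reference,
            mask_components=components,
            mask=mask,
            truth=truth,
            caller_views=views,
            sv_sets=sv_sets,
            sv_known=sv_known,
            target_reads=reads,
        )


@dataclass
class SimulationResult:
    """Bundle of one simulated family and its synthetic call sets."""

    config: SimulationConfig
    reference: dict[str, str]
    mask_components: list[MaskIntervals]
    mask: MaskIntervals
    truth: TruthSet
    caller_views: dict[str, list[VariantRecord]]
    sv_sets: dict[str, dict[str, list[SvRecord]]]
    sv_known: list[SvRecord]
    target_reads: list[TargetReadRecord]

    def write(self, outdir: str) -> None:
        """Write reference FASTA, per-caller VCFs, mask BED, known-variant
        VCF, and truth tables as TSV."""
        import os

        from trioaudit.io_formats import write_bed, write_fasta, write_vcf

        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.reference, os.path.join(outdir, "reference.fa"))
        contigs = {c: len(s) for c, s in self.reference.items()}
        for caller, records in self.caller_views.items():
            write_vcf(
                records,
                self.config.samples,
                os.path.join(outdir, f"{caller}.vcf"),
                contigs=contigs,
            )
        write_bed(self.mask, os.path.join(outdir, "mask.bed"))
        with open(os.path.join(outdir, "known_db.tsv"), "w") as fh:
            fh.write("chrom\tpos0\talt\n")
            for chrom, pos, alt in sorted(self.truth.known_db.keys):
                fh.write(f"{chrom}\t{pos}\t{alt}\n")
        with open(os.path.join(outdir, "truth_variants.tsv"), "w") as fh:
            fh.write("chrom\tpos0\tref\talt\tclass\towner\n")
            for v in self.truth.variants:
                fh.write(f"{v.chrom}\t{v.start}\t{v.ref}\t{v.alt}\t{v.cls}\t{v.owner}\n")
        with open(os.path.join(outdir, "planted_offtargets.tsv"), "w") as fh:
            fh.write("chrom\tstart\tend\tstrand\tmismatches\tpam\n")
            sites = list(self.truth.planted_offtargets)
            if self.truth.on_target is not None:
                sites.append(self.truth.on_target)
            for s in sorted(sites, key=lambda s: (s.chrom, s.start)):
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.strand}\t{s.mismatches}\t{s.pam_observed}\n")
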