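"""CRISPR off-target site enumeration and target-region read analysis.

A candidate off-target site is any genomic 20-mer, on either strand, that
(1) is immediately followed (3') on the same strand by a PAM matching one
of the allowed patterns (NGG canonical for SpCas9; NAG tolerated), and
(2) lies within a Hamming-distance budget of the guide protospacer
(ungapped comparison).  Sites are reported in reference coordinates as a
23-bp footprint (protospacer + PAM).

The module also annotates DNMs falling near predicted sites and computes
the read-level on-target ratio: the fraction of reads spanning the cut
site that carry a deletion there, a proxy for the mosaic editing fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Protospacer",
    "OffTargetSite",
    "TargetReadRecord",
    "scan_offtargets",
    "annotate_dnm_proximity",
    "on_target_ratio",
    "cut_site_of",
    "expected_background_sites",
]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGT", "TGCA")

SITE_LEN = 23  # 20-nt protospacer + 3-nt PAM
PROTOSPACER_LEN = 20
#: Cas9 makes a blunt cut 3 bp 5' of the PAM (between protospacer
#: positions 17 and 18).
CUT_OFFSET_FROM_PAM = 3


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Protospacer:
    """A 20-nt guide sequence and its allowed PAM patterns.

    A 23-mer input is parsed as protospacer + PAM, with the trailing
    3-mer discarded (the genomic PAM is a property of the site, not the
    guide).
    """

    seq: str
    pam_rules: tuple[str, ...] = ("NGG", "NAG")
    name: str = "sgRNA"

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        if len(seq) == SITE_LEN:
            seq = seq[:PROTOSPACER_LEN]
        if len(seq) != PROTOSPACER_LEN:
            raise ValueError(f"protospacer must be 20 nt (or 23 with PAM); got {len(self.seq)}")
        if not set(seq) <= set("ACGT"):
            raise ValueError(f"protospacer has non-ACGT characters: {seq}")
        object.__setattr__(self, "seq", seq)
        for pam in self.pam_rules:
            if len(pam) != 3 or not set(pam) <= set("ACGTN"):
                raise ValueError(f"bad PAM pattern {pam!r}")


@dataclass(frozen=True)
class OffTargetSite:
    """A genomic locus matching the protospacer within k mismatches.

    ``start``/``end`` delimit the 23-bp footprint (protospacer + PAM) in
    reference coordinates, 0-based half-open, regardless of strand.  On the
    + strand the PAM occupies the footprint's last 3 bases; on the − strand
    its first 3 (reference-left) bases.
    """

    chrom: str
    start: int
    strand: str
    mismatches: int
    pam_observed: str
    is_on_target: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.mismatches < 0:
            raise ValueError("mismatch count must be >= 0")

    @property
    def end(self) -> int:
        return self.start + SITE_LEN

    @property
    def protospacer_start(self) -> int:
        """Reference coordinate of the protospacer 5' base on the site's strand."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class TargetReadRecord:
    """A simplified aligned read over the target window.

    ``span`` is the aligned reference interval; ``deletions`` lists
    reference intervals deleted from the read.  All 0-based half-open.
    """

    read_id: str
    span: tuple[int, int]
    deletions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.span
        for ds, de in self.deletions:
            if not (lo <= ds < de <= hi):
                raise ValueError(f"deletion {ds}-{de} outside aligned span {lo}-{hi}")


def _pam_matches(window: np.ndarray, pam_rules: Sequence[str]) -> np.ndarray:
    """Boolean mask over positions whose 3-mer matches any PAM pattern."""
    ok = np.zeros(window.shape[1], dtype=bool)
    for pam in pam_rules:
        m = np.ones(window.shape[1], dtype=bool)
        for j, ch in enumerate(pam):
            if ch == "N":
                m &= window[j] < 4
            else:
                m &= window[j] == _ENC[ch]
        ok |= m
    return ok


def _scan_strand(
    arr: np.ndarray, ps_arr: np.ndarray, max_mismatches: int, pam_rules: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (start indices, mismatch counts, n ambiguous windows skipped)
    for plus-strand scanning of an encoded sequence."""
    L = len(arr)
    n_windows = L - SITE_LEN + 1
    if n_windows <= 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int), 0
    mism = np.zeros(n_windows, dtype=np.int16)
    valid = np.ones(n_windows, dtype=bool)
    for j in range(PROTOSPACER_LEN):
        col = arr[j : j + n_windows]
        mism += (col != ps_arr[j]).astype(np.int16)
        valid &= col < 4
    pam_window = np.stack([arr[PROTOSPACER_LEN + j : PROTOSPACER_LEN + j + n_windows] for j in range(3)])
    pam_ok = _pam_matches(pam_window, pam_rules)
    valid_pam = np.all(pam_window < 4, axis=0)
    n_skipped = int(np.count_nonzero(~(valid & valid_pam)))
    hits = np.flatnonzero(valid & valid_pam & pam_ok & (mism <= max_mismatches))
    return hits, mism[hits], n_skipped


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), 255, dtype=np.uint8)
    for base, code in _ENC.items():
        out[arr == ord(base)] = code
    return out


def scan_offtargets(
    reference: Mapping[str, str],
    ps: Protospacer,
    max_mismatches: int = 5,
    pam_rules: Sequence[str] | None = None,
) -> list[OffTargetSite]:
    """Enumerate all candidate off-target sites in a reference genome.

    Every 20-mer on either strand whose 3'-adjacent 3-mer matches an
    allowed PAM and whose Hamming distance to the protospacer is at most
    ``max_mismatches`` is reported exactly once.  Windows containing
    ambiguous bases are skipped.  Sites at distance 0 are flagged
    on-target.
    """
    if not reference:
        raise ValueError("empty reference")
    if not 0 <= max_mismatches <= PROTOSPACER_LEN:
        raise ValueError(f"max_mismatches must be in [0, 20], got {max_mismatches}")
    pam_rules = tuple(pam_rules) if pam_rules is not None else ps.pam_rules
    ps_arr = _encode(ps.seq)
    sites: list[OffTargetSite] = []
    for chrom in sorted(reference):
        seq = reference[chrom].upper()
        L = len(seq)
        arr = _encode(seq)
        # plus strand: footprint [i, i+23), PAM at [i+20, i+23)
        hits, mm, _ = _scan_strand(arr, ps_arr, max_mismatches, pam_rules)
        for i, k in zip(hits.tolist(), mm.tolist()):
            sites.append(
                OffTargetSite(
                    chrom=chrom,
                    start=i,
                    strand="+",
                    mismatches=int(k),
                    pam_observed=seq[i + PROTOSPACER_LEN : i + SITE_LEN],
                    is_on_target=k == 0,
                )
            )
        # minus strand: scan the reverse complement, then mirror coordinates
        rc = revcomp(seq)
        arr_rc = _encode(rc)
        hits, mm, _ = _scan_strand(arr_rc, ps_arr, max_mismatches, pam_rules)
        for i, k in zip(hits.tolist(), mm.tolist()):
            start = L - (i + SITE_LEN)
            sites.append(
                OffTargetSite(
                    chrom=chrom,
                    start=start,
                    strand="-",
                    mismatches=int(k),
                    pam_observed=rc[i + PROTOSPACER_LEN : i + SITE_LEN],
                    is_on_target=k == 0,
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def cut_site_of(site: OffTargetSite) -> int:
    """Blunt-cut boundary (0-based, between two bases) for a site.

    Cas9 cuts 3 bp 5' of the PAM: for a + strand footprint [s, s+23) the
    boundary is s+17; for a − strand footprint (PAM reference-left) it is
    s+6.
    """
    if site.strand == "+":
        return site.start + PROTOSPACER_LEN - CUT_OFFSET_FROM_PAM
    return site.start + CUT_OFFSET_FROM_PAM + 3


def annotate_dnm_proximity(
    dnm_positions: Iterable[tuple[str, int]],
    sites: Sequence[OffTargetSite],
    window_bp: int = 40,
) -> list[bool]:
    """Flag DNMs lying within ``window_bp`` of any site footprint.

    A DNM at (chrom, 0-based pos) is flagged iff its position falls in
    [site.start − window, site.end + window).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append((s.start - window_bp, s.end + window_bp))
    for iv in by_chrom.values():
        iv.sort()
    flags = []
    for chrom, pos in dnm_positions:
        flags.append(any(lo <= pos < hi for lo, hi in by_chrom.get(chrom, ())))
    return flags


def on_target_ratio(
    reads: Sequence[TargetReadRecord], cut_site: int, near_window_bp: int = 5
) -> float:
    """Fraction of cut-site-spanning reads carrying a deletion at the cut.

    The near-window is [cut_site − w, cut_site + w); a read counts toward
    the numerator when any of its deletion spans intersects that window,
    and toward the denominator when its aligned span overlaps it.
    """
    lo, hi = cut_site - near_window_bp, cut_site + near_window_bp
    overlapping = [r for r in reads if r.span[0] < hi and r.span[1] > lo]
    if not overlapping:
        raise ValueError("no reads overlap the cut-site window")
    with_del = sum(
        1 for r in overlapping if any(ds < hi and de > lo for ds, de in r.deletions)
    )
    return with_del / len(overlapping)


def expected_background_sites(
    genome_length: int, max_mismatches: int, pam_rules: Sequence[str] = ("NGG", "NAG")
) -> float:
    """Analytic expectation of chance off-target sites on uniform-random
    sequence: 2 strands x L x P(PAM) x sum_i C(20,i) (3/4)^i (1/4)^(20-i)."""
    from math import comb

    p_match = sum(
        comb(PROTOSPACER_LEN, i) * (3 / 4) ** i * (1 / 4) ** (PROTOSPACER_LEN - i)
        for i in range(max_mismatches + 1)
    )
    # P(a random 3-mer matches any allowed pattern); patterns may overlap
    p_pam = _pam_set_probability(pam_rules)
    return 2 * genome_length * p_match * p_pam


def _pam_set_probability(pam_rules: Sequence[str]) -> float:
    from itertools import product

    matched = set()
    for trimer in product("ACGT", repeat=3):
        for pam in pam_rules:
            if all(p == "N" or p == b for p, b in zip(pam, trimer)):
                matched.add(trimer)
                break
    return len(matched) / 64
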