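"""Binomial power model for detecting mosaic de novo mutations.

A DNM arising at the single-cell stage of the zygote is expected in half
the cells (mutant-allele fraction p = 0.5, assuming a heterozygous
mutation and unbiased read sampling); one arising at the two-cell stage in
a quarter (p = 0.25).  At sequencing depth n, calling requires at least
m = ceil(min_af x n) mutant reads (minimum de novo allele frequency
min_af, default 10%).  The number of mutant reads is X ~ Binomial(n, p),
so the probability of missing the mutation is P(X <= m - 1) and the
detection power its complement.  The model also converts a per-nucleotide
per-generation mutation-rate band into an expected DNM count band.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

from scipy import stats

__all__ = [
    "PowerModel",
    "MutationRateRange",
    "min_supporting_reads",
    "miss_probability",
    "detection_power",
    "stage_allele_fraction",
    "expected_dnm_count",
    "dnm_efficiency_correlation",
]

#: Mutant-allele fraction by zygotic stage of mutation origin.
STAGE_FRACTIONS = {"single-cell": 0.5, "two-cell": 0.25}


def min_supporting_reads(n: int, min_af: float) -> int:
    """Minimum mutant reads to call a DNM: ceil(min_af x n)."""
    if n <= 0:
        raise ValueError(f"depth must be positive, got {n}")
    if not 0 <= min_af <= 1:
        raise ValueError(f"min_af must be in [0, 1], got {min_af}")
    return ceil(min_af * n)


@dataclass(frozen=True)
class PowerModel:
    """Binomial detection model at depth ``n`` and allele fraction ``p``.

    ``m`` is derived as ceil(min_af x n) unless given explicitly.
    """

    n: int
    p: float
    min_af: float = 0.10
    m: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p <= 0.5:
            raise ValueError(f"allele fraction must be in (0, 0.5], got {self.p}")
        if self.m is None:
            object.__setattr__(self, "m", min_supporting_reads(self.n, self.min_af))
        elif self.m < 0:
            raise ValueError("m must be >= 0")

    @classmethod
    def for_stage(cls, stage: str, n: int, min_af: float = 0.10) -> "PowerModel":
        if stage not in STAGE_FRACTIONS:
            raise ValueError(f"stage must be one of {sorted(STAGE_FRACTIONS)}, got {stage!r}")
        return cls(n=n, p=STAGE_FRACTIONS[stage], min_af=min_af)


def stage_allele_fraction(stage: str) -> float:
    """Expected mutant-allele fraction for a zygotic stage."""
    try:
        return STAGE_FRACTIONS[stage]
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}; known: {sorted(STAGE_FRACTIONS)}") from None


def miss_probability(model: PowerModel) -> float:
    """P(mutation not called) = P(X <= m - 1), X ~ Binomial(n, p), exact."""
    if model.m == 0:
        return 0.0
    return float(stats.binom.cdf(model.m - 1, model.n, model.p))


def detection_power(model: PowerModel) -> float:
    """1 − miss_probability."""
    return 1.0 - miss_probability(model)


@dataclass(frozen=True)
class MutationRateRange:
    """Per-nucleotide per-generation mutation-rate band and callable sites.

    ``callable_sites`` is the diploid nucleotide count over which DNMs can
    be called; default 2 x 2.9e9 (two copies of a ~2.9 Gb genome).
    """

    mu_low: float
    mu_high: float
    callable_sites: float = 2 * 2.9e9

    def __post_init__(self) -> None:
        if not 0 < self.mu_low <= self.mu_high:
            raise ValueError("need 0 < mu_low <= mu_high")


def expected_dnm_count(r: MutationRateRange) -> tuple[float, float]:
    """Expected DNMs per generation: (mu_low, mu_high) x callable_sites."""
    if r.callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    return (r.mu_low * r.callable_sites, r.mu_high * r.callable_sites)


def dnm_efficiency_correlation(
    pairs: list[tuple[float, float]]
) -> tuple[float, float]:
    """Pearson correlation between editing efficiency and DNM count.

    ``pairs`` are (on-target ratio, DNM count) per animal.  Returns
    (r, two-sided p-value).  Requires at least 3 pairs with nonzero
    variance in both coordinates.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = [a for a, _ in pairs]
    y = [b for _, b in pairs]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("degenerate variance in one coordinate")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
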