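"""Off-target enumeration vs brute-force oracle; cut-site and on-target logic."""

import numpy as np
import pytest

from trioaudit.offtarget_scan import (
    OffTargetSite,
    Protospacer,
    TargetReadRecord,
    annotate_dnm_proximity,
    cut_site_of,
    expected_background_sites,
    on_target_ratio,
    revcomp,
    scan_offtargets,
)

GUIDE = "CCTATGTTGAAGTGTGGTCA"  # 20-nt protospacer


def brute_force_scan(reference, ps, max_mm, pam_rules=("NGG", "NAG")):
    """All-positions Hamming scan, string arithmetic only."""

    def pam_ok(trimer):
        return any(
            all(p == "N" or p == b for p, b in zip(pam, trimer)) for pam in pam_rules
        )

    hits = set()
    for chrom, seq in reference.items():
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for i in range(L - 23 + 1):
                window = s[i : i + 23]
                if set(window) - set("ACGT"):
                    continue
                if not pam_ok(window[20:23]):
                    continue
                mm = sum(a != b for a, b in zip(window[:20], ps.seq))
                if mm <= max_mm:
                    start = i if strand == "+" else L - (i + 23)
                    hits.add((chrom, start, strand, mm))
    return hits


class TestScan:
    def test_exact_site_plus_strand(self):
        ref = {"chr1": "TTTT" + GUIDE + "CGG" + "TTTT"}
        (site,) = scan_offtargets(ref, Protospacer(GUIDE), max_mismatches=0)
        assert (site.start, site.strand, site.mismatches) == (4, "+", 0)
        assert site.is_on_target and site.pam_observed == "CGG"

    def test_reverse_strand_site(self):
        ref = {"chr1": "AAAA" + revcomp(GUIDE + "TGG") + "AAAA"}
        (site,) = scan_offtargets(ref, Protospacer(GUIDE), max_mismatches=0)
        assert (site.start, site.strand) == (4, "-")

    def test_guide_with_pam_is_parsed(self):
        ps = Protospacer("CCTATGTTGAAGTGTGGTCATCC")  # 23-mer guide + PAM
        assert ps.seq == GUIDE

    def test_matches_brute_force_on_random_genome(self, rng):
        ref = {
            "chr1": "".join(rng.choice(list("ACGT"), size=10_000)),
            "chr2": "".join(rng.choice(list("ACGT"), size=5_000)),
        }
        ps = Protospacer(GUIDE)
        for k in (3, 7):
            got = {
                (s.chrom, s.start, s.strand, s.mismatches)
                for s in scan_offtargets(ref, ps, max_mismatches=k)
            }
            assert got == brute_force_scan(ref, ps, k)

    def test_ambiguous_windows_skipped(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=200))
        ref = {"chr1": core[:100] + "N" + core[100:]}
        for s in scan_offtargets(ref, Protospacer(GUIDE), max_mismatches=7):
            assert "N" not in ref["chr1"][s.start : s.end]

    def test_monotone_in_mismatches_and_pam_set(self, rng):
        ref = {"chr1": "".join(rng.choice(list("ACGT"), size=20_000))}
        ps = Protospacer(GUIDE)
        prev = -1
        for k in range(0, 8):
            n = len(scan_offtargets(ref, ps, max_mismatches=k))
            assert n >= prev
            prev = n
        ngg_only = len(scan_offtargets(ref, ps, max_mismatches=6, pam_rules=("NGG",)))
        both = len(scan_offtargets(ref, ps, max_mismatches=6, pam_rules=("NGG", "NAG")))
        assert both >= ngg_only

    def test_strand_symmetry(self, rng):
        ref = {"chr1": "".join(rng.choice(list("ACGT"), size=8_000))}
        ps = Protospacer(GUIDE)
        fwd = scan_offtargets(ref, ps, max_mismatches=5)
        rc = {"chr1": revcomp(ref["chr1"])}
        L = len(ref["chr1"])
        mirrored = {
            ("chr1", L - s.end, {"+": "-", "-": "+"}[s.strand], s.mismatches)
            for s in scan_offtargets(rc, ps, max_mismatches=5)
        }
        assert {( "chr1", s.start, s.strand, s.mismatches) for s in fwd} == mirrored

    def test_background_site_count_near_analytic_expectation(self, rng):
        """On random sequence, chance-hit counts follow the per-window
        match probability; check a Monte-Carlo total against +/-4 sigma."""
        ps = Protospacer(GUIDE)
        L, reps = 50_000, 4
        counts = []
        for i in range(reps):
            r = np.random.default_rng(1000 + i)
            ref = {"chr1": "".join(r.choice(list("ACGT"), size=L))}
            counts.append(len(scan_offtargets(ref, ps, max_mismatches=7)))
        expected = expected_background_sites(L, 7)
        total, mu = sum(counts), reps * expected
        assert abs(total - mu) < 4 * np.sqrt(mu)


class TestCutSite:
    def test_plus_strand_cut_three_bp_from_pam(self):
        site = OffTargetSite(chrom="chr1", start=100, strand="+", mismatches=0, pam_observed="AGG")
        assert cut_site_of(site) == 117

    def test_minus_strand_mirrors(self):
        # same physical site on the other strand: PAM occupies the
        # reference-left 3 bases, so the cut sits 6 bp into the footprint
        site = OffTargetSite(chrom="chr1", start=100, strand="-", mismatches=0, pam_observed="AGG")
        assert cut_site_of(site) == 106
        plus = OffTargetSite(chrom="chr1", start=100, strand="+", mismatches=0, pam_observed="AGG")
        assert (cut_site_of(plus) - plus.start) + (cut_site_of(site) - site.start) == 23

    def test_simulator_round_trip(self, sim_result):
        on = sim_result.truth.on_target
        assert sim_result.truth.cut_site == cut_site_of(on)
        found = [
            s
            for s in scan_offtargets(
                sim_result.reference, Protospacer(sim_result.config.sgRNA), 0
            )
            if s.is_on_target
        ]
        assert any(s.start == on.start and s.chrom == on.chrom for s in found)


class TestProximity:
    SITE = OffTargetSite(chrom="chr1", start=1000, strand="+", mismatches=2, pam_observed="TGG")

    def test_inside_footprint_flagged(self):
        assert annotate_dnm_proximity([("chr1", 1010)], [self.SITE]) == [True]

    def test_window_boundary(self):
        # footprint [1000, 1023); 40 bp window extends to 1063 exclusive
        assert annotate_dnm_proximity([("chr1", 1062)], [self.SITE]) == [True]
        assert annotate_dnm_proximity([("chr1", 1063)], [self.SITE]) == [False]
        assert annotate_dnm_proximity([("chr1", 960)], [self.SITE]) == [True]
        assert annotate_dnm_proximity([("chr1", 959)], [self.SITE]) == [False]

    def test_no_sites_no_flags(self):
        assert annotate_dnm_proximity([("chr1", 5)], []) == [False]


class TestOnTargetRatio:
    def _reads(self, n, n_del, cut=500):
        reads = []
        for i in range(n):
            dels = ((cut - 3, cut + 2),) if i < n_del else ()
            reads.append(TargetReadRecord(f"r{i}", (cut - 60, cut + 60), dels))
        return reads

    def test_fraction_of_deletion_reads(self):
        assert on_target_ratio(self._reads(1000, 435), 500) == pytest.approx(0.435)
        assert on_target_ratio(self._reads(10, 0), 500) == 0.0
        assert on_target_ratio(self._reads(10, 10), 500) == 1.0

    def test_no_overlapping_reads_errors(self):
        with pytest.raises(ValueError):
            on_target_ratio(self._reads(5, 0, cut=500), 10_000)
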