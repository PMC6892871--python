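"""Simulator determinism, inheritance structure, and truth bookkeeping."""

import numpy as np
import pytest

from trioaudit.offtarget_scan import Protospacer, scan_offtargets
from trioaudit.synthetic_trio import SimulationConfig, TrioSimulator


class TestReference:
    def test_deterministic_per_seed(self, small_config):
        a, _ = TrioSimulator(small_config).simulate_reference()
        b, _ = TrioSimulator(small_config).simulate_reference()
        assert a == b

    def test_on_target_site_at_recorded_coordinate(self, sim_result):
        on = sim_result.truth.on_target
        seq = sim_result.reference[on.chrom][on.start : on.end]
        assert seq == sim_result.config.sgRNA + "TGG"

    def test_gc_fraction_near_half(self):
        cfg = SimulationConfig(seed=2, genome_length=100_000, n_chroms=1)
        ref, _ = TrioSimulator(cfg).simulate_reference()
        seq = ref["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        sigma = 0.5 / np.sqrt(len(seq))
        assert abs(gc - 0.5) < 3 * sigma

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(genome_length=500)


class TestPlantedOfftargets:
    def test_rescan_recovers_all_planted_sites(self, sim_result):
        cfg = sim_result.config
        sites = scan_offtargets(
            sim_result.reference,
            Protospacer(cfg.sgRNA),
            max_mismatches=max(cfg.planted_offtarget_mismatches),
        )
        found = {(s.chrom, s.start, s.strand, s.mismatches) for s in sites}
        for p in sim_result.truth.planted_offtargets:
            assert (p.chrom, p.start, p.strand, p.mismatches) in found

    def test_both_strands_represented(self):
        cfg = SimulationConfig(seed=4, genome_length=400_000,
                               planted_offtarget_mismatches=tuple(range(8)))
        sim = TrioSimulator(cfg)
        ref, _ = sim.simulate_reference()
        _, planted = sim.plant_offtargets(ref)
        assert {p.strand for p in planted} == {"+", "-"}
        assert sorted(p.mismatches for p in planted) == list(range(8))


class TestTrioTruth:
    def test_inheritance_consistent_outside_dnms_and_artifacts(self, sim_result):
        for v in sim_result.truth.variants:
            if v.cls != "parental_het":
                continue
            f, m = v.gts["F"], v.gts["M"]
            for off in sim_result.config.offspring:
                a, b = v.gts[off]
                assert (a in f and b in m) or (b in f and a in m)

    def test_dnm_positions_free_of_parental_variants(self, sim_result):
        parental = {
            (v.chrom, v.start) for v in sim_result.truth.variants if v.cls == "parental_het"
        }
        for keys in sim_result.truth.true_dnm_keys.values():
            assert all((c, s) not in parental for c, s, _, _ in keys)

    def test_parental_allele_artifact_genotypes(self, sim_result):
        for v in sim_result.truth.variants:
            if v.cls != "artifact_parental":
                continue
            assert {v.gts["F"], v.gts["M"]} == {(0, 0), (1, 1)}
            assert v.gts[v.owner] in {(0, 0), (1, 1)}  # hom for a parental allele

    def test_zero_dnms_config(self):
        cfg = SimulationConfig(seed=1, genome_length=50_000, dnm_count=0,
                               artifact_count=5, shared_artifact_count=1, db_artifact_count=1)
        sim = TrioSimulator(cfg)
        ref, _ = sim.simulate_reference()
        truth = sim.simulate_trio(ref, TrioSimulator(cfg).simulate_masks(ref)[0])
        assert all(not keys for keys in truth.true_dnm_keys.values())


class TestMasks:
    def test_fraction_within_relative_tolerance(self, sim_result):
        from trioaudit.consensus_filtering import build_universal_mask

        cfg = sim_result.config
        total = sum(len(s) for s in sim_result.reference.values())
        random_components = [
            c for c in sim_result.mask_components if c.label != "low-complexity"
        ]
        frac = build_universal_mask(random_components).total_length() / total
        assert abs(frac - cfg.mask_fraction) <= 0.1 * cfg.mask_fraction

    def test_zero_fraction_leaves_only_homopolymers(self):
        cfg = SimulationConfig(seed=3, genome_length=60_000, mask_fraction=0.0)
        sim = TrioSimulator(cfg)
        ref, _ = sim.simulate_reference()
        comps = sim.simulate_masks(ref)
        for c in comps:
            if c.label != "low-complexity":
                assert len(c) == 0
        lc = next(c for c in comps if c.label == "low-complexity")
        for chrom, s, e in lc:
            run = ref[chrom][s:e]
            assert e - s >= 10 and len(set(run)) == 1

    def test_deterministic(self, small_config):
        sim1, sim2 = TrioSimulator(small_config), TrioSimulator(small_config)
        r1, _ = sim1.simulate_reference()
        r2, _ = sim2.simulate_reference()
        m1 = [c.intervals for c in sim1.simulate_masks(r1)]
        m2 = [c.intervals for c in sim2.simulate_masks(r2)]
        assert m1 == m2


class TestCallerViews:
    def test_no_noise_views_agree_on_sites(self, sim_result):
        keysets = [
            {r.key() for r in records} for records in sim_result.caller_views.values()
        ]
        assert all(k == keysets[0] for k in keysets)

    def test_ad_shared_across_callers(self, sim_result):
        views = list(sim_result.caller_views.values())
        by_key = [{r.key(): r for r in v} for v in views]
        for key, rec in by_key[0].items():
            for other in by_key[1:]:
                assert [c.ad for c in other[key].calls] == [c.ad for c in rec.calls]

    def test_mosaic_alt_read_mean_matches_binomial(self):
        """Unconditioned quarter-fraction DNMs at depth 40 average ~10 alt
        reads — the binomial expectation."""
        cfg = SimulationConfig(seed=21, genome_length=500_000, dnm_count=150,
                               n_offspring=1, mosaic_fraction_options=(0.25,),
                               condition_detectable=False, artifact_count=0,
                               shared_artifact_count=0, db_artifact_count=0)
        res = TrioSimulator(cfg).run()
        alts = [
            r.call(v.owner).ad[1]
            for v in res.truth.variants
            if v.cls == "dnm"
            for r in [next(x for x in res.caller_views["caller1"] if x.key() == v.key)]
        ]
        mean = np.mean(alts)
        se = np.sqrt(40 * 0.25 * 0.75 / len(alts))
        assert abs(mean - 10.0) < 4 * se

    def test_fp_sites_absent_from_truth(self):
        cfg = SimulationConfig(seed=8, genome_length=100_000, caller_fp_rate=0.05,
                               dnm_count=3, artifact_count=5, shared_artifact_count=1,
                               db_artifact_count=0)
        res = TrioSimulator(cfg).run()
        truth_keys = {v.key for v in res.truth.variants}
        fp_keys = set()
        for records in res.caller_views.values():
            fp_keys |= {r.key() for r in records} - truth_keys
        assert fp_keys  # some were injected
        assert not (fp_keys & truth_keys)

    def test_full_run_deterministic(self, small_config, sim_result):
        res2 = TrioSimulator(small_config).run()
        assert res2.reference == sim_result.reference
        assert res2.caller_views == sim_result.caller_views
        assert res2.truth.variants == sim_result.truth.variants


class TestTargetReads:
    def test_exact_deletion_count(self, sim_result):
        from trioaudit.offtarget_scan import on_target_ratio

        cfg = sim_result.config
        measured = on_target_ratio(sim_result.target_reads, sim_result.truth.cut_site)
        expected = round(cfg.on_target_ratio * cfg.n_target_reads) / cfg.n_target_reads
        assert measured == pytest.approx(expected)

    def test_zero_ratio_no_deletions(self, small_config):
        sim = TrioSimulator(small_config)
        reads = sim.simulate_target_reads(cut_site=5000, on_target_ratio=0.0, n_reads=50)
        assert all(not r.deletions for r in reads)

    def test_invalid_read_count(self, small_config):
        with pytest.raises(ValueError):
            TrioSimulator(small_config).simulate_target_reads(5000, n_reads=0)


class TestWrite:
    def test_outputs_round_trip(self, sim_result, tmp_path):
        from trioaudit.io_formats import read_bed, read_fasta, read_vcf

        out = tmp_path / "sim"
        sim_result.write(str(out))
        ref = read_fasta(out / "reference.fa")
        assert ref == sim_result.reference
        mask = read_bed(out / "mask.bed")
        assert mask.intervals == sim_result.mask.intervals
        records = read_vcf(out / "caller1.vcf")
        assert len(records) == len(sim_result.caller_views["caller1"])
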