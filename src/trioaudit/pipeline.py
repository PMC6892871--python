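"""End-to-end orchestration: simulate -> filter -> DNM cascade -> off-target
-> SV -> power, with truth scoring and a machine-readable report.

``run_selftest`` is the audit-in-a-box: it builds a synthetic family with
known truth, pushes the per-caller call sets through the same stages a real
trio study would use, and checks that every planted DNM is recovered and
every injected artifact removed by the stage responsible for its class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

from trioaudit.consensus_filtering import FilterThresholds, filter_caller_set
from trioaudit.dnm_pipeline import (
    DnmCandidate,
    allele_filter,
    cross_filter,
    dbsnp_filter,
    detect_candidates,
    overlap_candidates,
    score_against_truth,
)
from trioaudit.offtarget_scan import (
    Protospacer,
    annotate_dnm_proximity,
    on_target_ratio,
    scan_offtargets,
)
from trioaudit.power_stats import PowerModel, detection_power, min_supporting_reads, miss_probability
from trioaudit.sv_consensus import (
    SvFilterConfig,
    de_novo_sv_filter,
    filter_sv_shortread,
    intersect_sv_callers,
)
from trioaudit.synthetic_trio import SimulationConfig, SimulationResult, TrioSimulator

__all__ = ["SelftestReport", "run_dnm_cascade", "run_selftest", "run_report"]


@dataclass
class SelftestReport:
    """Everything a selftest run measured, ready for tabulation."""

    config: SimulationConfig
    funnels: dict[str, dict[str, int]]
    final_dnms: dict[str, list[DnmCandidate]]
    scores: dict[str, dict[str, float]]
    offtarget: dict[str, Any]
    sv: dict[str, Any]
    power: dict[str, float]
    on_target: dict[str, float]
    invariant_failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.invariant_failures


def run_dnm_cascade(
    per_caller_filtered: Mapping[str, Sequence],
    father: str,
    mother: str,
    offspring: str,
    known_db,
) -> tuple[list[DnmCandidate], dict[str, int]]:
    """Detect candidates per caller, overlap, then allele + known-variant
    filtering for one offspring.  Cross filtering happens across offspring
    and is applied by the caller of this function."""
    per_caller = [
        detect_candidates(records, father, mother, offspring, caller=name)
        for name, records in per_caller_filtered.items()
    ]
    primary_raw = len(per_caller[0]) if per_caller else 0
    nostrict = overlap_candidates(per_caller)
    af = allele_filter(nostrict)
    dbf = dbsnp_filter(af, known_db)
    funnel = {
        "Raw": primary_raw,
        "noStrict": len(nostrict),
        "AF": len(af),
        "dbSNPF": len(dbf),
    }
    return dbf, funnel


def run_selftest(
    config: SimulationConfig | None = None,
    thresholds: FilterThresholds | None = None,
    sim: SimulationResult | None = None,
) -> SelftestReport:
    """Simulate a family and audit it end to end against the truth."""
    config = config or SimulationConfig()
    thresholds = thresholds or FilterThresholds()
    if sim is None:
        sim = TrioSimulator(config).run()
    truth = sim.truth
    failures: list[str] = []

    # per-offspring: SF/GF/UM per caller, candidate detection, cascade
    per_off_dbf: dict[str, list[DnmCandidate]] = {}
    funnels: dict[str, dict[str, int]] = {}
    for off in config.offspring:
        filtered: dict[str, list] = {}
        caller_counts: dict[str, int] = {}
        primary = next(iter(sim.caller_views))
        for caller, records in sim.caller_views.items():
            um, counts = filter_caller_set(
                records, sim.mask, thresholds, trio_samples=("F", "M", off)
            )
            filtered[caller] = um
            if caller == primary:
                caller_counts = counts
        dbf, funnel = run_dnm_cascade(filtered, "F", "M", off, truth.known_db)
        per_off_dbf[off] = dbf
        funnels[off] = {**caller_counts, **funnel}

    final = cross_filter(per_off_dbf) if len(per_off_dbf) > 1 else {
        off: cands for off, cands in per_off_dbf.items()
    }
    for off, funnel in funnels.items():
        funnel["CF"] = len(final[off])
        stages = [funnel[s] for s in ("Raw", "noStrict", "AF", "dbSNPF", "CF")]
        if any(a < b for a, b in zip(stages, stages[1:])):
            failures.append(f"funnel not monotone for {off}: {stages}")

    scores = score_against_truth(final, truth.true_dnm_keys, truth.artifact_classes)
    for off, score in scores.items():
        if score["precision"] != 1.0 or score["recall"] != 1.0:
            failures.append(
                f"{off}: precision={score['precision']:.3f} recall={score['recall']:.3f}"
            )

    # off-target scan: recover every planted site, flag DNMs near sites
    ps = Protospacer(config.sgRNA)
    max_mm = max(config.planted_offtarget_mismatches, default=0)
    sites = scan_offtargets(sim.reference, ps, max_mismatches=max_mm)
    found = {(s.chrom, s.start, s.strand) for s in sites}
    planted = list(truth.planted_offtargets)
    if truth.on_target is not None:
        planted.append(truth.on_target)
    missed = [
        s for s in planted if (s.chrom, s.start, s.strand) not in found
    ]
    if missed:
        failures.append(f"off-target scan missed {len(missed)} planted sites")
    dnm_positions = [
        (c.chrom, c.start) for cands in final.values() for c in cands
    ]
    near_flags = annotate_dnm_proximity(dnm_positions, sites, window_bp=40)
    offtarget_summary = {
        "n_sites": len(sites),
        "n_planted": len(planted),
        "n_planted_recovered": len(planted) - len(missed),
        "n_final_dnms_near_sites": sum(near_flags),
    }

    # SV consensus and de novo filtering
    svcfg = SvFilterConfig()
    consensus_sv = {}
    for sample, by_caller in sim.sv_sets.items():
        a = [sv for sv in by_caller["svcallerA"] if filter_sv_shortread(sv, svcfg).passed]
        b = [sv for sv in by_caller["svcallerB"] if filter_sv_shortread(sv, svcfg).passed]
        consensus_sv[sample] = intersect_sv_callers(a, b, svcfg.reciprocal_threshold, svcfg)
    denovo_by_off = {}
    for off in config.offspring:
        sibs = [consensus_sv[o] for o in config.offspring if o != off]
        denovo_by_off[off] = de_novo_sv_filter(
            consensus_sv[off],
            [consensus_sv["F"], consensus_sv["M"]],
            sim.sv_known,
            sibs,
            svcfg.reciprocal_threshold,
            svcfg,
        )
    n_true_denovo = len(truth.sv_truth.get("denovo", []))
    n_called_denovo = sum(len(v) for v in denovo_by_off.values())
    true_keys = {
        (sv.chrom, sv.start, sv.end, sv.svtype, sv.sample)
        for sv in truth.sv_truth.get("denovo", [])
    }
    called_keys = {
        (sv.chrom, sv.start, sv.end, sv.svtype, sv.sample)
        for v in denovo_by_off.values()
        for sv in v
    }
    if called_keys != true_keys:
        failures.append(
            f"SV de novo set mismatch: called {n_called_denovo}, planted {n_true_denovo}"
        )
    sv_summary = {
        "n_denovo_called": n_called_denovo,
        "n_denovo_planted": n_true_denovo,
        "exact_match": called_keys == true_keys,
    }

    # on-target ratio round-trip
    assert truth.cut_site is not None
    measured = on_target_ratio(sim.target_reads, truth.cut_site, near_window_bp=5)
    on_target_summary = {
        "configured": config.on_target_ratio,
        "measured": measured,
    }
    expected = round(config.on_target_ratio * config.n_target_reads) / config.n_target_reads
    if abs(measured - expected) > 1e-12:
        failures.append(f"on-target ratio {measured} != constructed {expected}")

    # power table at the study depth
    m = min_supporting_reads(config.depth_mean, config.min_af)
    power = {}
    for stage, p in (("single-cell", 0.5), ("two-cell", 0.25)):
        model = PowerModel(n=config.depth_mean, p=p, min_af=config.min_af)
        power[f"miss_{stage}"] = miss_probability(model)
        power[f"power_{stage}"] = detection_power(model)
    power["min_supporting_reads"] = float(m)

    return SelftestReport(
        config=config,
        funnels=funnels,
        final_dnms=final,
        scores=scores,
        offtarget=offtarget_summary,
        sv=sv_summary,
        power=power,
        on_target=on_target_summary,
        invariant_failures=failures,
    )


def run_report(report: SelftestReport) -> "pd.DataFrame":
    """One row per offspring: depth, on-target ratio, funnel and final counts."""
    import pandas as pd

    rows = []
    for off in report.config.offspring:
        cands = report.final_dnms.get(off, [])
        n_snv = sum(c.is_snv for c in cands)
        row = {
            "offspring": off,
            "depth": report.config.depth_mean,
            "on_target_ratio": report.on_target["measured"],
            "candidate_dnms": report.funnels[off].get("Raw", 0),
            "final_snvs": n_snv,
            "final_indels": len(cands) - n_snv,
            "final_total": len(cands),
            "precision": report.scores[off]["precision"],
            "recall": report.scores[off]["recall"],
        }
        for stage in ("noStrict", "AF", "dbSNPF", "CF"):
            row[stage] = report.funnels[off].get(stage, 0)
        rows.append(row)
    return pd.DataFrame(rows)
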