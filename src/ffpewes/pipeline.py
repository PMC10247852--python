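"""End-to-end orchestration of the four evaluation steps.

Step 1 - feasibility: pre-library QC advisories, predicted success,
pooling by amplification potential, QC-metric/success correlations.
Step 2 - performance: per-sample coverage metrics, the 90%-at-20X success
rule, joint low-coverage regions across the FFPE cohort, gene coverage.
Step 3 - concordance: truth-catalogue benchmarking, matched FFPE/blood
comparison with a stratification ladder, and the internal database of
problematic regions clustered from discordant calls.
Step 4 - clinical value: ensemble call sets are annotated, triaged through
the tiered panel strategy, and summarized as diagnostic yield.

The run is a pure function of its configuration: identical config (and
seed) produces byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .blacklist import ClusterConfig, build_blacklist
from .concordance import (
    build_ladder,
    compare_callsets,
    coverage_intersect,
    discordant_keys,
    matched_pair_summary,
    round_half_up,
    stratified_concordance,
    venn_partition,
)
from .core import CallSet
from .coverage import (
    QCThresholds,
    gene_coverage_curve,
    is_successful,
    joint_low_coverage,
    pool_cohort,
    qc_correlation,
    sample_metrics,
)
from .ensemble import EnsembleConfig, consensus_calls
from .io import write_bed
from .simulate import SimulationConfig, annotate_callset, simulate_cohort
from .triage import ReferralRequest, cohort_yield, run_referral

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    outdir: Optional[str] = None

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _ensemble_sets(cohort, cfg: PipelineConfig) -> dict:
    out = {}
    for (sid, material), callers in cohort.caller_sets.items():
        ordered = [callers[c] for c in cfg.ensemble.caller_labels if c in callers]
        out[(sid, material)] = consensus_calls(ordered, cfg.ensemble)
    return out


def run_all(cfg: PipelineConfig, cohort=None) -> dict:
    """Run every evaluation step on a (simulated) cohort; return the summary.

    When ``cfg.outdir`` is set, per-step TSV/BED reports and a summary JSON
    are written there. A pre-built cohort may be passed to avoid
    re-simulating; it must come from ``simulate_cohort(cfg.sim)``.
    """
    if cohort is None:
        cohort = simulate_cohort(cfg.sim)
    summary: dict = {
        "version": __version__,
        "seed": cfg.sim.seed,
        "config_hash": cfg.config_hash(),
    }

    # ---- step 1+2: feasibility and sequencing performance -----------------
    metrics, success, qc_rows = {}, {}, []
    for q in cohort.qc:
        track = cohort.coverage[(q.sample_id, "ffpe")]
        m = sample_metrics(track)
        metrics[q.sample_id] = m
        success[q.sample_id] = is_successful(m, cfg.qc)
        q.pct_ge_20x = m.pct_ge[20]
        qc_rows.append(
            {
                "sample_id": q.sample_id,
                "qpcr": q.qpcr_value,
                "din": q.din,
                "fragment_length": q.fragment_length_bp,
                "mean_depth": round_half_up(m.mean_depth, 2),
                "pct_ge_20x": round_half_up(m.pct_ge[20], 2),
                "pct_zero": round_half_up(m.pct_zero, 2),
                "fold80": None if m.fold80 is None else round_half_up(m.fold80, 2),
                "successful": success[q.sample_id],
            }
        )
    qc_table = pd.DataFrame(qc_rows)
    advisories = pool_cohort(cohort.qc, cfg.qc)
    correlations = qc_correlation(cohort.qc)
    successful_ffpe = [sid for sid, ok in success.items() if ok]
    summary["n_samples"] = len(cohort.qc)
    summary["n_successful"] = len(successful_ffpe)
    summary["pct_successful"] = round_half_up(
        100.0 * len(successful_ffpe) / len(cohort.qc), 1
    )
    summary["qpcr_spearman_rho"] = round_half_up(correlations.loc["qpcr", "rho"], 3)
    summary["qpcr_spearman_p"] = float(correlations.loc["qpcr", "p_value"])

    low_cov = joint_low_coverage(
        [cohort.coverage[(sid, "ffpe")] for sid in successful_ffpe] or
        [cohort.coverage[(q.sample_id, "ffpe")] for q in cohort.qc],
        cfg.qc,
    )
    summary["joint_low_coverage_bases"] = low_cov.total_bases

    gene_curve = None
    if successful_ffpe:
        gene_curve = gene_coverage_curve(
            cohort.coverage[(successful_ffpe[0], "ffpe")], cohort.truth.gene_map
        )

    # ---- step 3: concordance ----------------------------------------------
    ensembles = _ensemble_sets(cohort, cfg)
    target = cohort.truth.target

    platinum_rows = []
    for sid in cohort.matched_sample_ids:
        for material in ("blood", "ffpe"):
            r = compare_callsets(cohort.truth.truth, ensembles[(sid, material)], target)
            platinum_rows.append(
                {"sample_id": sid, "material": material, **r.rounded(3)}
            )
    platinum = pd.DataFrame(platinum_rows)

    matched_ok = [
        sid for sid in cohort.matched_sample_ids if success[sid]
    ] or cohort.matched_sample_ids
    raw_results, final_results, discordant = [], [], {}
    exclusion_order = ["tandem_repeats_homopolymers", "bad_promoters", "low_mappability", "internal"]
    strat_rows = []
    for sid in matched_ok:
        blood = ensembles[(sid, "blood")]
        ffpe = ensembles[(sid, "ffpe")]
        cov20 = coverage_intersect(
            cohort.coverage[(sid, "ffpe")], cohort.coverage[(sid, "blood")], 20
        )
        ladder = build_ladder(
            target,
            restrict=[cov20, cohort.truth.confident],
            exclude=[cohort.truth.exclusions[k] for k in exclusion_order],
        )
        results = stratified_concordance(blood, ffpe, ladder)
        raw_results.append(results[0])
        final_results.append(results[-1])
        for (label, region), r in zip(ladder, results):
            strat_rows.append(
                {
                    "sample_id": sid,
                    "rung": label,
                    "bases": region.total_bases,
                    **r.rounded(3),
                }
            )
        discordant[sid] = discordant_keys(blood, ffpe, target)
    stratified = pd.DataFrame(strat_rows)

    raw = matched_pair_summary(raw_results)
    final = matched_pair_summary(final_results)
    summary["matched_n"] = raw.n
    summary["matched_mean_fp_raw"] = round_half_up(raw.mean["fp"], 1)
    summary["matched_mean_fn_raw"] = round_half_up(raw.mean["fn"], 1)
    summary["matched_mean_fp_stratified"] = round_half_up(final.mean["fp"], 1)
    summary["matched_mean_fn_stratified"] = round_half_up(final.mean["fn"], 1)
    summary["matched_ppv_raw"] = round_half_up(raw.pooled_ppv, 4)
    summary["matched_sensitivity_raw"] = round_half_up(raw.pooled_sensitivity, 4)
    summary["matched_ppv_stratified"] = round_half_up(final.pooled_ppv, 4)
    summary["matched_sensitivity_stratified"] = round_half_up(final.pooled_sensitivity, 4)
    summary["fp_reduction_pct"] = round_half_up(
        100.0 * (1.0 - final.mean["fp"] / raw.mean["fp"]), 1
    ) if raw.mean["fp"] else None
    summary["fn_reduction_pct"] = round_half_up(
        100.0 * (1.0 - final.mean["fn"] / raw.mean["fn"]), 1
    ) if raw.mean["fn"] else None

    venn = None
    if cohort.matched_sample_ids:
        sid = cohort.matched_sample_ids[0]
        venn = venn_partition(
            cohort.truth.truth, ensembles[(sid, "blood")], ensembles[(sid, "ffpe")]
        )

    blacklist = build_blacklist(discordant, cfg.cluster)
    summary["blacklist_regions"] = len(blacklist)
    summary["blacklist_bases"] = blacklist.total_bases

    # ---- step 4: clinical value -------------------------------------------
    rng = np.random.default_rng((cfg.sim.seed * 7919 + 13) % (2**31))
    reports = []
    for q in cohort.qc:
        sid = q.sample_id
        calls = ensembles[(sid, "ffpe")]
        assertion = cohort.planted_findings[sid]
        planted_genes = (
            cohort.panels["cdgp"].genes
            if assertion == "pathogenic"
            else cohort.panels["sdgp"].genes
        )
        annotate_callset(
            calls,
            cohort.truth.gene_map,
            rng,
            planted_assertion=assertion,
            planted_genes=planted_genes,
        )
        reports.append(
            run_referral(
                ReferralRequest(sid, "general_scd", None),
                calls,
                cohort.coverage[(sid, "ffpe")],
                cohort.panels,
                cfg.qc,
                failed_sequencing=not success[sid],
            )
        )
    yields = cohort_yield(reports)
    summary.update(yields)

    triage_rows = [
        {
            "case_id": r.case_id,
            "yield_category": r.yield_category,
            "n_retained": len(r.retained),
            "assertions": ",".join(sorted(r.retained_assertions())) or "none",
        }
        for r in reports
    ]
    triage_table = pd.DataFrame(triage_rows)

    # ---- reports ------------------------------------------------------------
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        qc_table.to_csv(outdir / "qc_metrics.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"sample_id": a.sample_id, "predicted_success": a.predicted_success,
                 "protocol": a.protocol, "pool_id": a.pool_id}
                for a in advisories
            ]
        ).to_csv(outdir / "advisories.tsv", sep="\t", index=False)
        correlations.to_csv(outdir / "qc_correlation.tsv", sep="\t")
        platinum.to_csv(outdir / "concordance_truth.tsv", sep="\t", index=False)
        stratified.to_csv(outdir / "concordance_stratified.tsv", sep="\t", index=False)
        triage_table.to_csv(outdir / "triage.tsv", sep="\t", index=False)
        write_bed(blacklist, outdir / "blacklist.bed")
        write_bed(low_cov, outdir / "joint_low_coverage.bed")
        if gene_curve is not None:
            gene_curve.to_csv(outdir / "gene_coverage_curve.tsv", sep="\t")
        if venn is not None:
            (outdir / "venn_counts.json").write_text(json.dumps(venn, indent=2) + "\n")
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
        )
        logger.info("pipeline run %s written to %s", summary["config_hash"], outdir)
    return summary
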