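"""Feasibility and sequencing performance of the FFPE cohort.

Computes per-sample coverage metrics (mean depth, %>=20X, %0X, fold80),
applies the 90%-at-20X success rule, correlates the pre-library QC metrics
(qPCR, DIN, fragment length) with sequencing success, flags jointly
low-covered target regions, and emits the pre-sequencing lab advisories
(frag/nofrag protocol, predicted failure above qPCR 10, pooling by
amplification potential).
"""

import argparse
from pathlib import Path

import pandas as pd

from ffpewes.coverage import (
    gene_coverage_curve,
    is_successful,
    joint_low_coverage,
    pool_cohort,
    qc_correlation,
    sample_metrics,
)
from ffpewes.io import write_bed
from ffpewes.simulate import SimulationConfig, simulate_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort(SimulationConfig(seed=args.seed))
    rows = []
    for q in cohort.qc:
        m = sample_metrics(cohort.coverage[(q.sample_id, "ffpe")])
        q.pct_ge_20x = m.pct_ge[20]
        rows.append(
            {
                "sample_id": q.sample_id,
                "qpcr": q.qpcr_value,
                "mean_depth": round(m.mean_depth, 2),
                "pct_ge_20x": round(m.pct_ge[20], 2),
                "pct_zero": round(m.pct_zero, 2),
                "fold80": None if m.fold80 is None else round(m.fold80, 2),
                "successful": is_successful(m),
            }
        )
    metrics = pd.DataFrame(rows)
    metrics.to_csv(args.out / "coverage_metrics.tsv", sep="\t", index=False)

    corr = qc_correlation(cohort.qc)
    corr.to_csv(args.out / "qc_correlation.tsv", sep="\t")

    advisories = pool_cohort(cohort.qc)
    pd.DataFrame(
        [
            {"sample_id": a.sample_id, "predicted_success": a.predicted_success,
             "protocol": a.protocol, "pool_id": a.pool_id}
            for a in advisories
        ]
    ).to_csv(args.out / "lab_advisories.tsv", sep="\t", index=False)

    ok = metrics[metrics.successful]
    low = joint_low_coverage(
        [cohort.coverage[(s, "ffpe")] for s in ok.sample_id]
    )
    write_bed(low, args.out / "joint_low_coverage.bed")
    curve = gene_coverage_curve(
        cohort.coverage[(ok.sample_id.iloc[0], "ffpe")], cohort.truth.gene_map
    )
    curve.to_csv(args.out / "gene_coverage_curve.tsv", sep="\t")

    n = len(metrics)
    print(f"{ok.shape[0]}/{n} samples successful "
          f"({100 * ok.shape[0] / n:.1f}%, rule: >=90% of target at 20X)")
    print("Spearman rho vs %>=20X: "
          + ", ".join(f"{m}={corr.loc[m, 'rho']:+.2f} (p={corr.loc[m, 'p_value']:.2g})"
                      for m in corr.index))
    print(f"joint low-coverage regions: {len(low)} ({low.total_bases} bases)")
    print(f"fold80 range: {metrics.fold80.min():.2f}-{metrics.fold80.max():.2f}")


if __name__ == "__main__":
    main()
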