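"""Coverage QC for targeted capture sequencing of FFPE material.

Per-sample metrics (mean depth, %>=X thresholds, %0X, fold80 base
penalty), the sequencing success rule (90% of target bases at >=20X),
joint low-coverage region detection across a cohort, gene-level
sliding-threshold coverage curves, and the correlation/advisory logic
linking pre-library QC measurements (qPCR amplification score, DIN,
fragment length) to sequencing outcome.

fold80 base penalty follows the Picard convention: mean depth divided by
the depth at the 20th percentile of target bases (nearest-rank on the
sorted per-base depth vector). A perfectly uniform track scores 1; the
value is the factor of extra sequencing needed to lift 80% of bases to the
mean depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CoverageTrack, RegionSet, SampleQC

__all__ = [
    "CoverageMetrics",
    "QCThresholds",
    "sample_metrics",
    "is_successful",
    "joint_low_coverage",
    "gene_coverage_curve",
    "qc_correlation",
    "lab_advisories",
    "pool_cohort",
    "LabAdvisory",
]

DEFAULT_DEPTH_THRESHOLDS = (10, 20, 30)


@dataclass(frozen=True)
class CoverageMetrics:
    sample_id: str
    mean_depth: float
    pct_ge: dict  # depth threshold -> percent of target bases at >= depth
    pct_zero: float
    fold80: Optional[float]  # None when the 20th-percentile depth is 0


@dataclass(frozen=True)
class QCThresholds:
    """Tunable QC constants of the workflow.

    ``success_pct20x``: percent of target bases at >=20X defining a
    successful exome. ``low_cov_*``: the four OR-combined per-base criteria
    flagging consistently low-covered positions across a cohort.
    ``qpcr_fail``: amplification score above which sequencing is predicted
    to fail. ``frag_protocol_bp``/``din_protocol``: thresholds routing a
    sample to the enzymatic-fragmentation library protocol. ``pool_size``:
    samples per sequencing pool.
    """

    success_pct20x: float = 90.0
    low_cov_sample_frac_zero: float = 0.25
    low_cov_max: int = 20
    low_cov_sum: int = 100
    low_cov_median: int = 20
    qpcr_fail: float = 10.0
    frag_protocol_bp: float = 1000.0
    din_protocol: float = 3.0
    pool_size: int = 8
    local_depth: int = 20  # depth for answering a single-position query

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")


def nearest_rank_percentile(depths: np.ndarray, pct: float) -> int:
    """Nearest-rank percentile of a depth vector (sorted ascending)."""
    n = len(depths)
    rank = max(1, math.ceil(pct / 100.0 * n))
    return int(np.partition(depths, rank - 1)[rank - 1])


def sample_metrics(
    track: CoverageTrack, thresholds: Sequence[int] = DEFAULT_DEPTH_THRESHOLDS
) -> CoverageMetrics:
    """Summary coverage metrics over all target bases of one sample."""
    depths = track.depths
    if len(depths) == 0:
        raise ValueError("empty coverage track")
    n = len(depths)
    pct_ge = {int(t): float((depths >= t).sum()) / n * 100.0 for t in thresholds}
    d20 = nearest_rank_percentile(depths, 20.0)
    mean = float(depths.mean())
    return CoverageMetrics(
        sample_id=track.sample_id,
        mean_depth=mean,
        pct_ge=pct_ge,
        pct_zero=float((depths == 0).sum()) / n * 100.0,
        fold80=(mean / d20) if d20 > 0 else None,
    )


def is_successful(metrics: CoverageMetrics, qc: QCThresholds = QCThresholds()) -> bool:
    """Successful sequencing: >= ``qc.success_pct20x``% of target bases at 20X."""
    if 20 not in metrics.pct_ge:
        raise KeyError("metrics lack the 20X entry needed for the success rule")
    return metrics.pct_ge[20] >= qc.success_pct20x


def joint_low_coverage(
    tracks: Sequence[CoverageTrack], qc: QCThresholds = QCThresholds()
) -> RegionSet:
    """Flag target bases with consistently poor coverage across a cohort.

    A base is flagged when ANY of the four criteria holds:
      - fraction of samples with zero depth >= ``low_cov_sample_frac_zero``
      - maximum depth across samples < ``low_cov_max``
      - sum of depths across samples < ``low_cov_sum``
      - median depth across samples < ``low_cov_median``
    Flagged bases are merged into a region set.
    """
    if not tracks:
        raise ValueError("need at least one coverage track")
    target = tracks[0].target
    for t in tracks[1:]:
        if t.target != target:
            raise ValueError("coverage tracks must share a target")
    depth = np.stack([t.depths for t in tracks])  # samples x bases
    flagged = (
        ((depth == 0).mean(axis=0) >= qc.low_cov_sample_frac_zero)
        | (depth.max(axis=0) < qc.low_cov_max)
        | (depth.sum(axis=0) < qc.low_cov_sum)
        | (np.median(depth, axis=0) < qc.low_cov_median)
    )
    return tracks[0].mask_to_regions(flagged, "joint_low_coverage")


def gene_coverage_curve(
    track: CoverageTrack,
    genes: Mapping[str, RegionSet],
    depth_thresholds: Sequence[int] = DEFAULT_DEPTH_THRESHOLDS,
    fraction_grid: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Fraction of genes "covered" across a sliding completeness threshold.

    A gene counts as covered at (depth d, fraction f) iff at least
    f * (gene target bases) of its bases reach depth >= d. Returns a
    DataFrame indexed by the fraction grid with one column per depth
    threshold; the curve is monotone non-increasing in both arguments.
    Genes without target bases are excluded.
    """
    if fraction_grid is None:
        fraction_grid = np.round(np.linspace(0.0, 1.0, 101), 4)
    fraction_grid = np.asarray(fraction_grid, dtype=float)
    covered_fraction = []
    for gene, region in genes.items():
        mask = track.region_mask(region)
        n = int(mask.sum())
        if n == 0:
            continue
        gene_depths = track.depths[mask]
        covered_fraction.append(
            [float((gene_depths >= d).sum()) / n for d in depth_thresholds]
        )
    if not covered_fraction:
        raise ValueError("no gene has target bases")
    frac = np.asarray(covered_fraction)  # genes x thresholds
    data = {}
    for j, d in enumerate(depth_thresholds):
        # covered at f iff count >= f*n  <=>  fraction >= f (tolerant at ties)
        data[int(d)] = [
            float((frac[:, j] >= f - 1e-12).mean()) for f in fraction_grid
        ]
    return pd.DataFrame(data, index=pd.Index(fraction_grid, name="fraction"))


def qc_correlation(qcs: Sequence[SampleQC]) -> pd.DataFrame:
    """Correlate each pre-library QC metric with sequencing success.

    For each of qpcr, din and fragment length: Spearman rho and p-value
    against the percent of target bases at >=20X, plus a logistic fit of
    pct_ge_20x/100 on the metric (GLM binomial with a quasi-likelihood
    dispersion estimate) with r^2 reported as the squared Pearson
    correlation between fitted and observed values. Constant metrics yield
    missing rho.
    """
    import statsmodels.api as sm

    qcs = [q for q in qcs if q.pct_ge_20x is not None]
    if len(qcs) < 4:
        raise ValueError("need at least 4 samples with pct_ge_20x")
    y = np.array([q.pct_ge_20x / 100.0 for q in qcs])
    metrics = {
        "qpcr": np.array([q.qpcr_value for q in qcs]),
        "din": np.array([q.din for q in qcs]),
        "fragment_length": np.array([q.fragment_length_bp for q in qcs]),
    }
    rows = []
    for name, x in metrics.items():
        if np.ptp(x) == 0:
            rows.append(
                {"metric": name, "rho": np.nan, "p_value": np.nan, "intercept": np.nan,
                 "slope": np.nan, "r2": np.nan, "dispersion": np.nan}
            )
            continue
        rho, pval = stats.spearmanr(x, y)
        model = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial())
        fit = model.fit()
        dispersion = fit.pearson_chi2 / fit.df_resid  # quasi-binomial scale
        fitted = np.asarray(fit.fittedvalues)
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) if np.ptp(fitted) > 0 else np.nan
        rows.append(
            {
                "metric": name,
                "rho": float(rho),
                "p_value": float(pval),
                "intercept": float(fit.params[0]),
                "slope": float(fit.params[1]),
                "r2": r2,
                "dispersion": float(dispersion),
            }
        )
    return pd.DataFrame(rows).set_index("metric")


@dataclass(frozen=True)
class LabAdvisory:
    sample_id: str
    predicted_success: bool
    protocol: str  # "frag" | "nofrag"
    pool_id: Optional[int] = None


def lab_advisories(qc: SampleQC, thresholds: QCThresholds = QCThresholds()) -> LabAdvisory:
    """Pre-sequencing advisory for one sample.

    Sequencing is predicted to fail for amplification scores above
    ``qpcr_fail``; the enzymatic-fragmentation protocol is chosen when the
    input is long (> ``frag_protocol_bp``) or intact (DIN > ``din_protocol``).
    """
    return LabAdvisory(
        sample_id=qc.sample_id,
        predicted_success=qc.qpcr_value <= thresholds.qpcr_fail,
        protocol=(
            "frag"
            if qc.fragment_length_bp > thresholds.frag_protocol_bp
            or qc.din > thresholds.din_protocol
            else "nofrag"
        ),
    )


def pool_cohort(
    qcs: Sequence[SampleQC], thresholds: QCThresholds = QCThresholds()
) -> list:
    """Assign samples to sequencing pools of similar amplification potential.

    Samples are sorted by qPCR score and chunked into pools of
    ``thresholds.pool_size`` so that each batch shares roughly equal
    quality, giving a more even read distribution within a run.
    """
    ranked = sorted(qcs, key=lambda q: (q.qpcr_value, q.sample_id))
    out = []
    for i, qc in enumerate(ranked):
        adv = lab_advisories(qc, thresholds)
        out.append(
            LabAdvisory(
                sample_id=adv.sample_id,
                predicted_success=adv.predicted_success,
                protocol=adv.protocol,
                pool_id=i // thresholds.pool_size,
            )
        )
    return out
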