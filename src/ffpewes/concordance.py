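"""Variant concordance between call sets, with region stratification.

Two validation designs are supported. Against a high-confidence truth
catalogue ("platinum"-style), truth variants found in the test sample are
true positives, truth variants missing are false negatives, and extra test
variants are false positives; sensitivity = TP/(TP+FN) and positive
predictive value PPV = TP/(TP+FP). For matched pairs, the blood sample
plays the role of truth against the FFPE sample.

Matching is by exact normalized variant key (allele-aware, genotype-blind).
Ratios with a zero denominator are reported as missing, never as 0.

A stratification ladder evaluates the same comparison over successively
restricted region sets (raw target, >=20X intersect, confident regions,
then exclusion of tandem repeats/homopolymers, low-mappability and other
difficult contexts), quantifying how much of the discordance lives in
problematic genomic contexts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .core import CallSet, CoverageTrack, RegionSet
from . import regions as rg

__all__ = [
    "ConcordanceResult",
    "concordance_from_counts",
    "compare_callsets",
    "MatchedSummary",
    "matched_pair_summary",
    "coverage_intersect",
    "StratificationLadder",
    "build_ladder",
    "stratified_concordance",
    "venn_partition",
    "round_half_up",
]


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding, as used for report tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConcordanceResult:
    """TP/FP/FN counts and derived rates for one comparison in one region."""

    tp: int
    fp: int
    fn: int
    region_name: str = "target"
    truth_label: str = "truth"
    test_label: str = "test"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def truth_size(self) -> int:
        return self.tp + self.fn

    @property
    def test_size(self) -> int:
        return self.tp + self.fp

    @property
    def sensitivity(self) -> Optional[float]:
        """TP/(TP+FN); None when the truth set is empty in the region."""
        return self.tp / self.truth_size if self.truth_size else None

    @property
    def ppv(self) -> Optional[float]:
        """TP/(TP+FP); None when the test set is empty in the region."""
        return self.tp / self.test_size if self.test_size else None

    def rounded(self, decimals: int = 3) -> dict:
        out = {"tp": self.tp, "fp": self.fp, "fn": self.fn}
        out["sensitivity"] = (
            None if self.sensitivity is None else round_half_up(self.sensitivity, decimals)
        )
        out["ppv"] = None if self.ppv is None else round_half_up(self.ppv, decimals)
        return out


def concordance_from_counts(
    truth_size: int,
    test_size: int,
    overlap: int,
    region_name: str = "target",
    truth_label: str = "truth",
    test_label: str = "test",
) -> ConcordanceResult:
    """Build a result from published-table style counts (truth, test, overlap)."""
    if overlap > min(truth_size, test_size):
        raise ValueError("overlap cannot exceed either set size")
    return ConcordanceResult(
        tp=overlap,
        fp=test_size - overlap,
        fn=truth_size - overlap,
        region_name=region_name,
        truth_label=truth_label,
        test_label=test_label,
    )


def compare_callsets(
    truth: CallSet, test: CallSet, region: RegionSet
) -> ConcordanceResult:
    """Classify variants by key overlap after restricting both sets to ``region``."""
    truth_keys = {k for k in truth.calls if rg.contains(region, k)}
    test_keys = {k for k in test.calls if rg.contains(region, k)}
    tp = len(truth_keys & test_keys)
    result = ConcordanceResult(
        tp=tp,
        fp=len(test_keys) - tp,
        fn=len(truth_keys) - tp,
        region_name=region.name,
        truth_label=f"{truth.sample_id}:{truth.material}",
        test_label=f"{test.sample_id}:{test.material}",
    )
    assert result.truth_size == len(truth_keys) and result.test_size == len(test_keys)
    return result


def discordant_keys(truth: CallSet, test: CallSet, region: RegionSet) -> set:
    """FP plus FN keys of a comparison (the non-overlapping variants)."""
    truth_keys = {k for k in truth.calls if rg.contains(region, k)}
    test_keys = {k for k in test.calls if rg.contains(region, k)}
    return truth_keys ^ test_keys


@dataclass(frozen=True)
class MatchedSummary:
    """Cohort summary of matched-pair comparisons: mean and (min, max) per field.

    ``mean``/``minimum``/``maximum`` map field name -> value for tp, fp, fn,
    sensitivity, ppv. Undefined ratios are excluded from their mean.
    ``pooled_sensitivity``/``pooled_ppv`` are the ratios recomputed from the
    mean counts (the convention of published cohort tables).
    """

    n: int
    mean: dict
    minimum: dict
    maximum: dict

    @property
    def pooled_sensitivity(self) -> Optional[float]:
        denom = self.mean["tp"] + self.mean["fn"]
        return self.mean["tp"] / denom if denom else None

    @property
    def pooled_ppv(self) -> Optional[float]:
        denom = self.mean["tp"] + self.mean["fp"]
        return self.mean["tp"] / denom if denom else None


def matched_pair_summary(results: Sequence[ConcordanceResult]) -> MatchedSummary:
    if not results:
        raise ValueError("need at least one result")
    fields = ("tp", "fp", "fn", "sensitivity", "ppv")
    values = {
        f: [getattr(r, f) for r in results if getattr(r, f) is not None] for f in fields
    }
    mean = {f: float(np.mean(v)) if v else None for f, v in values.items()}
    minimum = {f: min(v) if v else None for f, v in values.items()}
    maximum = {f: max(v) if v else None for f, v in values.items()}
    return MatchedSummary(n=len(results), mean=mean, minimum=minimum, maximum=maximum)


def coverage_intersect(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    depth_threshold: int = 20,
    name: Optional[str] = None,
) -> RegionSet:
    """Maximal regions where both samples reach ``depth_threshold``."""
    if track_a.target != track_b.target:
        raise ValueError("coverage tracks must share a target")
    mask = (track_a.depths >= depth_threshold) & (track_b.depths >= depth_threshold)
    return track_a.mask_to_regions(
        mask, name or f"{depth_threshold}X_intersect"
    )


# A stratification ladder is an ordered list of (label, RegionSet) rungs.
StratificationLadder = list


def build_ladder(
    target: RegionSet,
    restrict: Sequence[RegionSet] = (),
    exclude: Sequence[RegionSet] = (),
) -> StratificationLadder:
    """Build the evaluation ladder: raw target, successive restrictions
    (e.g. the matched >=20X intersect, confident regions), then cumulative
    exclusions of problematic region sets."""
    ladder = [(target.name, target)]
    current = target
    for rs in restrict:
        current = rg.intersect(current, rs, name=rs.name)
        ladder.append((rs.name, current))
    for rs in exclude:
        current = rg.subtract(current, rs, name=f"minus_{rs.name}")
        ladder.append((f"minus_{rs.name}", current))
    return ladder


def stratified_concordance(
    truth: CallSet, test: CallSet, ladder: StratificationLadder
) -> list:
    """One :class:`ConcordanceResult` per ladder rung, in ladder order."""
    return [compare_callsets(truth, test, region) for _label, region in ladder]


def venn_partition(a: CallSet, b: CallSet, c: CallSet) -> dict:
    """Counts of the 7 membership classes of three call sets (Venn layout)."""
    ka, kb, kc = a.keys(), b.keys(), c.keys()
    return {
        "a_only": len(ka - kb - kc),
        "b_only": len(kb - ka - kc),
        "c_only": len(kc - ka - kb),
        "ab": len((ka & kb) - kc),
        "ac": len((ka & kc) - kb),
        "bc": len((kb & kc) - ka),
        "abc": len(ka & kb & kc),
    }
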