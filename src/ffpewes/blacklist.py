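"""Discovery of problematic regions from discordant variant positions.

Non-overlapping (discordant) variants from matched-pair comparisons are
pooled across samples and merged into regions with a 100 bp sliding
window. The iterative window merge is implemented as its fixed point:
single-linkage clustering where two positions on the same chromosome join
one cluster iff a chain of successive gaps <= window links them. The
resulting intervals form the internal database of highly problematic
regions; variants falling in them are excluded from downstream
interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import GenomicInterval, RegionSet, VariantKey

__all__ = ["ClusterConfig", "cluster_positions", "build_blacklist"]


@dataclass(frozen=True)
class ClusterConfig:
    window_bp: int = 100
    # a lone discordant call is noise; a cluster is a region enriched for them
    min_variants_per_region: int = 2
    min_samples: int = 1

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.min_variants_per_region < 1 or self.min_samples < 1:
            raise ValueError("minimum counts must be >= 1")


def _clusters(positions: Sequence, window_bp: int) -> list:
    """Single-linkage clusters of (chrom, pos1) pairs; gap <= window joins."""
    by_chrom: dict[str, list] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)
    out = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom])
        start = prev = ps[0]
        members = [ps[0]]
        for p in ps[1:]:
            if p - prev <= window_bp:
                members.append(p)
            else:
                out.append((chrom, start, prev, members))
                start = p
                members = [p]
            prev = p
        out.append((chrom, start, prev, members))
    return out


def cluster_positions(positions: Iterable, cfg: ClusterConfig) -> RegionSet:
    """Merge 1-based variant positions into regions (order independent).

    Each cluster spans [min_pos - 1, max_pos) in 0-based half-open
    coordinates (minimum width 1 base). Clusters with fewer than
    ``cfg.min_variants_per_region`` member positions (repeats counted)
    are dropped.
    """
    positions = list(positions)
    if not positions:
        return RegionSet("problematic_regions")
    intervals = [
        GenomicInterval(chrom, lo - 1, hi)
        for chrom, lo, hi, members in _clusters(positions, cfg.window_bp)
        if len(members) >= cfg.min_variants_per_region
    ]
    return RegionSet("problematic_regions", intervals)


def build_blacklist(
    per_sample_discordant: Mapping[str, Iterable[VariantKey]], cfg: ClusterConfig
) -> RegionSet:
    """Pool discordant anchor positions across samples and cluster them.

    After clustering, regions supported by fewer than ``cfg.min_samples``
    distinct samples are dropped.
    """
    pooled = []
    sample_of = []
    for sample, keys in per_sample_discordant.items():
        for key in keys:
            pooled.append((key.chrom, key.pos))
            sample_of.append(sample)
    if not pooled:
        return RegionSet("blacklist")
    clustered = cluster_positions(pooled, cfg)
    if cfg.min_samples <= 1:
        return clustered.rename("blacklist")
    kept = []
    for iv in clustered:
        supporters = {
            s
            for (chrom, pos), s in zip(pooled, sample_of)
            if chrom == iv.chrom and iv.start < pos <= iv.end
        }
        if len(supporters) >= cfg.min_samples:
            kept.append(iv)
    return RegionSet("blacklist", kept)
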