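"""Interval-set algebra on half-open genomic regions.

Implements the operations behind target construction (exon flanking),
stratification (intersect/subtract with confident and problematic region
files), and region-restricted variant comparisons. All sets are kept
normalized (sorted, merged, book-ended intervals fused) so base counts are
representation independent.

Variant-to-region membership tests use the variant's POS anchor base only
(``pos - 1`` in 0-based coordinates), not the full REF span; this matches
how interval tools typically intersect VCF records and makes membership
unambiguous for indels straddling a boundary.
"""

from __future__ import annotations

from typing import Iterable

from .core import GenomicInterval, RegionSet, VariantKey

__all__ = [
    "flank_target",
    "intersect",
    "subtract",
    "union",
    "total_bases",
    "contains",
]


def flank_target(exons: RegionSet, flank_bp: int, name: str | None = None) -> RegionSet:
    """Extend every interval by ``flank_bp`` on both sides (clipped at 0).

    Overlaps created by flanking are merged, so flanking two nearby exons
    by 10 bp can fuse them into one target interval.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    out = [
        GenomicInterval(iv.chrom, max(0, iv.start - flank_bp), iv.end + flank_bp)
        for iv in exons
    ]
    return RegionSet(name or f"{exons.name}+{flank_bp}bp", out)


def _per_chrom(rs: RegionSet) -> dict:
    d: dict[str, list] = {}
    for iv in rs:
        d.setdefault(iv.chrom, []).append(iv)
    return d


def intersect(a: RegionSet, b: RegionSet, name: str | None = None) -> RegionSet:
    """Bases present in both sets (two-pointer sweep per chromosome)."""
    bd = _per_chrom(b)
    out = []
    for chrom, ivs in _per_chrom(a).items():
        others = bd.get(chrom)
        if not others:
            continue
        i = j = 0
        while i < len(ivs) and j < len(others):
            lo = max(ivs[i].start, others[j].start)
            hi = min(ivs[i].end, others[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if ivs[i].end <= others[j].end:
                i += 1
            else:
                j += 1
    return RegionSet(name or f"{a.name}&{b.name}", out)


def subtract(a: RegionSet, b: RegionSet, name: str | None = None) -> RegionSet:
    """Bases in ``a`` not in ``b``."""
    bd = _per_chrom(b)
    out = []
    for chrom, ivs in _per_chrom(a).items():
        others = bd.get(chrom, [])
        j = 0
        for iv in ivs:
            cursor = iv.start
            while j < len(others) and others[j].end <= cursor:
                j += 1
            k = j
            while k < len(others) and others[k].start < iv.end:
                if others[k].start > cursor:
                    out.append(GenomicInterval(chrom, cursor, others[k].start))
                cursor = max(cursor, others[k].end)
                k += 1
            if cursor < iv.end:
                out.append(GenomicInterval(chrom, cursor, iv.end))
    return RegionSet(name or f"{a.name}-{b.name}", out)


def union(sets: Iterable[RegionSet], name: str = "union") -> RegionSet:
    ivs = [iv for rs in sets for iv in rs]
    return RegionSet(name, ivs)


def total_bases(a: RegionSet) -> int:
    """Total base count of a normalized region set."""
    return a.total_bases


def contains(a: RegionSet, key: VariantKey) -> bool:
    """True iff the variant's anchor base (pos - 1, 0-based) lies in ``a``."""
    return a.contains_pos(key.chrom, key.anchor0)
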