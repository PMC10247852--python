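"""Core domain types for FFPE whole-exome validation.

Coordinate conventions
----------------------
All internal interval arithmetic is 0-based, half-open (BED convention).
Variant positions (:class:`VariantKey.pos`) are 1-based, as in VCF. The
anchor base of a variant in 0-based coordinates is therefore ``pos - 1``.

Variant identity is a normalized ``(chrom, pos, ref, alt)`` tuple:
left-aligned and parsimony-trimmed, one alternate allele per key, so that
set comparisons between call sets are representation-invariant.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, NamedTuple, Optional

import numpy as np

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "VariantKey",
    "VariantAnnotations",
    "VariantCall",
    "CallSet",
    "CoverageTrack",
    "SampleQC",
    "normalize_variant",
    "trim_key",
    "canonical_contig",
    "NormalizationError",
]

_BASES = frozenset("ACGTN")

MATERIALS = ("blood", "ffpe", "truth")

PATHOGENICITY_LEVELS = ("pathogenic", "likely_pathogenic", "vus", "benign", "none")


class NormalizationError(ValueError):
    """Raised when an allele contradicts the reference sequence."""


def canonical_contig(name: str, aliases: Optional[dict] = None) -> str:
    """Map a contig name to its canonical form.

    By default bare names ("1", "X") gain a "chr" prefix so that files
    mixing "chr1" and "1" compare on one namespace. An explicit alias map
    overrides the default.
    """
    if aliases and name in aliases:
        return aliases[name]
    if not name.startswith("chr"):
        return "chr" + name
    return name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def _merge_intervals(intervals: Iterable[GenomicInterval]) -> tuple:
    """Sort and merge overlapping or adjacent intervals per chromosome."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return tuple(merged)


class RegionSet:
    """A named, normalized collection of genomic intervals.

    Normalization (applied on construction) sorts intervals by
    (chrom, start) and merges any overlapping or book-ended pairs, so the
    base count of a region set is representation independent.
    """

    __slots__ = ("name", "intervals", "_index")

    def __init__(self, name: str, intervals: Iterable[GenomicInterval] = ()):
        self.name = name
        self.intervals: tuple = _merge_intervals(intervals)
        # per-chrom sorted (starts, ends) for O(log n) membership lookups
        index: dict[str, tuple[list, list]] = {}
        for iv in self.intervals:
            starts, ends = index.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)
        self._index = index

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionSet) and self.intervals == other.intervals

    def __hash__(self) -> int:
        return hash(self.intervals)

    def __repr__(self) -> str:
        return f"RegionSet({self.name!r}, {len(self.intervals)} intervals, {self.total_bases} bases)"

    @property
    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    @property
    def chroms(self) -> tuple:
        return tuple(self._index)

    def contains_pos(self, chrom: str, pos0: int) -> bool:
        """True iff the 0-based position lies inside the set."""
        entry = self._index.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < ends[i]

    def rename(self, name: str) -> "RegionSet":
        return RegionSet(name, self.intervals)


class VariantKey(NamedTuple):
    """Normalized variant identity: 1-based position, single ALT allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def validate(self) -> "VariantKey":
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _BASES:
                raise ValueError(f"allele {allele!r} contains non-ACGTN characters")
        return self

    @property
    def anchor0(self) -> int:
        """0-based coordinate of the POS anchor base."""
        return self.pos - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class VariantAnnotations:
    """Interpretation-layer annotations consumed (never computed) here."""

    gene: Optional[str] = None
    transcript: Optional[str] = None
    population_af: Optional[float] = None
    pathogenicity: str = "none"

    def __post_init__(self) -> None:
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValueError(f"population_af must be in [0,1], got {self.population_af}")
        if self.pathogenicity not in PATHOGENICITY_LEVELS:
            raise ValueError(f"unknown pathogenicity level {self.pathogenicity!r}")

    def merged_with(self, other: "VariantAnnotations") -> "VariantAnnotations":
        """First non-missing field wins (self has priority)."""
        return VariantAnnotations(
            gene=self.gene if self.gene is not None else other.gene,
            transcript=self.transcript if self.transcript is not None else other.transcript,
            population_af=(
                self.population_af if self.population_af is not None else other.population_af
            ),
            pathogenicity=(
                self.pathogenicity if self.pathogenicity != "none" else other.pathogenicity
            ),
        )


@dataclass
class VariantCall:
    """One variant observation with caller provenance."""

    key: VariantKey
    genotype: Optional[tuple] = None  # unordered allele pair, e.g. ("A", "G")
    quality: Optional[float] = None
    callers: frozenset = frozenset()
    annotations: VariantAnnotations = field(default_factory=VariantAnnotations)

    def __post_init__(self) -> None:
        self.key.validate()
        self.callers = frozenset(self.callers)
        if not self.callers:
            raise ValueError("callers must be non-empty")
        if self.genotype is not None:
            self.genotype = tuple(sorted(self.genotype))


@dataclass
class CallSet:
    """One sample's variant calls from one provenance (caller or ensemble)."""

    sample_id: str
    material: str
    provenance: str
    calls: dict = field(default_factory=dict)  # VariantKey -> VariantCall

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValueError(f"material must be one of {MATERIALS}, got {self.material!r}")
        for key, call in self.calls.items():
            if call.key != key:
                raise ValueError(f"call keyed by {key} carries key {call.key}")

    def add(self, call: VariantCall) -> None:
        self.calls[call.key] = call

    def keys(self) -> set:
        return set(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.calls

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls.values())

    def sorted_calls(self) -> list:
        return [self.calls[k] for k in sorted(self.calls)]

    def restricted_to(self, region: "RegionSet") -> "CallSet":
        """Calls whose anchor base lies inside ``region``."""
        kept = {
            k: c for k, c in self.calls.items() if region.contains_pos(k.chrom, k.anchor0)
        }
        return CallSet(self.sample_id, self.material, self.provenance, kept)


class CoverageTrack:
    """Per-base sequencing depth over a target region set for one sample.

    Depths are stored as one flat integer vector whose order follows the
    normalized target intervals (chrom, then position).
    """

    __slots__ = ("sample_id", "target", "depths", "_offsets")

    def __init__(self, sample_id: str, target: RegionSet, depths):
        depths = np.asarray(depths, dtype=np.int64)
        if depths.ndim != 1 or len(depths) != target.total_bases:
            raise ValueError(
                f"need {target.total_bases} depth values for target "
                f"{target.name!r}, got {depths.shape}"
            )
        if (depths < 0).any():
            raise ValueError("depths must be non-negative")
        self.sample_id = sample_id
        self.target = target
        self.depths = depths
        offsets = {}
        cum = 0
        for iv in target.intervals:
            offsets[(iv.chrom, iv.start)] = cum
            cum += len(iv)
        self._offsets = offsets

    def __len__(self) -> int:
        return len(self.depths)

    def index_of(self, chrom: str, pos0: int) -> Optional[int]:
        """Flat index of a 0-based position, or None if off target."""
        entry = self.target._index.get(chrom)
        if entry is None:
            return None
        starts, ends = entry
        i = bisect.bisect_right(starts, pos0) - 1
        if i < 0 or pos0 >= ends[i]:
            return None
        return self._offsets[(chrom, starts[i])] + (pos0 - starts[i])

    def depth_at(self, chrom: str, pos0: int) -> Optional[int]:
        i = self.index_of(chrom, pos0)
        return None if i is None else int(self.depths[i])

    def region_mask(self, region: RegionSet) -> np.ndarray:
        """Boolean mask over target bases that fall inside ``region``."""
        mask = np.zeros(len(self.depths), dtype=bool)
        for iv in region:
            entry = self.target._index.get(iv.chrom)
            if entry is None:
                continue
            starts, ends = entry
            lo = bisect.bisect_right(starts, iv.start) - 1
            for j in range(max(lo, 0), len(starts)):
                if starts[j] >= iv.end:
                    break
                a = max(starts[j], iv.start)
                b = min(ends[j], iv.end)
                if a < b:
                    off = self._offsets[(iv.chrom, starts[j])]
                    mask[off + (a - starts[j]) : off + (b - starts[j])] = True
        return mask

    def mask_to_regions(self, mask: np.ndarray, name: str) -> RegionSet:
        """Turn a boolean mask over target bases back into genomic intervals."""
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != len(self.depths):
            raise ValueError("mask length must equal the number of target bases")
        intervals = []
        cum = 0
        for iv in self.target.intervals:
            sub = mask[cum : cum + len(iv)]
            if sub.any():
                edges = np.flatnonzero(np.diff(np.concatenate(([0], sub.view(np.int8), [0]))))
                for a, b in zip(edges[::2], edges[1::2]):
                    intervals.append(GenomicInterval(iv.chrom, iv.start + int(a), iv.start + int(b)))
            cum += len(iv)
        return RegionSet(name, intervals)


@dataclass
class SampleQC:
    """Pre-library and sequencing QC measurements for one sample.

    ``qpcr_value`` is a dCq-style amplification-potential score (higher is
    worse); ``din`` the DNA Integrity Number (1-10, electrophoretic);
    ``fragment_length_bp`` the average input fragment length.
    """

    sample_id: str
    qpcr_value: float
    din: float
    fragment_length_bp: float
    mapped_reads: int
    pct_ge_20x: Optional[float] = None

    def __post_init__(self) -> None:
        if self.qpcr_value < 0:
            raise ValueError("qpcr_value must be >= 0")
        if not 1.0 <= self.din <= 10.0:
            raise ValueError("din must lie in [1, 10]")
        if self.fragment_length_bp <= 0:
            raise ValueError("fragment_length_bp must be positive")
        if self.mapped_reads < 0:
            raise ValueError("mapped_reads must be >= 0")
        if self.pct_ge_20x is not None and not 0.0 <= self.pct_ge_20x <= 100.0:
            raise ValueError("pct_ge_20x must lie in [0, 100]")


# ---------------------------------------------------------------------------
# Variant normalization
# ---------------------------------------------------------------------------

def trim_key(key: VariantKey) -> VariantKey:
    """Reference-free parsimony trim of shared leading/trailing bases.

    Keeps the mandatory single anchor base for indels. Cannot left-align
    (that needs reference sequence); see :func:`normalize_variant`.
    """
    chrom, pos, ref, alt = key
    # trim shared suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt).validate()


def normalize_variant(
    key: VariantKey, reference_lookup: Callable[[str, int, int], str]
) -> VariantKey:
    """Left-align and parsimony-trim a variant against the reference.

    ``reference_lookup(chrom, start0, end0)`` must return the reference
    bases of the half-open interval. The result is the canonical
    (left-most, minimal) representation; the operation is idempotent.

    Raises :class:`NormalizationError` when the REF allele disagrees with
    the reference sequence.
    """
    key = key.validate()
    chrom, pos, ref, alt = key
    expected = reference_lookup(chrom, pos - 1, pos - 1 + len(ref)).upper()
    if expected != ref:
        raise NormalizationError(
            f"REF {ref!r} at {chrom}:{pos} does not match reference {expected!r}"
        )
    while True:
        # trim shared trailing base
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        # left-extend when one allele is exhausted down to the anchor and
        # both still share their last base (pure indel not yet left-most)
        if (len(ref) == 1 or len(alt) == 1) and ref[-1] == alt[-1] and pos > 1:
            prev = reference_lookup(chrom, pos - 2, pos - 1).upper()
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            continue
        break
    # trim shared leading bases beyond the mandatory anchor
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt).validate()
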