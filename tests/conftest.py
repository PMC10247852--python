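"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use the dumbest possible representation (per-base
boolean masks over a small genome, exhaustive set arithmetic, pairwise
union-find) so they stay independent of the interval/set algebra they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from ffpewes.core import GenomicInterval, RegionSet
from ffpewes.simulate import SimulationConfig, simulate_cohort

GENOME = {"chr1": 10_000, "chr2": 10_000}


# ---------------------------------------------------------------------------
# per-base mask oracle for region algebra
# ---------------------------------------------------------------------------

def mask_of(rs: RegionSet, genome: dict = GENOME) -> dict:
    masks = {c: np.zeros(n, dtype=bool) for c, n in genome.items()}
    for iv in rs:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def regions_from_mask(masks: dict, name: str = "oracle") -> RegionSet:
    out = []
    for chrom, mask in masks.items():
        padded = np.concatenate(([0], mask.view(np.int8), [0]))
        edges = np.flatnonzero(np.diff(padded))
        for a, b in zip(edges[::2], edges[1::2]):
            out.append(GenomicInterval(chrom, int(a), int(b)))
    return RegionSet(name, out)


def random_regionset(rng: np.random.Generator, n: int = 20, name: str = "rand",
                     genome: dict = GENOME) -> RegionSet:
    ivs = []
    chroms = list(genome)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, genome[chrom] - 200))
        ivs.append(GenomicInterval(chrom, start, start + int(rng.integers(1, 200))))
    return RegionSet(name, ivs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_817)


# ---------------------------------------------------------------------------
# small simulated cohort, sized so the full suite stays fast
# ---------------------------------------------------------------------------

SMALL_SIM = SimulationConfig(
    seed=7,
    genome=(("chr1", 30_000), ("chr2", 30_000)),
    n_exons=200,
    exon_length=100,
    n_truth_variants=1_500,
    n_problematic_regions=12,
    n_capture_poor_regions=2,
    exons_per_gene=1,
    n_samples=6,
    n_matched_pairs=3,
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_SIM)
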