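"""Build the internal database of problematic regions from discordant calls.

Pools the non-overlapping variants of every matched FFPE/blood comparison,
clusters them with a 100 bp sliding window, and reports how well the
resulting blacklist recovers the regions where errors were planted.
"""

import argparse
from pathlib import Path

from ffpewes.blacklist import ClusterConfig, build_blacklist
from ffpewes.concordance import discordant_keys
from ffpewes.core import RegionSet
from ffpewes.ensemble import EnsembleConfig, consensus_calls
from ffpewes.io import write_bed
from ffpewes.regions import intersect, subtract
from ffpewes.simulate import SimulationConfig, simulate_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--window", type=int, default=100)
    parser.add_argument("--min-variants", type=int, default=2)
    parser.add_argument("--min-samples", type=int, default=2)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort(SimulationConfig(seed=args.seed))
    ecfg = EnsembleConfig()
    per_sample = {}
    for sid in cohort.matched_sample_ids:
        blood = consensus_calls(
            [cohort.caller_sets[(sid, "blood")][c] for c in ecfg.caller_labels], ecfg
        )
        ffpe = consensus_calls(
            [cohort.caller_sets[(sid, "ffpe")][c] for c in ecfg.caller_labels], ecfg
        )
        per_sample[sid] = discordant_keys(blood, ffpe, cohort.truth.target)

    cfg = ClusterConfig(
        window_bp=args.window,
        min_variants_per_region=args.min_variants,
        min_samples=args.min_samples,
    )
    blacklist = build_blacklist(per_sample, cfg)
    write_bed(blacklist, args.out / "blacklist.bed")

    planted = cohort.truth.problematic
    recovered = sum(
        intersect(blacklist, RegionSet("one", [iv])).total_bases > 0 for iv in planted
    )
    overlap = intersect(blacklist, planted)
    spill = subtract(blacklist, planted)
    n_disc = sum(len(v) for v in per_sample.values())
    print(f"pooled {n_disc} discordant calls from {len(per_sample)} matched pairs")
    print(f"blacklist: {len(blacklist)} regions, {blacklist.total_bases:,} bases "
          f"(window {args.window} bp, >= {args.min_variants} variants, "
          f">= {args.min_samples} samples)")
    print(f"planted problematic regions intersected: {recovered}/{len(planted)}")
    print(f"blacklist bases inside planted regions: {overlap.total_bases:,}; "
          f"outside: {spill.total_bases:,}")


if __name__ == "__main__":
    main()
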