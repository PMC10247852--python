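"""Generate the synthetic molecular-autopsy cohort used by all later steps.

Writes the cohort in its on-disk form (per-caller VCFs, target and
stratification BEDs, coverage bedGraphs, the pre-library QC table) under
results/simdir/ so every downstream step can also be run from files.
"""

import argparse
from pathlib import Path

from ffpewes.simulate import SimulationConfig, simulate_cohort, write_simdir


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/simdir"))
    args = parser.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    cohort = simulate_cohort(cfg)
    write_simdir(cohort, args.out)

    n_matched = cfg.n_matched_pairs
    print(f"simulated {cfg.n_samples} FFPE cases ({n_matched} with a matched blood sample)")
    print(f"toy exome: {cohort.truth.target.total_bases:,} target bases, "
          f"{len(cohort.truth.truth):,} truth variants")
    print(f"problematic regions: {len(cohort.truth.problematic)} "
          f"({cohort.truth.problematic.total_bases:,} bases, "
          f"error enrichment x{cfg.problematic_enrichment:.0f})")
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
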