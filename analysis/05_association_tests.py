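#!/usr/bin/env python
"""Carrier-based association of rare candidate-gene missense variants.

Finding: 3 of 73 index cases versus 326 of 64,603 reference individuals
carry a qualifying (MAF <= 0.001) missense variant — cumulative carrier
frequencies 0.0411 vs 0.00505, two-sided Fisher's exact p = 0.00624.  On
a synthetic cohort realizing the study's 3/73-case vs 0/100-control
carrier configuration, permutation burden and SKAT-style tests give
concordant, seed-reproducible p-values.
"""

import argparse
from pathlib import Path

import numpy as np

from aneuvar import io, simulate
from aneuvar.association import (CarrierTable, SkatInput, burden_test,
                                 cumulative_carrier_frequency,
                                 fisher_exact, skat_test)

OUT = Path(__file__).resolve().parent.parent / "results" / "association"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--permutations", type=int, default=99_999)
    args = parser.parse_args()

    fisher = fisher_exact(CarrierTable(3, 70, 326, 64277))
    cohort_freq = cumulative_carrier_frequency(3, 73)
    reference_freq = cumulative_carrier_frequency(326, 64603)
    print(f"cumulative carrier frequency: cohort {cohort_freq:.3g}, "
          f"reference {reference_freq:.3g}")
    print(f"Fisher's exact (two-sided): p = {fisher.p_value:.3g}, "
          f"Haldane OR = {fisher.odds_ratio_haldane:.1f}")

    cfg = simulate.SyntheticCohortConfig(
        seed=args.seed, n_cases=73, n_controls=100,
        carrier_specs=[simulate.CarrierSpec("EDIL3", "c.383G>A",
                                            "cases", 3)],
        n_background_variants=0)
    callset, _ann, pedigree = simulate.generate_cohort(cfg)
    phenotype = np.array([
        1.0 if pedigree[s].affection.value == "affected" else 0.0
        for s in callset.sample_ids])
    inp = SkatInput(phenotype=phenotype, genotypes=callset.dosage_matrix(),
                    n_permutations=args.permutations, seed=args.seed)
    burden = burden_test(inp)
    skat = skat_test(inp)
    print(f"synthetic 73/100 cohort (3 case carriers, "
          f"{args.permutations} permutations):")
    print(f"  burden: statistic {burden.statistic:.4g}, "
          f"p = {burden.p_value:.4g}")
    print(f"  SKAT:   statistic {skat.statistic:.4g}, "
          f"p = {skat.p_value:.4g} "
          f"(moment-matched {skat.p_value_moment:.4g})")

    io.write_report({"association": {
        "fisher": {"table": fisher.contingency, "p": fisher.p_value},
        "cumulative_carrier_frequency": {"cohort": cohort_freq,
                                         "reference": reference_freq},
        "burden": {"statistic": burden.statistic, "p": burden.p_value,
                   "seed": args.seed,
                   "n_permutations": args.permutations},
        "skat": {"statistic": skat.statistic, "p": skat.p_value,
                 "p_moment": skat.p_value_moment, "seed": args.seed,
                 "n_permutations": args.permutations},
    }}, OUT)
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
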