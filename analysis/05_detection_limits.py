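"""Detection limits for rare populations and the drift barrier to establishment.

How often does a population at 1 cell/ml escape notice in an amplicon
library, even though it numbers billions of cells in a small lake?  Tables
the binomial read-count distribution at survey-scale library sizes, the
census sizes implied by low densities, and the expected number of times an
immigrant lineage must appear before establishing against ecological drift.
"""

import argparse
from pathlib import Path

import pandas as pd

from saltscan.detect import (
    DetectionParams,
    census_size,
    detection_probability,
    establishment_appearances,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for library in (10_000, 50_000, 150_000, 500_000):
        params = DetectionParams(population_density=1.0,
                                 community_density=500_000.0,
                                 library_size=library)
        rows.append({
            "library_size": library,
            "p_missed": detection_probability(params, 0),
            "p_single_read": detection_probability(params, 1),
            "p_detected": 1 - detection_probability(params, 0),
        })
    detection = pd.DataFrame(rows)
    detection.to_csv(args.out / "detection_probability.tsv", sep="\t", index=False)
    print(detection.to_string(index=False))
    at_150k = detection.set_index("library_size").loc[150_000]
    print(
        f"\nAt 150,000 reads a 1-in-500,000 population is missed "
        f"{at_150k['p_missed']:.0%} of the time and seen exactly once "
        f"{at_150k['p_single_read']:.0%} of the time."
    )

    census = pd.DataFrame(
        [
            {"system": "small bog lake (1 km^2)", "cells":
                census_size(DetectionParams(1.0, 2.0, 1, area_m2=1e6, depth_m=1.0))},
            {"system": "large lake (5.8e10 m^2)", "cells":
                census_size(DetectionParams(1.0, 2.0, 1, area_m2=5.8e10, depth_m=1.0))},
        ]
    )
    census.to_csv(args.out / "census_size.tsv", sep="\t", index=False)
    print("\nCensus size of a 1 cell/ml population in a 1 m layer:")
    print(census.to_string(index=False))

    drift = pd.DataFrame(
        [{"selective_advantage": s, "expected_appearances": establishment_appearances(s)}
         for s in (0.5, 0.1, 0.01, 0.001)]
    )
    drift.to_csv(args.out / "establishment.tsv", sep="\t", index=False)
    print("\nAppearances needed before establishment (2s approximation):")
    print(drift.to_string(index=False))


if __name__ == "__main__":
    main()
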