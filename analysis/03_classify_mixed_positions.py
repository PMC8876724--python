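#!/usr/bin/env python
"""Classify every mixed position as NUMT variant or PHP; score vs truth.

Writes results/classification.tsv and prints the confusion against the
simulation truth labels (donor-derived positions are true NUMT variants,
planted heteroplasmies true PHPs).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from cohort import RESULTS, TRUE_DONOR_POSITIONS, cohort_specs, \
    processed_results
from mitowgs.pipeline import classify_cohort


def main() -> None:
    results = processed_results()
    table = classify_cohort(results)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "classification.tsv", sep="\t", index=False)

    specs = cohort_specs()
    correct = wrong = other = 0
    for row in table.itertuples():
        spec = specs[row.sample]
        true_php = {p.position for p in spec.phps}
        has_donor = bool(spec.donors)
        if has_donor and row.position in TRUE_DONOR_POSITIONS:
            truth = "NUMT"
        elif row.position in true_php:
            truth = "PHP"
        else:
            other += 1  # contaminant-driven or artifact positions
            continue
        if row.label == truth:
            correct += 1
        else:
            wrong += 1
            print(f"  mismatch: {row.sample} {row.variant} "
                  f"labelled {row.label}, truth {truth}")
    print(f"{len(table)} mixed positions classified; "
          f"{correct}/{correct + wrong} truth-labelled positions correct, "
          f"{other} positions from mixture/artifact sources")
    print(table.groupby("label").size().to_string())


if __name__ == "__main__":
    main()
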