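#!/usr/bin/env python
"""Sample QC: completeness categories, mixture flags, kinship exclusion.

Writes results/qc.tsv. Expected outcome for this cohort: the 60X sample is
incomplete, the contaminated sample is flagged mixed, and exactly one
member of the maternal duplicate pair is excluded as related.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))

from cohort import RESULTS, SCRATCH, processed_results
from mitowgs.pipeline import classify_cohort, qc_cohort
from mitowgs.qc import KinshipTable


def main() -> None:
    results = processed_results()
    classify_cohort(results)  # fills residual PHP / NUMT counts
    kinship = KinshipTable.from_tsv(SCRATCH / "kinship.tsv")
    frame = qc_cohort(results, kinship)
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "qc.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    counts = frame.groupby("category").size()
    print("\ncategory counts:")
    print(counts.to_string())
    assert counts.sum() == len(frame)


if __name__ == "__main__":
    main()
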