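#!/usr/bin/env python
"""Classify the synthetic cohort with the modified DLCN criteria.

Reads scratch/cohort/ (running 01_simulate_cohort.py first if absent),
corrects LDL-C for treatment, scores, classifies, and reports class counts
and the definite-or-probable prevalence.
"""

import argparse
import subprocess
import sys
from pathlib import Path

import pandas as pd

from fhscreen.dlcn import CorrectionFactorMap, classify_cohort
from fhscreen.simulate import read_phenotypes
from fhscreen.stats import prevalence


def ensure_cohort(scratch: Path) -> None:
    if not (scratch / "phenotypes.tsv").exists():
        subprocess.run([sys.executable, "analysis/01_simulate_cohort.py",
                        "--scratch", str(scratch)], check=True)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scratch", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    ensure_cohort(args.scratch)

    phen = read_phenotypes(args.scratch / "phenotypes.tsv")
    factors = CorrectionFactorMap.from_table(args.scratch / "correction_factors.tsv")
    results, counts, excluded = classify_cohort(phen, factors)
    results.to_csv(args.scratch / "dlcn_results.tsv", sep="\t", index=False)

    n_inc = len(results)
    k = counts["definite"] + counts["probable"]
    prev = prevalence(k, n_inc)
    table = pd.DataFrame(
        [(c, n, round(100 * n / n_inc, 2)) for c, n in counts.items()],
        columns=["fh_class", "count", "percent"],
    )
    args.results.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.results / "dlcn_class_counts.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\nexcluded (missing LDL-C): {len(excluded)}")
    print(f"definite-or-probable prevalence: {prev}")


if __name__ == "__main__":
    main()
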