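#!/usr/bin/env python
"""LDL-C SNP scores and the bottom-quartile polygenic-inheritance assessment.

Computes the 11-SNP weighted allele score for every participant, compares
group means across FH classes (one-way ANOVA), and reports the fraction of
mutation-negative definite-or-probable individuals above the unlikely-FH
bottom quartile."""

import argparse
import json
import subprocess
import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from fhscreen.prs import compute_scores, load_weights, polygenic_assessment


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scratch", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    if not (args.scratch / "mutation_positive.tsv").exists():
        subprocess.run([sys.executable, "analysis/03_variant_carriers.py",
                        "--scratch", str(args.scratch)], check=True)

    weights = load_weights(args.scratch / "prs_weights.tsv")
    scores = compute_scores(args.scratch / "genotypes.vcf", weights)
    dlcn_results = pd.read_csv(args.scratch / "dlcn_results.tsv", sep="\t", dtype={"id": str})
    mut = pd.read_csv(args.scratch / "mutation_positive.tsv", sep="\t", dtype={"id": str})
    mut_pos = mut.set_index("id")["mutation_positive"].astype(bool)

    rep = polygenic_assessment(scores, dlcn_results, mut_pos)

    args.results.mkdir(parents=True, exist_ok=True)
    groups = pd.DataFrame([asdict(g) for g in rep["groups"].values()])
    groups.to_csv(args.results / "prs_groups.tsv", sep="\t", index=False)
    payload = {
        "bottom_quartile_threshold": rep["threshold"],
        "n_mutation_negative_definite_or_probable": rep["n_mutation_negative_cases"],
        "fraction_above_threshold": rep["fraction_above_threshold"],
        "anova_f": rep["anova_f"],
        "anova_p": rep["anova_p"],
    }
    (args.results / "polygenic.json").write_text(json.dumps(payload, indent=2))

    for g in rep["groups"].values():
        print(f"{g.label:>22}: n={g.n:5d}  score {g.mean:.3f} +/- {g.sd:.3f}")
    print(f"\nbottom-quartile threshold (unlikely FH): {rep['threshold']:.3f}")
    print(f"mutation-negative definite-or-probable above threshold: "
          f"{rep['fraction_above_threshold']:.0%} of {rep['n_mutation_negative_cases']}")
    print(f"one-way ANOVA: F={rep['anova_f']:.2f}, p={rep['anova_p']:.2e}")


if __name__ == "__main__":
    main()
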