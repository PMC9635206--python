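#!/usr/bin/env python
"""Genetic-epidemiology statistics over the classified cohort: carriage odds
ratios by FH class, comorbidity cross-tabs, and chi-square comparisons."""

import argparse
import json
import subprocess
import sys
from pathlib import Path

import pandas as pd

from fhscreen.simulate import read_phenotypes
from fhscreen.stats import (
    ContingencyTable2x2,
    chi_square_2x2,
    comorbidity_crosstab,
    odds_ratio_woolf,
)

FIELDS = ["obesity", "metabolic_syndrome", "diabetes", "hypertension",
          "smoker", "premature_cad"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scratch", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    if not (args.scratch / "mutation_positive.tsv").exists():
        subprocess.run([sys.executable, "analysis/03_variant_carriers.py",
                        "--scratch", str(args.scratch)], check=True)

    dlcn_results = pd.read_csv(args.scratch / "dlcn_results.tsv", sep="\t", dtype={"id": str})
    phen = read_phenotypes(args.scratch / "phenotypes.tsv")
    mut = pd.read_csv(args.scratch / "mutation_positive.tsv", sep="\t", dtype={"id": str})
    carrier = dlcn_results["id"].map(
        mut.set_index("id")["mutation_positive"].astype(bool)).fillna(False)
    classes = dlcn_results["fh_class"]

    args.results.mkdir(parents=True, exist_ok=True)

    # carriage odds ratios vs unlikely FH
    or_payload = {}
    for label, grp in (("definite_or_probable", ("definite", "probable")),
                       ("possible", ("possible",))):
        exp = classes.isin(grp)
        unexp = classes == "unlikely"
        t = ContingencyTable2x2(
            a=int((exp & carrier).sum()), b=int((exp & ~carrier).sum()),
            c=int((unexp & carrier).sum()), d=int((unexp & ~carrier).sum()))
        r = odds_ratio_woolf(t)
        or_payload[label] = {
            "table": [t.a, t.b, t.c, t.d], "odds_ratio": r.odds_ratio,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
            "haldane_corrected": r.haldane_corrected,
        }
        print(f"OR({label} vs unlikely) = {r.odds_ratio:.1f} "
              f"(95% CI {r.ci_low:.1f}-{r.ci_high:.1f})"
              + ("  [Haldane-corrected]" if r.haldane_corrected else ""))
    (args.results / "odds_ratios.json").write_text(json.dumps(or_payload, indent=2))

    # comorbidity cross-tab and chi-square, pooled cases vs unlikely
    ct = comorbidity_crosstab(dlcn_results, phen, FIELDS)
    ct.to_csv(args.results / "comorbidity_crosstab.tsv", sep="\t", index=False)
    print("\ncomorbidity (definite-or-probable vs unlikely, chi-square):")
    pooled = classes.isin(["definite", "probable"])
    unlikely = classes == "unlikely"
    merged = dlcn_results[["id"]].merge(phen, on="id")
    for f in FIELDS:
        flag = merged[f].astype(bool)
        t = ContingencyTable2x2(
            a=int((pooled & flag).sum()), b=int((pooled & ~flag).sum()),
            c=int((unlikely & flag).sum()), d=int((unlikely & ~flag).sum()))
        res = chi_square_2x2(t)
        pct_cases = ct[(ct["field"] == f) & (ct["fh_class"] == "definite_or_probable")
                       ]["percent"].iloc[0]
        pct_unl = ct[(ct["field"] == f) & (ct["fh_class"] == "unlikely")]["percent"].iloc[0]
        p_txt = f"p={res.p_value:.3g}" if res.defined else "p undefined (zero margin)"
        print(f"  {f:>22}: {pct_cases}% vs {pct_unl}%  ({p_txt})")


if __name__ == "__main__":
    main()
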