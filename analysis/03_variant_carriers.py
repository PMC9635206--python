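#!/usr/bin/env python
"""Carrier detection and estimated clinical penetrance of the planted variants.

Cross-references the cohort VCF against the annotation table, reports per-
variant zygosity/allele counts, and estimates penetrance from the DLCN
classes (dominant: all carriers; recessive: homozygotes only).
"""

import argparse
from pathlib import Path

import pandas as pd

from fhscreen.carriers import carrier_status, estimated_penetrance, load_annotations, mutation_positive


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scratch", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    from importlib import import_module
    import sys
    sys.path.insert(0, "analysis")
    import_module("02_dlcn_classification").ensure_cohort(args.scratch)
    if not (args.scratch / "dlcn_results.tsv").exists():
        import subprocess
        subprocess.run([sys.executable, "analysis/02_dlcn_classification.py",
                        "--scratch", str(args.scratch)], check=True)

    dlcn_results = pd.read_csv(args.scratch / "dlcn_results.tsv", sep="\t", dtype={"id": str})
    ann = load_annotations(args.scratch / "annotations.tsv")
    summaries = carrier_status(args.scratch / "genotypes.vcf", ann)

    rows = []
    for s in summaries:
        pen = estimated_penetrance(s, dlcn_results)
        rows.append({
            "variant": s.key, "gene": s.gene, "mode": s.mode,
            "classification": s.classification,
            "n_het": len(s.het_ids), "n_hom": len(s.hom_ids),
            "allele_count": s.allele_count,
            "allele_frequency": round(s.allele_frequency, 6),
            "penetrance": f"{round(100 * pen.value)}% ({pen.numerator}/{pen.denominator})"
            if pen.value is not None else "undefined (no informative carriers)",
        })
    table = pd.DataFrame(rows)
    args.results.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.results / "carrier_penetrance.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    mut = mutation_positive(dlcn_results["id"], summaries)
    mut.rename("mutation_positive").astype(int).to_csv(
        args.scratch / "mutation_positive.tsv", sep="\t")
    print(f"\nmutation-positive participants: {int(mut.sum())}")


if __name__ == "__main__":
    main()
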