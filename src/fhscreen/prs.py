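"""LDL-C SNP score (polygenic score) and polygenic-inheritance assessment.

The score is the raw weighted sum of LDL-C-raising allele dosages,
score_i = sum_j dosage_ij * beta_j, over an 11-SNP weight table (per-allele
betas in mmol/L). Missing genotypes are imputed as twice the cohort effect-
allele frequency (flagged), or dropped in strict mode. Strand-ambiguous
(A/T, C/G) SNPs are rejected at load time: silent strand flips are the
classic failure mode of allele-matched scores.

The polygenic-inheritance call follows the bottom-quartile rule: among
participants classified definite-or-probable FH who carry no known pathogenic
variant, those whose score exceeds the 25th percentile of the unlikely-FH
score distribution are called consistent with polygenic hypercholesterolemia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import one_way_anova

__all__ = [
    "AMBIGUOUS_PAIRS",
    "WEIGHT_COLUMNS",
    "load_weights",
    "validate_weights",
    "dosage",
    "compute_scores",
    "bottom_quartile_threshold",
    "polygenic_assessment",
]

AMBIGUOUS_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))
WEIGHT_COLUMNS = ["rsid", "chrom", "pos", "effect_allele", "other_allele", "beta"]


def validate_weights(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    if df["rsid"].duplicated().any():
        dups = df.loc[df["rsid"].duplicated(), "rsid"].tolist()
        raise ValueError(f"duplicate rsIDs in weight table: {dups}")
    for r in df.itertuples(index=False):
        ea, oa = str(r.effect_allele).upper(), str(r.other_allele).upper()
        if ea == oa:
            raise ValueError(f"{r.rsid}: effect and other allele identical ({ea})")
        if frozenset({ea, oa}) in AMBIGUOUS_PAIRS:
            raise ValueError(
                f"{r.rsid}: strand-ambiguous allele pair {ea}/{oa}; "
                "resolve strand before scoring"
            )
    return df


def load_weights(path) -> pd.DataFrame:
    """Tab-delimited weight table (rsid, chrom, pos, effect_allele,
    other_allele, beta), validated for uniqueness and strand ambiguity."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"chrom": str, "effect_allele": str, "other_allele": str},
    )
    return validate_weights(df)


def dosage(gt, effect_allele: str, ref: str, alt: str) -> int:
    """Effect-allele copy count in a diploid genotype at a biallelic site.

    ``gt`` is a "0/1"-style string or a pair of allele indices. The effect
    allele may be either REF or ALT; anything else is an annotation error.
    Returns -1 for a genotype containing a missing allele.
    """
    if effect_allele == alt:
        target = 1
    elif effect_allele == ref:
        target = 0
    else:
        raise ValueError(f"effect allele {effect_allele} matches neither {ref} nor {alt}")
    if isinstance(gt, str):
        alleles = [-1 if a == "." else int(a) for a in gt.replace("|", "/").split("/")]
    else:
        alleles = list(gt)
    if any(a < 0 for a in alleles):
        return -1
    return sum(1 for a in alleles if a == target)


def compute_scores(
    vcf_path,
    weights: pd.DataFrame,
    impute_missing: bool = True,
) -> pd.DataFrame:
    """Per-participant weighted allele scores from a VCF.

    Weight-table sites are matched by chrom/pos and allele pair; sites absent
    from the VCF are logged and skipped for everyone. Returns a DataFrame with
    columns id, score, n_missing_snps, imputed.
    """
    import logging

    from cyvcf2 import VCF

    logger = logging.getLogger(__name__)
    weights = validate_weights(weights)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    n = len(samples)

    sites = {
        (str(r.chrom), int(r.pos)): r for r in weights.itertuples(index=False)
    }
    score = np.zeros(n)
    n_missing = np.zeros(n, dtype=int)
    imputed = np.zeros(n, dtype=bool)
    seen = set()

    for v in vcf:
        r = sites.get((v.CHROM, v.POS))
        if r is None or len(v.ALT) != 1:
            continue
        alleles = {v.REF.upper(), v.ALT[0].upper()}
        if alleles != {str(r.effect_allele).upper(), str(r.other_allele).upper()}:
            continue
        seen.add(r.rsid)
        dos = np.array(
            [dosage(gt[:-1], str(r.effect_allele).upper(), v.REF.upper(), v.ALT[0].upper())
             for gt in v.genotypes],
            dtype=float,
        )
        miss = dos < 0
        if miss.any():
            n_missing += miss.astype(int)
            if impute_missing:
                ok = dos[~miss]
                af = ok.sum() / (2 * len(ok)) if len(ok) else 0.0
                dos[miss] = 2 * af
                imputed |= miss
            else:
                dos[miss] = 0.0
        score += dos * float(r.beta)

    for r in weights.itertuples(index=False):
        if r.rsid not in seen:
            logger.info("weight-table SNP %s not found in VCF; skipped for all samples", r.rsid)

    return pd.DataFrame(
        {"id": samples, "score": score, "n_missing_snps": n_missing, "imputed": imputed}
    )


def bottom_quartile_threshold(scores, q: float = 0.25) -> float:
    """Quantile of the unlikely-FH score distribution (linear interpolation
    between order statistics, the "type 7" convention)."""
    arr = np.asarray(scores, dtype=float)
    if arr.size < 4:
        raise ValueError(f"need at least 4 scores to set a quartile threshold, got {arr.size}")
    return float(np.quantile(arr, q, method="linear"))


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


def polygenic_assessment(
    scores: pd.DataFrame,
    dlcn_results: pd.DataFrame,
    mutation_positive: pd.Series,
    q: float = 0.25,
) -> dict:
    """Bottom-quartile polygenic-inheritance report.

    Inputs align by participant id. Reports the fraction of mutation-negative
    definite-or-probable participants above the unlikely-FH bottom-quartile
    threshold, group mean +/- SD for definite-or-probable / possible /
    unlikely, and the one-way ANOVA across those three groups. Empty groups
    are omitted with a notice.
    """
    df = scores[["id", "score"]].merge(dlcn_results[["id", "fh_class"]], on="id", how="inner")
    df["mutation_positive"] = df["id"].map(mutation_positive).fillna(False).astype(bool)

    group_of = {
        "definite": "definite_or_probable",
        "probable": "definite_or_probable",
        "possible": "possible",
        "unlikely": "unlikely",
    }
    df["group"] = df["fh_class"].map(group_of)

    unlikely_scores = df.loc[df["group"] == "unlikely", "score"]
    threshold = bottom_quartile_threshold(unlikely_scores, q=q)

    cases = df[(df["group"] == "definite_or_probable") & (~df["mutation_positive"])]
    n_cases = len(cases)
    frac_above = float((cases["score"] > threshold).mean()) if n_cases else None

    groups, notices = {}, []
    vectors = []
    for label in ("definite_or_probable", "possible", "unlikely"):
        vals = df.loc[df["group"] == label, "score"].to_numpy()
        if vals.size == 0:
            notices.append(f"group {label} is empty; omitted")
            continue
        groups[label] = GroupSummary(
            label=label, n=int(vals.size), mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        )
        if vals.size >= 2:
            vectors.append(vals)

    anova = one_way_anova(vectors) if len(vectors) >= 2 else (None, None)
    return {
        "threshold": threshold,
        "quantile": q,
        "n_mutation_negative_cases": n_cases,
        "fraction_above_threshold": frac_above,
        "groups": groups,
        "anova_f": anova[0],
        "anova_p": anova[1],
        "notices": notices,
    }
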