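"""Pathogenic-variant carrier detection and clinical-penetrance estimation.

A curated annotation table (ClinVar/HGMD-style) is cross-referenced against
cohort genotypes. For each annotated variant we report heterozygous and
homozygous carriers, the cohort allele count and frequency (missing genotypes
shrink the denominator), and the estimated clinical penetrance: the fraction
of carriers whose DLCN class is definite, probable, or possible. For
recessive-mode variants both numerator and denominator are restricted to
homozygotes — heterozygous carriers of a recessive allele are not expected to
express the phenotype.

Genes are mode-assigned by inheritance: LDLR/APOB/PCSK9 act dominantly,
LDLRAP1/ABCG5/ABCG8/LIPA recessively. Variant keys are chrom/pos/ref/alt with
1-based positions, normalized (left-aligned, minimal) before matching;
multi-allelic VCF records are split to biallelic keys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CarrierSummary",
    "PenetranceEstimate",
    "DOMINANT_GENES",
    "RECESSIVE_GENES",
    "PLP_CLASSES",
    "AFFECTED_CLASSES",
    "load_annotations",
    "normalize_variant",
    "variant_key",
    "carrier_status",
    "estimated_penetrance",
    "mutation_positive",
]

DOMINANT_GENES = frozenset({"LDLR", "APOB", "PCSK9"})
RECESSIVE_GENES = frozenset({"LDLRAP1", "ABCG5", "ABCG8", "LIPA"})

#: classifications counted as pathogenic/likely pathogenic
PLP_CLASSES = frozenset({"P", "LP", "P/LP"})

#: DLCN classes counted as affected for penetrance
AFFECTED_CLASSES = frozenset({"definite", "probable", "possible"})

ANNOTATION_COLUMNS = ["gene", "chrom", "pos", "ref", "alt", "mode", "classification"]


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal left-aligned representation of a variant allele pair."""
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    pos, ref, alt = normalize_variant(int(pos), ref, alt)
    return f"{chrom}:{pos}:{ref}:{alt}"


def load_annotations(path) -> pd.DataFrame:
    """Read and validate a tab-delimited pathogenicity annotation table.

    Required columns: gene, chrom, pos, ref, alt, mode, classification.
    Optional: rsid, cdna, protein, source, phenotype, max_af, subclusters.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    bad_mode = set(df["mode"]) - {"dominant", "recessive"}
    if bad_mode:
        raise ValueError(f"unknown inheritance mode(s): {sorted(bad_mode)}")
    for gene, mode in zip(df["gene"], df["mode"]):
        if gene in DOMINANT_GENES and mode != "dominant":
            raise ValueError(f"{gene} variants must be dominant-mode, got {mode!r}")
        if gene in RECESSIVE_GENES and mode != "recessive":
            raise ValueError(f"{gene} variants must be recessive-mode, got {mode!r}")
    df = df.copy()
    df["key"] = [
        variant_key(c, p, r, a)
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    dup = df["key"][df["key"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate variant key(s): {sorted(set(dup))}")
    return df


@dataclass(frozen=True)
class CarrierSummary:
    key: str
    gene: str
    mode: str
    classification: str
    het_ids: tuple[str, ...]
    hom_ids: tuple[str, ...]
    n_genotyped: int

    @property
    def allele_count(self) -> int:
        return len(self.het_ids) + 2 * len(self.hom_ids)

    @property
    def allele_frequency(self) -> float:
        return self.allele_count / (2 * self.n_genotyped) if self.n_genotyped else float("nan")

    @property
    def carrier_ids(self) -> tuple[str, ...]:
        return self.het_ids + self.hom_ids


def carrier_status(vcf_path, annotations: pd.DataFrame) -> list[CarrierSummary]:
    """Scan a VCF for the annotated variants and summarize carriers per variant.

    Multi-allelic records are split per ALT; genotypes containing a missing
    allele are excluded from the frequency denominator. Annotated variants not
    present in the VCF yield zero-carrier summaries (with a logged notice).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    found: dict[str, CarrierSummary] = {}
    wanted = {k: row for k, row in zip(annotations["key"], annotations.to_dict("records"))}

    for v in vcf:
        for ai, alt in enumerate(v.ALT, start=1):
            key = variant_key(v.CHROM, v.POS, v.REF, alt)
            row = wanted.get(key)
            if row is None:
                continue
            het, hom = [], []
            n_genotyped = 0
            for s, gt in zip(samples, v.genotypes):
                alleles = gt[:-1]  # last element is phasing flag
                if any(a < 0 for a in alleles):
                    continue
                n_genotyped += 1
                n_alt = sum(1 for a in alleles if a == ai)
                if n_alt == 1:
                    het.append(s)
                elif n_alt >= 2:
                    hom.append(s)
            found[key] = CarrierSummary(
                key=key, gene=row["gene"], mode=row["mode"],
                classification=row["classification"],
                het_ids=tuple(het), hom_ids=tuple(hom), n_genotyped=n_genotyped,
            )

    out = []
    n_total = len(samples)
    for key, row in wanted.items():
        if key in found:
            out.append(found[key])
        else:
            logger.info("annotated variant %s absent from VCF; zero-carrier summary", key)
            out.append(
                CarrierSummary(
                    key=key, gene=row["gene"], mode=row["mode"],
                    classification=row["classification"],
                    het_ids=(), hom_ids=(), n_genotyped=n_total,
                )
            )
    return out


@dataclass(frozen=True)
class PenetranceEstimate:
    numerator: int
    denominator: int

    @property
    def value(self) -> float | None:
        """Fraction affected, or None when no informative carriers exist."""
        return self.numerator / self.denominator if self.denominator else None


def estimated_penetrance(
    summary: CarrierSummary,
    dlcn_results: pd.DataFrame,
    mode: str | None = None,
) -> PenetranceEstimate:
    """Estimated clinical penetrance of one variant.

    Dominant: affected carriers (het or hom, DLCN class definite/probable/
    possible) over all carriers. Recessive: affected homozygotes over all
    homozygotes. Carriers missing from the DLCN results raise, since the
    phenotype definition requires a class for every carrier.
    """
    mode = mode or summary.mode
    ids = summary.carrier_ids if mode == "dominant" else summary.hom_ids
    if len(ids) == 0:
        return PenetranceEstimate(0, 0)
    classes = dlcn_results.set_index("id")["fh_class"]
    missing = [i for i in ids if i not in classes.index]
    if missing:
        raise KeyError(f"carriers without a DLCN class: {missing[:5]}")
    affected = sum(1 for i in ids if classes[i] in AFFECTED_CLASSES)
    return PenetranceEstimate(numerator=affected, denominator=len(ids))


def mutation_positive(
    sample_ids,
    summaries,
    gene_set=DOMINANT_GENES,
    classifications=PLP_CLASSES,
) -> pd.Series:
    """Per-participant flag: carries >= 1 P/LP variant in the gene set.

    For the dominant FH genes any zygosity counts. Returns a boolean Series
    indexed by participant id.
    """
    positive = set()
    for s in summaries:
        if s.gene in gene_set and s.classification in classifications:
            positive.update(s.carrier_ids)
    ids = list(sample_ids)
    return pd.Series([i in positive for i in ids], index=pd.Index(ids, name="id"), dtype=bool)
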