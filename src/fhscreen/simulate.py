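"""Synthetic biobank generator for FH screening.

Emulates an adult biobank cohort with the structure the downstream analysis
assumes: ~6,140 adults, 57% female, log-normal LDL-C with mild age/sex trends,
~13% on lipid-lowering therapy (a true 30% reduction masks their observed
LDL-C), rare dominant/recessive pathogenic variants planted in Hardy-Weinberg
proportions with per-variant penetrance and LDL effects, eleven common
LDL-raising SNPs feeding both the genotype VCF and the true LDL-C level, and
two structural-variant call sets from simulated "callers" observing the same
true events with breakpoint jitter and caller-specific noise.

Every downstream stage can therefore be tested end-to-end, with parameter
recovery checked against the emitted ground truth (``TrueStatus``). One master
seed spawns per-component substreams so adding a component does not perturb
the others; identical parameters and seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dlcn import CorrectionFactorMap, classify_cohort
from .sv import SVCall

__all__ = [
    "PlantedVariant",
    "PRSSnp",
    "SimulationParams",
    "CohortBundle",
    "SimulationParameterError",
    "simulate_cohort",
    "write_cohort",
    "read_phenotypes",
    "penetrant_case_probability",
    "DEFAULT_PLANTED_VARIANTS",
    "DEFAULT_PRS_SNPS",
    "DEFAULT_GENES",
    "PHENOTYPE_COLUMNS",
]


class SimulationParameterError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedVariant:
    """A rare variant planted into the cohort.

    ``allele_freq`` is the population allele frequency (genotypes are drawn in
    Hardy-Weinberg proportions); ``penetrance`` is the probability that a
    carrier (dominant mode) or homozygote (recessive mode) expresses the
    phenotype, i.e. has ``ldl_effect`` mmol/L added to the true LDL-C.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    mode: str  # dominant | recessive
    allele_freq: float
    penetrance: float
    ldl_effect: float
    classification: str = "P"
    rsid: str = "."

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class PRSSnp:
    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    allele_freq: float  # effect-allele frequency
    beta: float  # mmol/L per effect allele
    effect_is_alt: bool = True


# Planted defaults emulate the observed spectrum: a handful of rare dominant
# LDLR alleles with high-but-incomplete penetrance and large LDL effects, one
# zero-penetrance allele, and a recessive ABCG8 (sitosterolemia-like) allele.
DEFAULT_PLANTED_VARIANTS = (
    PlantedVariant("19", 11100236, "G", "A", "LDLR", "dominant", 0.0005, 0.83, 3.5, "P"),
    PlantedVariant("19", 11113600, "A", "G", "LDLR", "dominant", 0.00025, 0.67, 3.0, "P/LP"),
    PlantedVariant("19", 11120436, "T", "G", "LDLR", "dominant", 0.0001, 0.0, 0.0, "LP"),
    PlantedVariant("2", 43850000, "G", "A", "ABCG8", "recessive", 0.015, 1.0, 3.0, "P/LP"),
)

# Eleven LDL-raising SNPs (rsIDs from the 12-SNP LDL-C score literature, minus
# the HFE SNP). Frequencies and betas are illustrative, chosen so the raw
# weighted score has mean ~0.76 and SD ~0.18 in the general cohort.
DEFAULT_PRS_SNPS = (
    PRSSnp("rs2479409", "1", 55063556, "G", "A", 0.35, 0.12),
    PRSSnp("rs629301", "1", 109818306, "G", "T", 0.44, 0.11, effect_is_alt=False),
    PRSSnp("rs1367117", "2", 21263900, "A", "G", 0.50, 0.10),
    PRSSnp("rs4299376", "2", 44072576, "G", "T", 0.48, 0.09, effect_is_alt=False),
    PRSSnp("rs1564348", "6", 160578860, "C", "T", 0.48, 0.08),
    PRSSnp("rs3757354", "6", 16127407, "T", "C", 0.50, 0.07, effect_is_alt=False),
    PRSSnp("rs11220462", "11", 126243952, "A", "G", 0.46, 0.06),
    PRSSnp("rs8017377", "14", 24883887, "A", "G", 0.50, 0.06, effect_is_alt=False),
    PRSSnp("rs6511720", "19", 11202306, "G", "T", 0.50, 0.05),
    PRSSnp("rs429358", "19", 45411941, "C", "T", 0.46, 0.04),
    PRSSnp("rs7412", "19", 45412079, "C", "T", 0.50, 0.04, effect_is_alt=False),
)

# Gene spans (1-based inclusive) used for the BED output and SV disruption.
DEFAULT_GENES = pd.DataFrame(
    [
        ("PCSK9", "1", 55039548, 55064852),
        ("LDLRAP1", "1", 25542417, 25870070),
        ("APOB", "2", 21001429, 21044073),
        ("ABCG5", "2", 43812472, 43838865),
        ("ABCG8", "2", 43838905, 43878144),
        ("LDLR", "19", 11089363, 11133820),
    ],
    columns=["gene", "chrom", "start", "end"],
)

PHENOTYPE_COLUMNS = [
    "id", "age", "sex", "ldl_observed", "on_med", "med_class",
    "first_degree_cvd", "premature_cad", "premature_cerebro_peripheral",
    "self_reported_hc", "obesity", "metabolic_syndrome", "diabetes",
    "hypertension", "smoker", "parental_mi",
]

_BOOL_COLUMNS = PHENOTYPE_COLUMNS[6:] + ["on_med"]


@dataclass(frozen=True)
class SimulationParams:
    n_participants: int = 6140
    seed: int = 20120601
    age_range: tuple[int, int] = (18, 88)
    female_fraction: float = 0.569
    ldl_mean: float = float(np.log(2.9))  # log-scale mmol/L
    ldl_sd: float = 0.35
    treatment_fraction: float = 0.134
    true_treatment_reduction: float = 0.30
    planted_variants: tuple[PlantedVariant, ...] = DEFAULT_PLANTED_VARIANTS
    prs_snps: tuple[PRSSnp, ...] = DEFAULT_PRS_SNPS
    selfreport_noise: float = 0.02

    def validate(self) -> None:
        if self.n_participants < 0:
            raise SimulationParameterError("n_participants must be >= 0")
        for name in ("female_fraction", "treatment_fraction",
                     "true_treatment_reduction", "selfreport_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationParameterError(f"{name} must be in [0, 1], got {v}")
        if self.ldl_sd <= 0:
            raise SimulationParameterError("ldl_sd must be positive")
        lo, hi = self.age_range
        if not 0 < lo < hi:
            raise SimulationParameterError(f"invalid age_range {self.age_range}")
        for pv in self.planted_variants:
            if not 0.0 < pv.allele_freq <= 0.5:
                raise SimulationParameterError(
                    f"allele frequency must be in (0, 0.5], got {pv.allele_freq} for {pv.key}"
                )
            if not 0.0 <= pv.penetrance <= 1.0:
                raise SimulationParameterError(f"penetrance must be in [0, 1] for {pv.key}")
            if pv.mode not in ("dominant", "recessive"):
                raise SimulationParameterError(f"unknown mode {pv.mode!r} for {pv.key}")
        for s in self.prs_snps:
            if not 0.0 < s.allele_freq <= 0.5:
                raise SimulationParameterError(
                    f"allele frequency must be in (0, 0.5], got {s.allele_freq} for {s.rsid}"
                )


@dataclass
class CohortBundle:
    params: SimulationParams
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    sites: pd.DataFrame        # chrom, pos, rsid, ref, alt (one per VCF record)
    alt_dosage: np.ndarray     # n_sites x n_participants, int8 ALT-allele dosage
    prs_weights: pd.DataFrame
    annotations: pd.DataFrame
    sv_calls_a: list
    sv_calls_b: list
    genes: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return self.phenotypes["id"].tolist()


# ---------------------------------------------------------------------------
# generation internals

_STREAMS = ("age", "sex", "ldl", "prs", "planted", "penetrance",
            "treatment", "history", "noise", "sv")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _draw_ages(params: SimulationParams, n: int, rng) -> np.ndarray:
    lo, hi = params.age_range
    # right-skewed ages with median near 39 under the default 18-88 range
    return np.floor(lo + (hi - lo) * rng.beta(1.5, 3.3, size=n)).astype(int)


def _true_base_ldl(params, n, rng, age, female, prs_dev):
    mu = params.ldl_mean + 0.004 * (age - 40) - 0.04 * female
    base = np.exp(rng.normal(mu, params.ldl_sd, size=n))
    return np.maximum(base + prs_dev, 0.3)


def _observe(params, rng_treat, rng_hist, rng_noise, ids, age, female,
             true_ldl, any_penetrant) -> pd.DataFrame:
    n = len(ids)
    # treatment propensity rises with true LDL, normalized to the target rate
    if params.treatment_fraction > 0 and n > 0:
        w = np.exp(0.8 * np.clip(true_ldl - 3.5, 0, 6))
        p_treat = np.clip(params.treatment_fraction * w / w.mean(), 0, 0.95)
    else:
        p_treat = np.zeros(n)
    on_med = rng_treat.random(n) < p_treat
    observed = np.where(on_med, true_ldl * (1 - params.true_treatment_reduction), true_ldl)

    high = np.clip(true_ldl - 4.0, 0, None)
    parental_mi = rng_hist.random(n) < np.clip(0.13 + 0.20 * any_penetrant, 0, 0.9)
    sibling_mi = rng_hist.random(n) < 0.002
    first_degree = parental_mi | sibling_mi
    prem_cad = rng_hist.random(n) < np.clip(0.003 + 0.012 * high, 0, 0.6)
    prem_vasc = rng_hist.random(n) < np.clip(0.0008 + 0.002 * high, 0, 0.3)
    self_hc = rng_hist.random(n) < np.clip(0.20 + 0.55 * on_med + 0.15 * (true_ldl >= 4.0), 0, 0.98)
    obesity = rng_hist.random(n) < np.clip(0.40 + 0.003 * (age - 39), 0.05, 0.9)
    metsyn = rng_hist.random(n) < np.clip(0.10 + 0.005 * (age - 30), 0.01, 0.8)
    diabetes = rng_hist.random(n) < np.clip(0.02 + 0.008 * (age - 30), 0.005, 0.8)
    hypertension = rng_hist.random(n) < np.clip(0.02 + 0.008 * (age - 30), 0.005, 0.8)
    smoker = rng_hist.random(n) < np.where(female, 0.06, 0.30)

    # symmetric questionnaire misreport noise on self-reported fields
    def flip(x):
        return x ^ (rng_noise.random(n) < params.selfreport_noise)

    df = pd.DataFrame(
        {
            "id": ids,
            "age": age,
            "sex": np.where(female, "female", "male"),
            "ldl_observed": observed,
            "on_med": on_med,
            "med_class": np.where(on_med, "unspecified", ""),
            "first_degree_cvd": flip(first_degree),
            "premature_cad": flip(prem_cad),
            "premature_cerebro_peripheral": flip(prem_vasc),
            "self_reported_hc": flip(self_hc),
            "obesity": obesity,
            "metabolic_syndrome": metsyn,
            "diabetes": flip(diabetes),
            "hypertension": flip(hypertension),
            "smoker": flip(smoker),
            "parental_mi": flip(parental_mi),
        },
        columns=PHENOTYPE_COLUMNS,
    )
    return df


def simulate_cohort(params: SimulationParams) -> CohortBundle:
    """Generate phenotypes, genotypes, SV call sets, and ground truth."""
    params.validate()
    n = params.n_participants
    rngs = _rngs(params.seed)
    ids = [f"QS{i:06d}" for i in range(1, n + 1)]

    age = _draw_ages(params, n, rngs["age"])
    female = rngs["sex"].random(n) < params.female_fraction

    # PRS genotypes: effect-allele dosage in Hardy-Weinberg proportions
    n_snps = len(params.prs_snps)
    eff_dos = np.zeros((n_snps, n), dtype=np.int8)
    for j, s in enumerate(params.prs_snps):
        eff_dos[j] = rngs["prs"].binomial(2, s.allele_freq, size=n)
    betas = np.array([s.beta for s in params.prs_snps])
    expected = sum(2 * s.allele_freq * s.beta for s in params.prs_snps)
    prs_dev = betas @ eff_dos - expected if n_snps else np.zeros(n)

    # planted rare variants, HW proportions at the stated allele frequency
    n_pv = len(params.planted_variants)
    pv_gt = np.zeros((n_pv, n), dtype=np.int8)
    penetrant = np.zeros((n_pv, n), dtype=bool)
    for j, pv in enumerate(params.planted_variants):
        pv_gt[j] = rngs["planted"].binomial(2, pv.allele_freq, size=n)
        expressing = pv_gt[j] >= (1 if pv.mode == "dominant" else 2)
        penetrant[j] = expressing & (rngs["penetrance"].random(n) < pv.penetrance)
    any_penetrant = penetrant.any(axis=0) if n_pv else np.zeros(n, dtype=bool)
    planted_effect = np.zeros(n)
    for j, pv in enumerate(params.planted_variants):
        planted_effect += penetrant[j] * pv.ldl_effect

    true_ldl = _true_base_ldl(params, n, rngs["ldl"], age, female, prs_dev) + planted_effect

    phen = _observe(params, rngs["treatment"], rngs["history"], rngs["noise"],
                    ids, age, female, true_ldl, any_penetrant)

    truth = pd.DataFrame({"id": ids, "true_ldl": true_ldl})
    for j, pv in enumerate(params.planted_variants):
        truth[f"gt_{pv.key}"] = pv_gt[j]
        truth[f"penetrant_{pv.key}"] = penetrant[j]
    truth["any_penetrant"] = any_penetrant

    sites, alt_dosage = _site_table(params, eff_dos, pv_gt, n)
    prs_weights = pd.DataFrame(
        [
            {"rsid": s.rsid, "chrom": s.chrom, "pos": s.pos,
             "effect_allele": s.effect_allele, "other_allele": s.other_allele,
             "beta": s.beta}
            for s in params.prs_snps
        ],
        columns=["rsid", "chrom", "pos", "effect_allele", "other_allele", "beta"],
    )
    annotations = pd.DataFrame(
        [
            {"gene": pv.gene, "chrom": pv.chrom, "pos": pv.pos, "ref": pv.ref,
             "alt": pv.alt, "rsid": pv.rsid, "mode": pv.mode,
             "classification": pv.classification, "source": "synthetic",
             "phenotype": "Familial Hypercholesterolemia" if pv.mode == "dominant"
             else "Sitosterolemia"}
            for pv in params.planted_variants
        ],
        columns=["gene", "chrom", "pos", "ref", "alt", "rsid", "mode",
                 "classification", "source", "phenotype"],
    )

    sv_a, sv_b = _simulate_sv_calls(params, ids, rngs["sv"])

    return CohortBundle(
        params=params, phenotypes=phen, truth=truth, sites=sites,
        alt_dosage=alt_dosage, prs_weights=prs_weights, annotations=annotations,
        sv_calls_a=sv_a, sv_calls_b=sv_b, genes=DEFAULT_GENES.copy(),
    )


def _site_table(params, eff_dos, pv_gt, n):
    """Assemble the VCF site table + ALT-dosage matrix, sorted by position."""
    rows, mats = [], []
    for j, pv in enumerate(params.planted_variants):
        rows.append({"chrom": pv.chrom, "pos": pv.pos, "rsid": pv.rsid,
                     "ref": pv.ref, "alt": pv.alt})
        mats.append(pv_gt[j])
    for j, s in enumerate(params.prs_snps):
        if s.effect_is_alt:
            ref, alt, dos = s.other_allele, s.effect_allele, eff_dos[j]
        else:
            ref, alt, dos = s.effect_allele, s.other_allele, 2 - eff_dos[j]
        rows.append({"chrom": s.chrom, "pos": s.pos, "rsid": s.rsid, "ref": ref, "alt": alt})
        mats.append(dos.astype(np.int8))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "rsid", "ref", "alt"])
    mat = np.vstack(mats).astype(np.int8) if rows else np.zeros((0, n), dtype=np.int8)
    order = sorted(
        range(len(sites)),
        key=lambda i: (_chrom_rank(sites["chrom"][i]), int(sites["pos"][i])),
    )
    return sites.iloc[order].reset_index(drop=True), mat[order]


def _chrom_rank(chrom: str):
    c = str(chrom).removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


_SV_CHROM_SPAN = {"1": 240_000_000, "2": 240_000_000, "19": 58_000_000}

#: whole-PCSK9 duplication planted for the first sample (both callers see it)
PCSK9_DUP = ("1", 54_828_792, 55_862_308, "DUP")


def _simulate_sv_calls(params, ids, rng):
    """Two callers observing shared true events with jitter plus private noise.

    A fraction of samples carry 1-3 true events; each caller reports an event
    with breakpoint jitter (<=0.5% of length) and may miss it; each caller
    also emits private false-positive calls, including a few below 50 bp and
    above 10 Mb so downstream size filtering has work to do.
    """
    calls_a, calls_b = [], []
    if not ids:
        return calls_a, calls_b

    def jitter(start, end, scale):
        d = max(1, int(scale * (end - start + 1)))
        s = start + int(rng.integers(-d, d + 1))
        e = end + int(rng.integers(-d, d + 1))
        if e < s:
            s, e = e, s
        return max(1, s), max(2, e)

    chrom, s0, e0, t0 = PCSK9_DUP
    calls_a.append(SVCall(ids[0], chrom, s0, e0, t0, "caller_a"))
    js, je = jitter(s0, e0, 0.002)
    calls_b.append(SVCall(ids[0], chrom, js, je, t0, "caller_b"))

    carriers = [i for i in ids if rng.random() < 0.05]
    for sample in carriers:
        for _ in range(int(rng.integers(1, 4))):
            c = str(rng.choice(list(_SV_CHROM_SPAN)))
            length = int(10 ** rng.uniform(2.5, 4.5))
            start = int(rng.integers(1_000_000, _SV_CHROM_SPAN[c] - length))
            end = start + length - 1
            sv_type = str(rng.choice(["DEL", "DUP"]))
            if rng.random() > 0.05:
                s, e = jitter(start, end, 0.005)
                calls_a.append(SVCall(sample, c, s, e, sv_type, "caller_a"))
            if rng.random() > 0.10:
                s, e = jitter(start, end, 0.005)
                calls_b.append(SVCall(sample, c, s, e, sv_type, "caller_b"))

    for caller, out in (("caller_a", calls_a), ("caller_b", calls_b)):
        n_fp = rng.poisson(max(1, int(0.02 * len(ids))))
        for _ in range(n_fp):
            sample = str(rng.choice(ids))
            c = str(rng.choice(list(_SV_CHROM_SPAN)))
            length = int(10 ** rng.uniform(2.0, 5.0))
            start = int(rng.integers(1_000_000, _SV_CHROM_SPAN[c] - length))
            out.append(SVCall(sample, c, start, start + length - 1, "DEL", caller))
        for length in (30, 45, 12_000_000):  # outside the 50 bp - 10 Mb window
            sample = str(rng.choice(ids))
            start = int(rng.integers(1_000_000, 100_000_000))
            out.append(SVCall(sample, "1", start, start + length - 1, "DEL", caller))
    key = lambda c: (c.sample, c.chrom, c.start, c.end)
    return sorted(calls_a, key=key), sorted(calls_b, key=key)


def penetrant_case_probability(
    params: SimulationParams,
    variant: PlantedVariant,
    n_mc: int = 20_000,
    seed: int = 1,
    factors: CorrectionFactorMap | None = None,
) -> float:
    """Monte Carlo estimate of s = P(penetrant carrier is classified
    possible-or-worse) under the generative model.

    Fresh draws, independent of any realized cohort: hypothetical penetrant
    carriers of ``variant`` are pushed through the observation path (treatment
    masking, correction, DLCN scoring) and the fraction reaching class
    possible/probable/definite is returned. Used to calibrate the expected
    numerator of the penetrance estimator, Bin(k, penetrance * s).
    """
    rngs = _rngs(seed)
    ids = [f"MC{i:06d}" for i in range(n_mc)]
    age = _draw_ages(params, n_mc, rngs["age"])
    female = rngs["sex"].random(n_mc) < params.female_fraction
    sd_prs = np.sqrt(sum(2 * s.allele_freq * (1 - s.allele_freq) * s.beta**2
                         for s in params.prs_snps))
    prs_dev = rngs["prs"].normal(0, sd_prs, size=n_mc)
    true_ldl = _true_base_ldl(params, n_mc, rngs["ldl"], age, female, prs_dev)
    true_ldl = true_ldl + variant.ldl_effect
    phen = _observe(params, rngs["treatment"], rngs["history"], rngs["noise"],
                    ids, age, female, true_ldl, np.ones(n_mc, dtype=bool))
    results, counts, _ = classify_cohort(phen, factors or CorrectionFactorMap())
    affected = counts["definite"] + counts["probable"] + counts["possible"]
    return affected / n_mc


# ---------------------------------------------------------------------------
# serialization


def write_cohort(bundle: CohortBundle, out_dir) -> dict[str, str]:
    """Write the bundle as plain-text files; returns a path manifest.

    Files: phenotypes.tsv, genotypes.vcf (v4.2, GT-only), prs_weights.tsv,
    annotations.tsv, sv_caller_a.tsv, sv_caller_b.tsv, genes.bed (0-based
    half-open), correction_factors.tsv, true_status.tsv.
    """
    from pathlib import Path

    from .sv import write_sv_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}

    phen = bundle.phenotypes.copy()
    for col in _BOOL_COLUMNS:
        phen[col] = phen[col].astype(int)
    p = out / "phenotypes.tsv"
    phen.to_csv(p, sep="\t", index=False)
    manifest["phenotypes"] = str(p)

    p = out / "genotypes.vcf"
    _write_vcf(bundle, p)
    manifest["genotypes"] = str(p)

    p = out / "prs_weights.tsv"
    bundle.prs_weights.to_csv(p, sep="\t", index=False)
    manifest["prs_weights"] = str(p)

    p = out / "annotations.tsv"
    bundle.annotations.to_csv(p, sep="\t", index=False)
    manifest["annotations"] = str(p)

    for name, calls in (("sv_caller_a", bundle.sv_calls_a), ("sv_caller_b", bundle.sv_calls_b)):
        p = out / f"{name}.tsv"
        write_sv_table(calls, p)
        manifest[name] = str(p)

    p = out / "genes.bed"
    bed = bundle.genes.copy()
    bed["bed_start"] = bed["start"] - 1  # back to 0-based half-open
    bed[["chrom", "bed_start", "end", "gene"]].to_csv(p, sep="\t", index=False, header=False)
    manifest["genes"] = str(p)

    p = out / "correction_factors.tsv"
    pd.DataFrame({"med_class": ["unspecified"], "factor": [1.43]}).to_csv(p, sep="\t", index=False)
    manifest["correction_factors"] = str(p)

    p = out / "true_status.tsv"
    truth = bundle.truth.copy()
    for col in truth.columns:
        if truth[col].dtype == bool:
            truth[col] = truth[col].astype(int)
    truth.to_csv(p, sep="\t", index=False)
    manifest["true_status"] = str(p)

    return manifest


_GT_STRINGS = np.array(["0/0", "0/1", "1/1"])


def _write_vcf(bundle: CohortBundle, path) -> None:
    samples = bundle.sample_ids
    chroms = []
    for c in bundle.sites["chrom"]:
        if c not in chroms:
            chroms.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=fhscreen-simulator\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                 + ("\t" + "\t".join(samples) if samples else "") + "\n")
        for i, row in bundle.sites.iterrows():
            gts = _GT_STRINGS[bundle.alt_dosage[i]]
            fields = [str(row["chrom"]), str(row["pos"]), str(row["rsid"]),
                      row["ref"], row["alt"], ".", "PASS", ".", "GT"]
            fh.write("\t".join(fields) + ("\t" + "\t".join(gts) if samples else "") + "\n")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype table written by write_cohort (booleans as 0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "med_class": str})
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    df["med_class"] = df["med_class"].fillna("")
    return df[PHENOTYPE_COLUMNS]
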