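"""End-to-end orchestration: simulate/ingest -> DLCN -> carriers -> SV -> PRS -> stats.

Stages communicate through plain files under the output directory so each can
be re-run (and tested) in isolation; the final RunReport JSON aggregates every
stage's headline numbers together with provenance (config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import carriers as car
from . import dlcn as dl
from . import prs as pr
from . import simulate as sim
from . import stats as st
from . import sv as svmod

logger = logging.getLogger("fhscreen.pipeline")

__all__ = ["PipelineConfig", "PipelineConfigError", "run", "load_config"]


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 20120601
    simulate: dict | None = None      # SimulationParams overrides, or None
    inputs: dict = field(default_factory=dict)  # paths when not simulating
    definite_at_8: bool = False
    sv_overlap_threshold: float = 0.8
    sv_min_size: int = 50
    sv_max_size: int = 10_000_000
    prs_quantile: float = 0.25

    REQUIRED_INPUTS = ("phenotypes", "genotypes", "annotations", "prs_weights",
                       "sv_caller_a", "sv_caller_b", "genes")

    def validate(self) -> None:
        if self.simulate is None and not self.inputs:
            raise PipelineConfigError("config needs either a simulate block or input paths")
        if self.simulate is None:
            missing = [k for k in self.REQUIRED_INPUTS if k not in self.inputs]
            if missing:
                raise PipelineConfigError(f"missing input paths: {missing}")
            absent = [k for k in self.REQUIRED_INPUTS if not Path(self.inputs[k]).exists()]
            if absent:
                raise PipelineConfigError(f"input files not found: {absent}")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
    if "out_dir" not in raw:
        raise PipelineConfigError("config needs out_dir")
    return PipelineConfig(**raw)


def _stage_simulate(config: PipelineConfig, out: Path) -> dict:
    overrides = dict(config.simulate or {})
    overrides.setdefault("seed", config.seed)
    if "planted_variants" in overrides:
        overrides["planted_variants"] = tuple(
            sim.PlantedVariant(**pv) for pv in overrides["planted_variants"]
        )
    if "prs_snps" in overrides:
        overrides["prs_snps"] = tuple(sim.PRSSnp(**s) for s in overrides["prs_snps"])
    if "age_range" in overrides:
        overrides["age_range"] = tuple(overrides["age_range"])
    params = sim.SimulationParams(**overrides)
    bundle = sim.simulate_cohort(params)
    manifest = sim.write_cohort(bundle, out / "cohort")
    logger.info("[simulate] wrote %d participants to %s", params.n_participants, out / "cohort")
    return manifest


def run(config: PipelineConfig) -> dict:
    """Execute all stages; returns the RunReport (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = _stage_simulate(config, out) if config.simulate is not None else dict(config.inputs)

    # --- DLCN ---------------------------------------------------------------
    phen = sim.read_phenotypes(inputs["phenotypes"])
    if "correction_factors" in inputs:
        factors = dl.CorrectionFactorMap.from_table(inputs["correction_factors"])
    else:
        factors = dl.CorrectionFactorMap()
    dlcn_results, class_counts, excluded = dl.classify_cohort(
        phen, factors, definite_at_8=config.definite_at_8
    )
    dlcn_results.to_csv(out / "dlcn_results.tsv", sep="\t", index=False)
    logger.info("[dlcn] classes %s, %d excluded", class_counts, len(excluded))

    n_included = len(dlcn_results)
    k_case = class_counts["definite"] + class_counts["probable"]
    prev = st.prevalence(k_case, n_included) if n_included else None

    # --- carriers / penetrance ----------------------------------------------
    ann = car.load_annotations(inputs["annotations"])
    summaries = car.carrier_status(inputs["genotypes"], ann)
    carrier_rows = []
    for s in summaries:
        pen = car.estimated_penetrance(s, dlcn_results)
        carrier_rows.append(
            {
                "key": s.key, "gene": s.gene, "mode": s.mode,
                "classification": s.classification,
                "n_het": len(s.het_ids), "n_hom": len(s.hom_ids),
                "allele_count": s.allele_count,
                "allele_frequency": s.allele_frequency,
                "penetrance_numerator": pen.numerator,
                "penetrance_denominator": pen.denominator,
                "penetrance": pen.value if pen.value is not None else "",
            }
        )
    carrier_table = pd.DataFrame(carrier_rows)
    carrier_table.to_csv(out / "carriers.tsv", sep="\t", index=False)
    mut_pos = car.mutation_positive(dlcn_results["id"], summaries)
    mut_pos.rename("mutation_positive").astype(int).to_csv(out / "mutation_positive.tsv", sep="\t")
    logger.info("[carriers] %d annotated variants, %d mutation-positive participants",
                len(summaries), int(mut_pos.sum()))

    # --- SV consensus --------------------------------------------------------
    calls_a = svmod.size_filter(svmod.read_sv_table(inputs["sv_caller_a"], caller="caller_a"),
                                config.sv_min_size, config.sv_max_size)
    calls_b = svmod.size_filter(svmod.read_sv_table(inputs["sv_caller_b"], caller="caller_b"),
                                config.sv_min_size, config.sv_max_size)
    consensus = svmod.merge_callers(calls_a, calls_b, threshold=config.sv_overlap_threshold)
    svmod.write_sv_table([c.as_call() for c in consensus], out / "sv_consensus.tsv")
    multi = svmod.multi_sample_consensus(consensus, threshold=config.sv_overlap_threshold)
    multi.to_csv(out / "sv_multisample.tsv", sep="\t", index=False)
    genes = svmod.read_genes_bed(inputs["genes"])
    hits = svmod.gene_disruption(consensus, genes)
    hits.to_csv(out / "sv_gene_hits.tsv", sep="\t", index=False)
    logger.info("[sv-consensus] %d consensus calls, %d gene hits", len(consensus), len(hits))

    # --- PRS -----------------------------------------------------------------
    weights = pr.load_weights(inputs["prs_weights"])
    scores = pr.compute_scores(inputs["genotypes"], weights)
    scores.to_csv(out / "prs_scores.tsv", sep="\t", index=False)
    poly = pr.polygenic_assessment(scores, dlcn_results, mut_pos, q=config.prs_quantile)
    poly_json = {
        "threshold": poly["threshold"],
        "quantile": poly["quantile"],
        "n_mutation_negative_cases": poly["n_mutation_negative_cases"],
        "fraction_above_threshold": poly["fraction_above_threshold"],
        "groups": {k: asdict(v) for k, v in poly["groups"].items()},
        "anova_f": poly["anova_f"],
        "anova_p": poly["anova_p"],
        "notices": poly["notices"],
    }
    (out / "polygenic.json").write_text(json.dumps(poly_json, indent=2, sort_keys=True))
    logger.info("[prs] %d scores, polygenic fraction %s", len(scores),
                poly["fraction_above_threshold"])

    # --- statistics ----------------------------------------------------------
    stats_block = _stage_stats(dlcn_results, phen, mut_pos, class_counts)
    (out / "stats.json").write_text(json.dumps(stats_block, indent=2, sort_keys=True))

    report = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_included": n_included,
            "n_excluded": len(excluded),
        },
        "class_counts": class_counts,
        "prevalence_definite_or_probable": {
            "proportion": prev.proportion if prev else None,
            "one_in_n": prev.one_in_n if prev else None,
        },
        "carriers": carrier_rows,
        "sv": {"n_consensus": len(consensus), "n_multisample": len(multi),
               "gene_hits": int(len(hits))},
        "prs": poly_json,
        "stats": stats_block,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stage_stats(dlcn_results, phen, mut_pos, class_counts) -> dict:
    """Carriage odds ratios by class and comorbidity cross-tabs."""
    classes = dlcn_results.set_index("id")["fh_class"]
    carrier = mut_pos.reindex(classes.index).fillna(False)

    def table_vs_unlikely(group_classes) -> st.ContingencyTable2x2 | None:
        exp = classes.isin(group_classes)
        unexp = classes == "unlikely"
        t = st.ContingencyTable2x2(
            a=int((exp & carrier).sum()), b=int((exp & ~carrier).sum()),
            c=int((unexp & carrier).sum()), d=int((unexp & ~carrier).sum()),
        )
        return t

    out = {"odds_ratios": {}}
    for label, grp in (("definite_or_probable", ("definite", "probable")),
                       ("possible", ("possible",))):
        try:
            t = table_vs_unlikely(grp)
        except ValueError:
            continue
        orr = st.odds_ratio_woolf(t)
        out["odds_ratios"][label] = {
            "table": [t.a, t.b, t.c, t.d],
            "odds_ratio": orr.odds_ratio,
            "ci_low": orr.ci_low, "ci_high": orr.ci_high,
            "haldane_corrected": orr.haldane_corrected,
        }

    fields = ["obesity", "metabolic_syndrome", "diabetes", "hypertension",
              "smoker", "premature_cad"]
    ct = st.comorbidity_crosstab(dlcn_results, phen, fields)
    out["comorbidity"] = ct.to_dict(orient="records")

    chi = {}
    pooled = classes.isin(["definite", "probable"])
    unlikely = classes == "unlikely"
    merged = dlcn_results[["id"]].merge(phen, on="id")
    merged = merged.set_index("id").reindex(classes.index)
    for f in fields:
        flag = merged[f].astype(bool)
        t = st.ContingencyTable2x2(
            a=int((pooled & flag).sum()), b=int((pooled & ~flag).sum()),
            c=int((unlikely & flag).sum()), d=int((unlikely & ~flag).sum()),
        )
        res = st.chi_square_2x2(t)
        chi[f] = {"statistic": res.statistic, "p_value": res.p_value}
    out["chi_square_definite_or_probable_vs_unlikely"] = chi
    return out
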