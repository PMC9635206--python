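"""LDL-C SNP score computation and polygenic-inheritance assessment."""

import numpy as np
import pandas as pd
import pytest

from fhscreen.dlcn import classify_cohort
from fhscreen.prs import (
    bottom_quartile_threshold,
    compute_scores,
    dosage,
    load_weights,
    polygenic_assessment,
    validate_weights,
)


class TestDosage:
    @pytest.mark.parametrize(
        "gt,effect,expected",
        [
            ("0/1", "alt", 1),
            ("1/1", "ref", 0),
            ("0/0", "ref", 2),
            ("1/1", "alt", 2),
            ("0|1", "alt", 1),
        ],
    )
    def test_effect_allele_counting(self, gt, effect, expected):
        ref, alt = "G", "A"
        ea = alt if effect == "alt" else ref
        assert dosage(gt, ea, ref, alt) == expected

    def test_missing_genotype_flagged(self):
        assert dosage("./.", "A", "G", "A") == -1

    def test_unmatched_effect_allele_is_error(self):
        with pytest.raises(ValueError, match="neither"):
            dosage("0/1", "T", "G", "A")


def _weights(rows):
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "effect_allele",
                                       "other_allele", "beta"])


class TestWeightValidation:
    def test_strand_ambiguous_pair_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            validate_weights(_weights([("rs1", "1", 100, "A", "T", 0.1)]))
        with pytest.raises(ValueError, match="ambiguous"):
            validate_weights(_weights([("rs2", "1", 200, "C", "G", 0.1)]))

    def test_duplicate_rsid_rejected(self):
        rows = [("rs1", "1", 100, "G", "A", 0.1), ("rs1", "1", 200, "G", "A", 0.2)]
        with pytest.raises(ValueError, match="duplicate"):
            validate_weights(_weights(rows))

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            validate_weights(_weights([("rs1", "1", 100, "G", "G", 0.1)]))


class TestComputeScores:
    def test_all_reference_genotypes_score_zero(self, vcf_writer):
        vcf = vcf_writer(["a", "b"], [("1", 100, "rs1", "G", "A", ["0/0", "0/0"])])
        scores = compute_scores(vcf, _weights([("rs1", "1", 100, "A", "G", 0.5)]))
        assert (scores["score"] == 0.0).all()

    def test_single_snp_arithmetic(self, vcf_writer):
        vcf = vcf_writer(["a"], [("1", 100, "rs1", "G", "A", ["1/1"])])
        scores = compute_scores(vcf, _weights([("rs1", "1", 100, "A", "G", 0.1)]))
        assert scores["score"].iloc[0] == pytest.approx(0.2)

    def test_effect_allele_as_reference(self, vcf_writer):
        vcf = vcf_writer(["a"], [("1", 100, "rs1", "G", "A", ["0/0"])])
        scores = compute_scores(vcf, _weights([("rs1", "1", 100, "G", "A", 0.1)]))
        assert scores["score"].iloc[0] == pytest.approx(0.2)

    def test_absent_snp_skipped_for_everyone(self, vcf_writer):
        vcf = vcf_writer(["a"], [("1", 100, "rs1", "G", "A", ["1/1"])])
        wt = _weights([("rs1", "1", 100, "A", "G", 0.1),
                       ("rs_absent", "9", 999, "T", "C", 5.0)])
        scores = compute_scores(vcf, wt)
        assert scores["score"].iloc[0] == pytest.approx(0.2)

    def test_missing_genotype_imputed_as_2af(self, vcf_writer):
        gts = ["1/1", "0/1", "./."]
        vcf = vcf_writer(["a", "b", "c"], [("1", 100, "rs1", "G", "A", gts)])
        wt = _weights([("rs1", "1", 100, "A", "G", 1.0)])
        scores = compute_scores(vcf, wt)
        af = 3 / 4  # among the two genotyped samples
        c = scores.set_index("id").loc["c"]
        assert c["score"] == pytest.approx(2 * af)
        assert bool(c["imputed"]) and c["n_missing_snps"] == 1

    def test_strict_mode_drops_missing(self, vcf_writer):
        vcf = vcf_writer(["a", "b"], [("1", 100, "rs1", "G", "A", ["1/1", "./."])])
        wt = _weights([("rs1", "1", 100, "A", "G", 1.0)])
        scores = compute_scores(vcf, wt, impute_missing=False)
        assert scores.set_index("id").loc["b", "score"] == 0.0

    def test_linearity_and_permutation_invariance(self, small_bundle, cohort_manifest):
        wt = load_weights(cohort_manifest["prs_weights"])
        base = compute_scores(cohort_manifest["genotypes"], wt)
        doubled = wt.copy()
        doubled["beta"] = 2 * doubled["beta"]
        twice = compute_scores(cohort_manifest["genotypes"], doubled)
        assert np.allclose(twice["score"], 2 * base["score"])
        shuffled = compute_scores(cohort_manifest["genotypes"],
                                  wt.sample(frac=1, random_state=0).reset_index(drop=True))
        assert np.allclose(shuffled["score"], base["score"])

    def test_cohort_mean_matches_hwe_expectation(self, small_bundle, cohort_manifest):
        """Mean score within 3 SE of sum_i 2 f_i beta_i under HWE planting."""
        params = small_bundle.params
        expected = sum(2 * s.allele_freq * s.beta for s in params.prs_snps)
        wt = load_weights(cohort_manifest["prs_weights"])
        scores = compute_scores(cohort_manifest["genotypes"], wt)
        se = scores["score"].std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores["score"].mean() - expected) < 3 * se


class TestBottomQuartile:
    def test_linear_interpolation_example(self):
        assert bottom_quartile_threshold([0.4, 0.6, 0.8, 1.0]) == pytest.approx(0.55)

    def test_constant_scores(self):
        assert bottom_quartile_threshold([0.7] * 10) == pytest.approx(0.7)

    def test_lower_tail_mass(self):
        assert bottom_quartile_threshold([0, 0, 0, 100]) == pytest.approx(0.0)

    def test_too_few_scores_is_error(self):
        with pytest.raises(ValueError):
            bottom_quartile_threshold([0.1, 0.2, 0.3])

    def test_quarter_of_continuous_sample_at_or_below(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(0.76, 0.19, size=1000)
        thr = bottom_quartile_threshold(scores)
        frac = (scores <= thr).mean()
        assert abs(frac - 0.25) <= 2 / len(scores)


def _scores_frame(ids, values):
    return pd.DataFrame({"id": ids, "score": values})


def _classes_frame(ids, classes):
    return pd.DataFrame({"id": ids, "fh_class": classes})


class TestPolygenicAssessment:
    def test_all_cases_above_threshold(self):
        ids = [f"u{i}" for i in range(8)] + ["c1", "c2"]
        scores = _scores_frame(ids, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 2.0, 3.0])
        classes = _classes_frame(ids, ["unlikely"] * 8 + ["definite", "probable"])
        mut = pd.Series(False, index=pd.Index(ids, name="id"))
        rep = polygenic_assessment(scores, classes, mut)
        assert rep["fraction_above_threshold"] == 1.0

    def test_mutation_positive_cases_excluded_from_fraction(self):
        ids = [f"u{i}" for i in range(8)] + ["c1", "c2"]
        scores = _scores_frame(ids, [0.1] * 8 + [0.0, 3.0])
        classes = _classes_frame(ids, ["unlikely"] * 8 + ["definite", "definite"])
        mut = pd.Series([False] * 8 + [True, False], index=pd.Index(ids, name="id"))
        rep = polygenic_assessment(scores, classes, mut)
        assert rep["n_mutation_negative_cases"] == 1
        assert rep["fraction_above_threshold"] == 1.0  # only c2 counted

    def test_planted_group_shifts_recover_ordering(self):
        """Group means 0.87 / 0.82 / 0.76 (SD 0.16/0.16/0.19) at the cohort's
        group sizes 49/334/5757: estimated ordering is preserved and ANOVA is
        decisive."""
        rng = np.random.default_rng(2024)
        sizes = {"definite_or_probable": 49, "possible": 334, "unlikely": 5757}
        means = {"definite_or_probable": 0.87, "possible": 0.82, "unlikely": 0.76}
        sds = {"definite_or_probable": 0.16, "possible": 0.16, "unlikely": 0.19}
        ids, vals, classes = [], [], []
        for label, cls in [("definite_or_probable", "probable"),
                           ("possible", "possible"), ("unlikely", "unlikely")]:
            n = sizes[label]
            vals.extend(rng.normal(means[label], sds[label], size=n))
            ids.extend(f"{label}_{i}" for i in range(n))
            classes.extend([cls] * n)
        scores = _scores_frame(ids, vals)
        frame = _classes_frame(ids, classes)
        mut = pd.Series(False, index=pd.Index(ids, name="id"))
        rep = polygenic_assessment(scores, frame, mut)
        g = rep["groups"]
        assert g["definite_or_probable"].mean > g["possible"].mean > g["unlikely"].mean
        assert rep["anova_p"] < 0.01

    def test_empty_group_omitted_with_notice(self):
        ids = [f"u{i}" for i in range(8)]
        rep = polygenic_assessment(
            _scores_frame(ids, np.linspace(0, 1, 8)),
            _classes_frame(ids, ["unlikely"] * 8),
            pd.Series(False, index=pd.Index(ids, name="id")),
        )
        assert "definite_or_probable" not in rep["groups"]
        assert any("definite_or_probable" in n for n in rep["notices"])

    def test_full_synthetic_cohort_assessment(self, small_bundle, cohort_manifest):
        wt = load_weights(cohort_manifest["prs_weights"])
        scores = compute_scores(cohort_manifest["genotypes"], wt)
        dlcn_results, _, _ = classify_cohort(small_bundle.phenotypes)
        mut = pd.Series(False, index=pd.Index(dlcn_results["id"], name="id"))
        rep = polygenic_assessment(scores, dlcn_results, mut)
        assert 0.0 < rep["threshold"] < 1.5
        assert rep["groups"]["unlikely"].n > 0
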