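"""Prevalence, Woolf odds ratios, chi-square, and one-way ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fhscreen.stats import (
    ChiSquareResult,
    ContingencyTable2x2,
    chi_square_2x2,
    comorbidity_crosstab,
    odds_ratio_woolf,
    one_way_anova,
    prevalence,
    round_half_away,
)


class TestPrevalence:
    def test_definite_or_probable_cohort_figures(self):
        p = prevalence(49, 6140)
        assert p.proportion == pytest.approx(0.00798, abs=5e-5)
        assert p.one_in_n == 125

    def test_zero_cases_undefined_reciprocal(self):
        p = prevalence(0, 100)
        assert p.proportion == 0.0 and p.one_in_n is None

    def test_single_case(self):
        assert prevalence(1, 6140).one_in_n == 6140

    @pytest.mark.parametrize("k,n", [(1, 0), (-1, 10), (11, 10)])
    def test_domain_errors(self, k, n):
        with pytest.raises(ValueError):
            prevalence(k, n)


class TestOddsRatioWoolf:
    def test_reconstructed_ldlr_carriage_table(self):
        """6/43 carriers among definite-or-probable vs 4/5753 among unlikely."""
        r = odds_ratio_woolf(ContingencyTable2x2(6, 43, 4, 5753))
        assert round(r.odds_ratio) == 201
        assert round(r.ci_low) == 55
        assert abs(r.ci_high - 736.5) < 1.0

    def test_unit_table(self):
        assert odds_ratio_woolf(ContingencyTable2x2(1, 1, 1, 1)).odds_ratio == 1.0

    def test_small_table_against_hand_formula(self):
        r = odds_ratio_woolf(ContingencyTable2x2(2, 3, 5, 7))
        assert r.odds_ratio == pytest.approx(14 / 15)
        se = math.sqrt(1 / 2 + 1 / 3 + 1 / 5 + 1 / 7)
        z = 1.959963984540054
        assert r.ci_low == pytest.approx(math.exp(math.log(14 / 15) - z * se))
        assert r.ci_high == pytest.approx(math.exp(math.log(14 / 15) + z * se))

    def test_zero_cell_haldane_corrected_and_flagged(self):
        r = odds_ratio_woolf(ContingencyTable2x2(0, 10, 5, 10))
        assert r.haldane_corrected
        assert r.odds_ratio == pytest.approx((0.5 * 10.5) / (10.5 * 5.5))

    def test_exposure_swap_inverts_or(self):
        t = ContingencyTable2x2(8, 12, 3, 40)
        r = odds_ratio_woolf(t)
        swapped = odds_ratio_woolf(ContingencyTable2x2(3, 40, 8, 12))
        assert swapped.odds_ratio == pytest.approx(1 / r.odds_ratio)
        assert swapped.ci_low == pytest.approx(1 / r.ci_high)

    def test_simultaneous_row_column_swap_preserves_or(self):
        r = odds_ratio_woolf(ContingencyTable2x2(8, 12, 3, 40))
        # transpose swaps b and c; OR = ad/bc is unchanged
        t = odds_ratio_woolf(ContingencyTable2x2(8, 3, 12, 40))
        assert t.odds_ratio == pytest.approx(r.odds_ratio)

    def test_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import Table2x2

        rng = np.random.default_rng(7)
        for _ in range(20):
            cells = rng.integers(1, 100, size=4)
            t = ContingencyTable2x2(*map(int, cells))
            r = odds_ratio_woolf(t)
            sm = Table2x2(t.as_array())
            assert r.odds_ratio == pytest.approx(sm.oddsratio)
            lo, hi = sm.oddsratio_confint()
            assert r.ci_low == pytest.approx(lo) and r.ci_high == pytest.approx(hi)

    def test_woolf_ci_coverage_under_null(self):
        """2,000 simulated OR=1 tables (binomial, n=500/arm): the 95% CI covers
        1 in 94-96% of replicates."""
        rng = np.random.default_rng(0)
        n, p = 500, 0.3
        covered = 0
        for _ in range(2000):
            a = int(rng.binomial(n, p))
            c = int(rng.binomial(n, p))
            r = odds_ratio_woolf(ContingencyTable2x2(a, n - a, c, n - c))
            covered += r.ci_low <= 1.0 <= r.ci_high
        assert 0.94 <= covered / 2000 <= 0.96


def _brute_force_chi2(t: ContingencyTable2x2) -> float:
    obs = [[t.a, t.b], [t.c, t.d]]
    total = t.a + t.b + t.c + t.d
    rows = [t.a + t.b, t.c + t.d]
    cols = [t.a + t.c, t.b + t.d]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / total
            stat += (obs[i][j] - e) ** 2 / e
    return stat


class TestChiSquare:
    def test_identical_proportions(self):
        r = chi_square_2x2(ContingencyTable2x2(10, 90, 10, 90))
        assert r.statistic == pytest.approx(0.0) and r.p_value == pytest.approx(1.0)

    def test_premature_cad_table_significant(self):
        r = chi_square_2x2(ContingencyTable2x2(4, 45, 25, 5732))
        assert r.p_value < 0.01

    def test_matches_definitional_oracle_on_grid(self):
        grid = [1, 2, 3, 5, 10, 50]
        for cells in itertools.product(grid, repeat=4):
            t = ContingencyTable2x2(*cells)
            r = chi_square_2x2(t)
            assert r.statistic == pytest.approx(_brute_force_chi2(t), abs=1e-10)

    def test_zero_margin_undefined(self):
        r = chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))
        assert not r.defined

    def test_yates_correction_reduces_statistic(self):
        t = ContingencyTable2x2(4, 16, 12, 8)
        assert chi_square_2x2(t, yates=True).statistic < chi_square_2x2(t).statistic


def _definitional_anova(groups):
    grand = np.concatenate(groups).mean()
    k = len(groups)
    n = sum(len(g) for g in groups)
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestAnova:
    def test_identical_groups(self):
        f, p = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        f, _ = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert f == pytest.approx(13.5)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 30)).tolist()
                      for _ in range(rng.integers(2, 5))]
            f, _ = one_way_anova(groups)
            assert f == pytest.approx(_definitional_anova(groups), abs=1e-10)

    def test_constant_data_degenerate(self):
        f, p = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert f == 0.0 and p == 1.0

    def test_rejects_planted_group_shifts_in_most_replicates(self):
        """Means 0.87/0.82/0.76 (SD 0.16/0.16/0.19) at n=49/334/5757: ANOVA
        rejects at alpha=0.01 in >= 95% of 200 seeded replicates."""
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(200):
            groups = [rng.normal(0.87, 0.16, 49), rng.normal(0.82, 0.16, 334),
                      rng.normal(0.76, 0.19, 5757)]
            _, p = one_way_anova(groups)
            rejections += p < 0.01
        assert rejections / 200 >= 0.95


# Table-style comorbidity counts: definite/probable/possible/unlikely
_CLASS_SIZES = {"definite": 8, "probable": 41, "possible": 334, "unlikely": 5757}


def _cohort_with_counts(field, counts):
    """Build aligned dlcn/phenotype frames realizing per-class flag counts."""
    ids, classes, flags = [], [], []
    for cls, n in _CLASS_SIZES.items():
        k = counts[cls]
        for i in range(n):
            ids.append(f"{cls}_{i}")
            classes.append(cls)
            flags.append(i < k)
    dlcn = pd.DataFrame({"id": ids, "fh_class": classes})
    phen = pd.DataFrame({"id": ids, field: flags})
    return dlcn, phen


class TestComorbidityCrosstab:
    @pytest.mark.parametrize(
        "field,counts,pooled_pct,unlikely_pct",
        [
            ("premature_cad", {"definite": 0, "probable": 4, "possible": 21, "unlikely": 25}, 8, 0),
            ("metabolic_syndrome", {"definite": 4, "probable": 19, "possible": 122, "unlikely": 870}, 47, 15),
            ("hypertension", {"definite": 2, "probable": 13, "possible": 117, "unlikely": 855}, 31, 15),
            ("diabetes", {"definite": 3, "probable": 20, "possible": 112, "unlikely": 912}, 47, 16),
        ],
    )
    def test_pooled_percentages_match_reported_rounding(self, field, counts,
                                                        pooled_pct, unlikely_pct):
        dlcn, phen = _cohort_with_counts(field, counts)
        ct = comorbidity_crosstab(dlcn, phen, field)
        pooled = ct[ct["fh_class"] == "definite_or_probable"].iloc[0]
        assert pooled["percent"] == pooled_pct
        unlikely = ct[ct["fh_class"] == "unlikely"].iloc[0]
        assert unlikely["percent"] == unlikely_pct

    def test_all_false_flag(self):
        dlcn, phen = _cohort_with_counts(
            "smoker", {c: 0 for c in _CLASS_SIZES})
        ct = comorbidity_crosstab(dlcn, phen, "smoker")
        assert (ct["percent"] == 0).all()

    def test_unknown_field_is_error(self):
        dlcn, phen = _cohort_with_counts("smoker", {c: 0 for c in _CLASS_SIZES})
        with pytest.raises(KeyError):
            comorbidity_crosstab(dlcn, phen, "no_such_field")


@pytest.mark.parametrize("x,expected", [(0.5, 1), (1.5, 2), (-0.5, -1), (2.4, 2)])
def test_round_half_away(x, expected):
    assert round_half_away(x) == expected
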