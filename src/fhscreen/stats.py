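"""Genetic-epidemiology statistics: prevalence, odds ratios, chi-square, ANOVA.

Conventions match the screening report layer: Pearson chi-square without
continuity correction by default (Yates available), Woolf log-scale confidence
intervals for odds ratios with a Haldane-Anscombe +0.5 correction when a cell
is empty, and report percentages rounded half away from zero to integers
(raw proportions are always retained).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "PrevalenceEstimate",
    "ORResult",
    "ChiSquareResult",
    "prevalence",
    "odds_ratio_woolf",
    "chi_square_2x2",
    "one_way_anova",
    "comorbidity_crosstab",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (report parity)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cells: a = exposed case, b = exposed non-case, c = unexposed case,
    d = unexposed non-case."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class PrevalenceEstimate:
    k: int
    n: int
    proportion: float
    one_in_n: int | None  # None when k == 0 (undefined)

    def __str__(self) -> str:
        rec = f"1:{self.one_in_n}" if self.one_in_n is not None else "undefined"
        return f"{100 * self.proportion:.1f}% ({rec})"


def prevalence(k: int, n: int) -> PrevalenceEstimate:
    """Point prevalence k/n with the rounded one-in-N reciprocal."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    one_in_n = round_half_away(n / k) if k > 0 else None
    return PrevalenceEstimate(k=k, n=n, proportion=k / n, one_in_n=one_in_n)


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    alpha: float
    haldane_corrected: bool


def odds_ratio_woolf(t: ContingencyTable2x2, alpha: float = 0.05) -> ORResult:
    """Odds ratio (a*d)/(b*c) with the Woolf log-scale CI.

    exp(ln OR +/- z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d)). Tables with an
    empty cell get 0.5 added to every cell (Haldane-Anscombe) and are flagged.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    log_or = math.log(or_)
    return ORResult(
        odds_ratio=or_,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        alpha=alpha,
        haldane_corrected=corrected,
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float | None
    p_value: float | None

    @property
    def defined(self) -> bool:
        return self.statistic is not None


def chi_square_2x2(t: ContingencyTable2x2, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square (df=1) on a 2x2 table; undefined on a zero margin."""
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return ChiSquareResult(statistic=None, p_value=None)
    stat, p, _, _ = sps.chi2_contingency(arr, correction=yates)
    return ChiSquareResult(statistic=float(stat), p_value=float(p))


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across >= 2 groups of n >= 2 each."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs at least two observations")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0  # all observations identical: no signal either way
    f, p = sps.f_oneway(*arrays)
    if math.isnan(f):  # zero within-group variance with equal means
        return 0.0, 1.0
    return float(f), float(p)


_CLASS_ORDER = ("definite", "probable", "possible", "unlikely")


def comorbidity_crosstab(
    dlcn_results: pd.DataFrame,
    phenotypes: pd.DataFrame,
    fields,
) -> pd.DataFrame:
    """Per-FH-class counts and percentages of boolean phenotype flags.

    ``fields`` is one column name or a list of them. Emits one row per
    (field, class) plus a pooled "definite_or_probable" row per field, with
    the integer report percentage and the raw proportion.
    """
    if isinstance(fields, str):
        fields = [fields]
    for f in fields:
        if f not in phenotypes.columns:
            raise KeyError(f"unknown phenotype field {f!r}")

    merged = dlcn_results[["id", "fh_class"]].merge(
        phenotypes[["id", *fields]], on="id", how="inner"
    )
    rows = []
    for f in fields:
        flag = merged[f].astype(bool)
        for cls in _CLASS_ORDER:
            in_cls = merged["fh_class"] == cls
            n = int(in_cls.sum())
            k = int((in_cls & flag).sum())
            prop = k / n if n else float("nan")
            rows.append({"field": f, "fh_class": cls, "n_class": n, "count": k,
                         "proportion": prop,
                         "percent": round_half_away(100 * prop) if n else None})
        pooled = merged["fh_class"].isin(["definite", "probable"])
        n = int(pooled.sum())
        k = int((pooled & flag).sum())
        prop = k / n if n else float("nan")
        rows.append({"field": f, "fh_class": "definite_or_probable", "n_class": n,
                     "count": k, "proportion": prop,
                     "percent": round_half_away(100 * prop) if n else None})
    return pd.DataFrame(rows)
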