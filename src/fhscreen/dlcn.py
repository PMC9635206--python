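"""Modified Dutch Lipid Clinic Network (DLCN) scoring for biobank phenotypes.

The modified criteria use only questionnaire-derivable items plus LDL-C:

* first-degree relative with known coronary/vascular disease  — 1 point
* premature coronary artery disease in the participant        — 2 points
* premature cerebral or peripheral vascular disease           — 1 point
* pre-treatment LDL-C band (mmol/L): >=8.5 -> 8, [6.5,8.5) -> 5,
  [5.0,6.5) -> 3, [4.0,5.0) -> 1, else 0

so the total score lies in [0, 12]. Clinical-exam items of the full DLCN
(tendon xanthomas, corneal arcus) and the genetic-test item are deliberately
absent: biobank questionnaires do not capture them.

Participants on lipid-lowering medication have observed LDL-C multiplied by a
medication-class-specific correction factor to estimate the pre-treatment
level; 1.43 (a 30% reduction) is the default for unspecified medication.
Participants without an LDL-C measurement are excluded, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CorrectionFactorMap",
    "DLCNResult",
    "MissingLDLError",
    "classify",
    "classify_cohort",
    "correct_ldl",
    "dlcn_score",
    "factor_from_reduction",
    "ldl_points",
]

#: default multiplicative correction for unspecified lipid-lowering therapy
DEFAULT_UNSPECIFIED_FACTOR = 1.43

FH_CLASSES = ("definite", "probable", "possible", "unlikely")


class MissingLDLError(ValueError):
    """Raised when a participant lacks an LDL-C measurement (exclusion signal)."""


def factor_from_reduction(reduction: float) -> float:
    """Correction factor corresponding to a fractional LDL-C *reduction*.

    A therapy that lowers LDL-C by 30% implies observed = 0.7 x pre-treatment,
    so the factor restoring the pre-treatment level is 1/0.7 = 1.43.
    """
    if not 0.0 <= reduction < 1.0:
        raise ValueError(f"reduction must be in [0, 1), got {reduction}")
    return 1.0 / (1.0 - reduction)


@dataclass(frozen=True)
class CorrectionFactorMap:
    """Medication class -> multiplicative LDL-C correction factor (all >= 1)."""

    factors: dict[str, float] = field(default_factory=dict)
    default: float = DEFAULT_UNSPECIFIED_FACTOR

    def __post_init__(self) -> None:
        if self.default < 1.0:
            raise ValueError("default correction factor must be >= 1")
        for cls, f in self.factors.items():
            if f < 1.0:
                raise ValueError(f"correction factor for {cls!r} must be >= 1, got {f}")

    def factor(self, med_class: str | None) -> float:
        if med_class is None or med_class == "" or med_class == "unspecified":
            return self.factors.get("unspecified", self.default)
        return self.factors.get(med_class, self.default)

    @classmethod
    def from_table(cls, path) -> "CorrectionFactorMap":
        """Read a two-column delimited table (med_class, factor)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"med_class", "factor"} <= set(df.columns):
            raise ValueError("correction-factor table needs columns med_class, factor")
        factors = dict(zip(df["med_class"].astype(str), df["factor"].astype(float)))
        default = factors.get("unspecified", DEFAULT_UNSPECIFIED_FACTOR)
        return cls(factors=factors, default=default)


@dataclass(frozen=True)
class DLCNResult:
    id: str
    ldl_corrected: float
    points_family: int
    points_cad: int
    points_vascular: int
    points_ldl: int

    @property
    def score(self) -> int:
        return self.points_family + self.points_cad + self.points_vascular + self.points_ldl

    def fh_class(self, definite_at_8: bool = False) -> str:
        return classify(self.score, definite_at_8=definite_at_8)


def correct_ldl(
    observed: float | None,
    on_med: bool,
    med_class: str | None,
    factors: CorrectionFactorMap,
) -> float:
    """Estimate pre-treatment LDL-C from the observed (possibly treated) value."""
    if observed is None or (isinstance(observed, float) and math.isnan(observed)):
        raise MissingLDLError("participant lacks an LDL-C measurement")
    if observed < 0:
        raise ValueError(f"LDL-C cannot be negative, got {observed}")
    if not on_med:
        return float(observed)
    return float(observed) * factors.factor(med_class)


def ldl_points(ldl_corrected: float) -> int:
    """DLCN points for a pre-treatment LDL-C level (mmol/L).

    Bands are contiguous half-open intervals so no value falls in a gap:
    [8.5, inf) -> 8, [6.5, 8.5) -> 5, [5.0, 6.5) -> 3, [4.0, 5.0) -> 1, else 0.
    """
    if ldl_corrected < 0:
        raise ValueError(f"LDL-C cannot be negative, got {ldl_corrected}")
    if ldl_corrected >= 8.5:
        return 8
    if ldl_corrected >= 6.5:
        return 5
    if ldl_corrected >= 5.0:
        return 3
    if ldl_corrected >= 4.0:
        return 1
    return 0


def classify(score: int, definite_at_8: bool = False) -> str:
    """Map a DLCN score to an FH class.

    Default banding: definite > 8, probable 6-8, possible 3-5, unlikely < 3.
    ``definite_at_8`` moves the definite boundary down to score >= 8.
    """
    if not 0 <= score <= 12:
        raise ValueError(f"DLCN score must be in [0, 12], got {score}")
    definite_cut = 8 if definite_at_8 else 9
    if score >= definite_cut:
        return "definite"
    if score >= 6:
        return "probable"
    if score >= 3:
        return "possible"
    return "unlikely"


def dlcn_score(
    p,
    factors: CorrectionFactorMap,
) -> DLCNResult:
    """Score one participant (mapping/Series with the phenotype fields)."""
    ldl = correct_ldl(p["ldl_observed"], bool(p["on_med"]), p.get("med_class"), factors)
    return DLCNResult(
        id=str(p["id"]),
        ldl_corrected=ldl,
        points_family=1 if p["first_degree_cvd"] else 0,
        points_cad=2 if p["premature_cad"] else 0,
        points_vascular=1 if p["premature_cerebro_peripheral"] else 0,
        points_ldl=ldl_points(ldl),
    )


def classify_cohort(
    phenotypes: pd.DataFrame,
    factors: CorrectionFactorMap | None = None,
    definite_at_8: bool = False,
) -> tuple[pd.DataFrame, dict[str, int], list[str]]:
    """Score every participant; exclude rows lacking LDL-C.

    Returns (per-participant results, class counts, excluded ids). Class counts
    cover the four classes and sum to the number of included participants.
    """
    factors = factors or CorrectionFactorMap()
    if len(phenotypes) == 0:
        empty = pd.DataFrame(
            columns=["id", "ldl_corrected", "points_family", "points_cad",
                     "points_vascular", "points_ldl", "score", "fh_class"]
        )
        return empty, {c: 0 for c in FH_CLASSES}, []

    df = phenotypes.reset_index(drop=True)
    missing = df["ldl_observed"].isna()
    excluded = df.loc[missing, "id"].astype(str).tolist()
    kept = df.loc[~missing]

    med_class = kept["med_class"] if "med_class" in kept else pd.Series(None, index=kept.index)
    fac = med_class.map(lambda c: factors.factor(None if pd.isna(c) else str(c)))
    ldl = kept["ldl_observed"].astype(float).where(~kept["on_med"].astype(bool),
                                                  kept["ldl_observed"].astype(float) * fac)
    if (ldl < 0).any():
        raise ValueError("negative LDL-C in phenotype table")

    pts_ldl = np.select([ldl >= 8.5, ldl >= 6.5, ldl >= 5.0, ldl >= 4.0], [8, 5, 3, 1], 0)
    pts_family = kept["first_degree_cvd"].astype(bool).astype(int).to_numpy()
    pts_cad = 2 * kept["premature_cad"].astype(bool).astype(int).to_numpy()
    pts_vasc = kept["premature_cerebro_peripheral"].astype(bool).astype(int).to_numpy()
    score = pts_family + pts_cad + pts_vasc + pts_ldl

    definite_cut = 8 if definite_at_8 else 9
    fh_class = np.select(
        [score >= definite_cut, score >= 6, score >= 3], ["definite", "probable", "possible"], "unlikely"
    )
    results = pd.DataFrame(
        {
            "id": kept["id"].astype(str).to_numpy(),
            "ldl_corrected": ldl.to_numpy(),
            "points_family": pts_family,
            "points_cad": pts_cad,
            "points_vascular": pts_vasc,
            "points_ldl": pts_ldl,
            "score": score,
            "fh_class": fh_class,
        }
    )
    counts = {c: int((results["fh_class"] == c).sum()) for c in FH_CLASSES}
    return results, counts, excluded
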