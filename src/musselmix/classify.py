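"""Purebred/hybrid classification and its performance evaluation.

Two classifiers are provided.  The direct allele-count rule assigns
individuals by their T-score: 0-1 to ME, 7-8 to MT, 2-6 to hybrids
(defined for four fully scored loci).  The ancestry-score rule assigns by
the admixture ISS with two thresholds (lower: ME/hybrid, upper:
hybrid/MT) calibrated on simulated individuals of known ancestry so as to
reach a nominal efficiency — 95% or 90% for the purebred classes, or 95%
or 90% for the compound hybrid class.  Classifier quality is summarised
per class by efficiency (recall), accuracy (precision) and the overall
performance (mean efficiency x mean accuracy over the three classes); the
criterion with the best overall performance on the calibration data is
the one used for empirical assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ThresholdRule", "PerformanceReport", "classify_by_tscore",
           "performance", "calibrate_thresholds", "select_best_criterion",
           "classify_by_iss", "CRITERIA"]

CLASSES = ("ME", "MT", "HYBRID")

#: criterion id -> (targeted classes, nominal efficiency %)
CRITERIA = {
    "pure95": ("pure", 95.0),
    "hyb95": ("hybrid", 95.0),
    "pure90": ("pure", 90.0),
    "hyb90": ("hybrid", 90.0),
}


class InfeasibleCriterionError(ValueError):
    """Calibration produced lower >= upper."""


@dataclass(frozen=True)
class ThresholdRule:
    """ISS thresholds: <= lower -> ME, >= upper -> MT, else HYBRID."""

    lower: float
    upper: float
    criterion_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.lower < self.upper <= 1):
            raise InfeasibleCriterionError(
                f"need 0 <= lower < upper <= 1, got ({self.lower}, {self.upper})")


@dataclass
class PerformanceReport:
    """Per-class efficiency/accuracy and overall performance."""

    efficiency: dict[str, float]
    accuracy: dict[str, float]
    overall: float

    def as_row(self) -> dict:
        row = {f"eff_{c}": self.efficiency[c] for c in CLASSES}
        row.update({f"acc_{c}": self.accuracy[c] for c in CLASSES})
        row["overall"] = self.overall
        return row


def classify_by_tscore(scores: pd.DataFrame, min_loci: int = 4) -> pd.Series:
    """Compound class from the T-score table of :func:`~musselmix.genotypes.t_score`.

    Individuals scored at fewer than *min_loci* loci are left unclassified
    (NaN): the 0-8 score bands are defined for four complete loci and are
    not rescaled.
    """
    def one(row):
        if row["n_loci_scored"] < min_loci:
            return np.nan
        t = row["t_score"]
        if t <= 1:
            return "ME"
        if t >= 7:
            return "MT"
        return "HYBRID"

    out = scores.apply(one, axis=1)
    out.name = "class_tscore"
    return out


def performance(true_labels, predicted) -> PerformanceReport:
    """Efficiency/accuracy per compound class from the 3x3 confusion table.

    Efficiency of class c = P(predicted c | true c); accuracy of class c =
    P(true c | predicted c).  A class never predicted has undefined
    accuracy and enters the mean as 1 with a warning (no wrong assignment
    was made to it).  Overall = mean efficiency x mean accuracy.
    """
    t = pd.Series(list(true_labels))
    p = pd.Series(list(predicted))
    if len(t) != len(p):
        raise ValueError("label vectors differ in length")
    missing = set(CLASSES) - set(t)
    if missing:
        raise ValueError(f"truth lacks classes {sorted(missing)}")
    conf = pd.crosstab(t, p).reindex(index=CLASSES, columns=CLASSES, fill_value=0)
    eff, acc = {}, {}
    for c in CLASSES:
        eff[c] = conf.loc[c, c] / conf.loc[c].sum()
        denom = conf[c].sum()
        if denom == 0:
            warnings.warn(f"class {c} never predicted; accuracy treated as 1")
            acc[c] = 1.0
        else:
            acc[c] = conf.loc[c, c] / denom
    overall = float(np.mean(list(eff.values())) * np.mean(list(acc.values())))
    return PerformanceReport(eff, acc, overall)


def calibrate_thresholds(iss_labeled: pd.DataFrame, criterion: str) -> ThresholdRule:
    """Derive ISS thresholds reaching a nominal efficiency on labeled
    calibration data.

    *iss_labeled* needs columns ``iss`` and ``compound`` (ME/MT/HYBRID).
    Purebred criteria place the lower threshold at the e-th percentile of
    true-ME ISS and the upper at the (100-e)-th percentile of true-MT ISS
    (e = 95 or 90).  Hybrid criteria split the complement symmetrically:
    thresholds at the ((100-e)/2)-th and (100-(100-e)/2)-th percentiles of
    true-hybrid ISS.  Percentiles use linear interpolation between order
    statistics.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    target, e = CRITERIA[criterion]
    groups = {c: iss_labeled.loc[iss_labeled["compound"] == c, "iss"].to_numpy()
              for c in CLASSES}
    empty = [c for c, v in groups.items() if len(v) == 0]
    if empty:
        raise ValueError(f"calibration data lacks classes {empty}")
    if target == "pure":
        lower = float(np.percentile(groups["ME"], e))
        upper = float(np.percentile(groups["MT"], 100 - e))
    else:
        tail = (100 - e) / 2
        lower = float(np.percentile(groups["HYBRID"], tail))
        upper = float(np.percentile(groups["HYBRID"], 100 - tail))
    if lower >= upper:
        raise InfeasibleCriterionError(
            f"criterion {criterion} infeasible: lower {lower:.3f} >= upper {upper:.3f}")
    return ThresholdRule(lower, upper, criterion)


def classify_by_iss(iss, rule: ThresholdRule):
    """Compound class from ISS: boundaries are inclusive toward the
    purebred classes (iss <= lower -> ME, iss >= upper -> MT)."""
    scalar = np.isscalar(iss)
    x = np.atleast_1d(np.asarray(iss, dtype=float))
    if ((x < 0) | (x > 1)).any():
        raise ValueError("ISS must lie in [0, 1]")
    out = np.where(x <= rule.lower, "ME", np.where(x >= rule.upper, "MT", "HYBRID"))
    if scalar:
        return str(out[0])
    if isinstance(iss, pd.Series):
        return pd.Series(out, index=iss.index, name="class_iss")
    return out


def select_best_criterion(
    iss_labeled: pd.DataFrame,
    criteria: tuple[str, ...] = tuple(CRITERIA),
) -> tuple[ThresholdRule, dict[str, PerformanceReport]]:
    """Calibrate every criterion on the labeled ISS, score each by
    re-classifying the calibration data, and return the rule with the
    best overall performance (ties broken by higher hybrid efficiency)
    together with the full report table."""
    reports: dict[str, PerformanceReport] = {}
    rules: dict[str, ThresholdRule] = {}
    for crit in criteria:
        try:
            rule = calibrate_thresholds(iss_labeled, crit)
        except InfeasibleCriterionError as err:
            warnings.warn(str(err))
            continue
        pred = classify_by_iss(iss_labeled["iss"], rule)
        reports[crit] = performance(iss_labeled["compound"], pred)
        rules[crit] = rule
    if not rules:
        raise InfeasibleCriterionError("all criteria infeasible")
    best = max(
        rules,
        key=lambda c: (reports[c].overall, reports[c].efficiency["HYBRID"]),
    )
    ties = [c for c in rules if c != best and reports[c].overall == reports[best].overall]
    if ties:
        warnings.warn(f"overall-performance tie between {best} and {ties}; "
                      "resolved by hybrid efficiency")
    return rules[best], reports
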