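"""Threshold and discrimination analysis for the KM index.

Confusion matrices at a cut-off, ROC curves with the Mann-Whitney AUC
identity, univariate correlation tables against midline shift, and
risk-class outcome tables. Thresholding is strict ``>`` throughout (an
index *above* the cut-off predicts a shift), switchable to ``>=``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .calibration import DegenerateInputError, pearson_r
from .cohort import Cohort
from .core import (
    DEFAULT_PARAMS,
    IndexParams,
    RiskClass,
    ValidationError,
    km_index,
    time_factor,
    weighting_factor_n,
)

__all__ = [
    "ThresholdReport",
    "RiskTable",
    "confusion_at_threshold",
    "auc_mann_whitney",
    "roc_curve",
    "threshold_sweep",
    "optimal_threshold",
    "univariate_table",
    "risk_table",
    "cohort_indices",
]


@dataclass(frozen=True)
class ThresholdReport:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def _validate_binary(values, flags):
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if values.shape != flags.shape or values.ndim != 1:
        raise ValidationError(
            f"values and flags must be equal-length 1-D, got {values.shape} and {flags.shape}"
        )
    if not flags.any():
        raise ValidationError("no positive cases: sensitivity undefined")
    if flags.all():
        raise ValidationError("no negative cases: specificity undefined")
    return values, flags


def confusion_at_threshold(
    values, flags, threshold: float, *, strict: bool = True
) -> ThresholdReport:
    """Confusion counts for predicting the outcome where index > threshold."""
    values, flags = _validate_binary(values, flags)
    predicted = values > threshold if strict else values >= threshold
    tp = int((predicted & flags).sum())
    fp = int((predicted & ~flags).sum())
    fn = int((~predicted & flags).sum())
    tn = int((~predicted & ~flags).sum())
    return ThresholdReport(threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn)


def auc_mann_whitney(values, flags) -> tuple[float, float, float]:
    """AUC via the Mann-Whitney U statistic: AUC = U / (n_pos * n_neg).

    Ties count one half. The p-value uses the normal approximation with
    continuity and tie correction. Returns (auc, U, p).
    """
    values, flags = _validate_binary(values, flags)
    pos = values[flags]
    neg = values[~flags]
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    u = float(res.statistic)
    auc = u / (pos.size * neg.size)
    return auc, u, float(res.pvalue)


def roc_curve(values, flags) -> tuple[np.ndarray, np.ndarray]:
    """ROC staircase from (0, 0) to (1, 1); trapezoidal area equals the
    Mann-Whitney AUC."""
    values, flags = _validate_binary(values, flags)
    fpr, tpr, _ = _sk_roc_curve(flags.astype(int), values, drop_intermediate=False)
    return fpr, tpr


def threshold_sweep(values, flags, *, strict: bool = True) -> pd.DataFrame:
    """Confusion report at every distinct observed index value."""
    values, flags = _validate_binary(values, flags)
    rows = []
    for thr in np.unique(values):
        rep = confusion_at_threshold(values, flags, float(thr), strict=strict)
        rows.append(
            {
                "threshold": rep.threshold,
                "tp": rep.tp, "fp": rep.fp, "tn": rep.tn, "fn": rep.fn,
                "sensitivity": rep.sensitivity, "specificity": rep.specificity,
                "youden_j": rep.sensitivity + rep.specificity - 1.0,
            }
        )
    return pd.DataFrame(rows)


def optimal_threshold(
    values, flags, *, selector: str = "youden", min_sensitivity: float = 0.9
) -> ThresholdReport:
    """Pick a cut-off from the sweep.

    ``selector="youden"`` maximizes sensitivity + specificity - 1;
    ``selector="sensitivity_first"`` takes the most specific threshold whose
    sensitivity still reaches ``min_sensitivity`` (screening-test logic).
    """
    sweep = threshold_sweep(values, flags)
    if selector == "youden":
        best = sweep.loc[sweep["youden_j"].idxmax()]
    elif selector == "sensitivity_first":
        eligible = sweep[sweep["sensitivity"] >= min_sensitivity]
        if eligible.empty:
            raise ValidationError(f"no threshold reaches sensitivity {min_sensitivity}")
        best = eligible.loc[eligible["specificity"].idxmax()]
    else:
        raise ValidationError(f"unknown selector {selector!r}")
    return confusion_at_threshold(values, flags, float(best["threshold"]))


def cohort_indices(cohort: Cohort, params: IndexParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Per-patient KM index, score and risk class as a tidy table."""
    rows = []
    for p in cohort:
        res = km_index(p.volumes, p.treatment, params)
        rows.append(
            {
                "id": p.id,
                "km_index": res.index,
                "km_score": res.score,
                "risk_class": res.risk_class.value,
                "n": res.components["n"],
                "mls_max_mm": p.mls_max_mm,
                "dhc": p.dhc,
                "death_7d": p.death_7d,
            }
        )
    return pd.DataFrame(rows)


_FACTORS = {
    "P": lambda p, params: p.volumes.v_penumbra / p.volumes.v_mip,
    "I": lambda p, params: p.volumes.v_core / p.volumes.v_mip,
    "MTT/MIP": lambda p, params: p.volumes.v_mtt / p.volumes.v_mip,
    "lysis": lambda p, params: float(p.treatment.rtpa),
    "n_without_lysis": lambda p, params: weighting_factor_n(
        dataclasses.replace(p.treatment, rtpa=False), params
    ),
    "n_with_lysis": lambda p, params: weighting_factor_n(p.treatment, params),
    "t": lambda p, params: float(time_factor(p.treatment.onset_to_groin_hours)),
}


def univariate_table(
    cohort: Cohort,
    factors: "list[str] | dict | None" = None,
    params: IndexParams = DEFAULT_PARAMS,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-factor Pearson correlation with maximum midline shift.

    The regression line is reported in the orientation factor = intercept +
    slope * MLS. Factors with p > alpha are marked not significant; constant
    factors are marked degenerate instead of failing. ``factors`` may be a
    list of built-in factor names or a mapping name -> callable(patient,
    params) for custom covariates.
    """
    if factors is None:
        table = dict(_FACTORS)
    elif isinstance(factors, dict):
        table = factors
    else:
        unknown = [n for n in factors if n not in _FACTORS]
        if unknown:
            raise ValidationError(f"unknown factors {unknown}; choose from {list(_FACTORS)}")
        table = {n: _FACTORS[n] for n in factors}
    mls = np.array([0.0 if p.mls_max_mm is None else p.mls_max_mm for p in cohort], dtype=float)
    rows = []
    for name, fn in table.items():
        x = np.array([fn(p, params) for p in cohort], dtype=float)
        try:
            r, p_val = pearson_r(x, mls)
        except DegenerateInputError:
            rows.append(
                {"factor": name, "r": np.nan, "intercept": np.nan, "slope": np.nan,
                 "p": np.nan, "significant": "NS", "note": "degenerate (constant factor)"}
            )
            continue
        slope, intercept = np.polyfit(mls, x, 1)
        rows.append(
            {"factor": name, "r": r, "intercept": float(intercept), "slope": float(slope),
             "p": p_val, "significant": "NS" if p_val > alpha else f"p<{alpha}", "note": ""}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RiskTable:
    """Outcome counts and rates per risk class."""

    table: pd.DataFrame


def risk_table(
    cohort: Cohort,
    params: IndexParams = DEFAULT_PARAMS,
    *,
    mls_threshold_mm: float = 0.0,
) -> RiskTable:
    """Per-risk-class counts and rates of midline shift, decompressive
    hemicraniectomy and death within 7 days.

    A midline shift counts when ``mls_max_mm > mls_threshold_mm`` was
    recorded on follow-up. Empty classes report ``0/0`` rates as None with
    an explicit marker rather than NaN.
    """
    idx = cohort_indices(cohort, params)
    rows = []
    for cls in RiskClass:
        sub = idx[idx["risk_class"] == cls.value]
        n = len(sub)
        mls_count = int((sub["mls_max_mm"].fillna(0.0) > mls_threshold_mm).sum())
        dhc_count = int(sub["dhc"].sum())
        death_count = int(sub["death_7d"].sum())
        rows.append(
            {
                "risk_class": cls.value,
                "n": n,
                "mls_count": mls_count,
                "dhc_count": dhc_count,
                "death_count": death_count,
                "mls_rate": mls_count / n if n else None,
                "dhc_rate": dhc_count / n if n else None,
                "death_rate": death_count / n if n else None,
                "empty": n == 0,
            }
        )
    table = pd.DataFrame(rows)
    if int(table["n"].sum()) != len(cohort):
        raise ValidationError("risk-class counts do not sum to cohort size")
    return RiskTable(table=table)
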