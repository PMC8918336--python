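"""Parameter calibration: recover (m_ratio, lambda) by maximizing the
Pearson correlation between the KM index and the maximum midline shift.

The search is a deterministic coordinate descent: a grid over the core
swelling ratio ``m`` (default 0.1 ... 5.0 in steps of 0.1, the interval the
index was originally fitted on) and a bracketed golden-section refinement of
the lysis factor ``lambda`` on (0, 1] to a 1e-3 tolerance, repeated for two
outer sweeps. Ties in correlation break toward smaller ``m`` and larger
``lambda`` (the weaker weighting). Patients without a recorded midline shift
contribute 0 mm by default — the outcome is the *maximum* shift observed,
and no shift observed is a shift of zero (switchable to dropping them).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .cohort import Cohort
from .core import (
    DEFAULT_PARAMS,
    UNKNOWN,
    IndexParams,
    ValidationError,
    time_factor,
    weighting_factor_n,
)

__all__ = [
    "CalibrationResult",
    "DegenerateInputError",
    "UnidentifiableError",
    "pearson_r",
    "grid_search_m",
    "optimize_lambda",
    "calibrate",
    "calibrate_time_variant",
    "cohort_arrays",
]

GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class DegenerateInputError(ValidationError):
    """A series is constant (or otherwise uninformative) for correlation."""


class UnidentifiableError(ValidationError):
    """The requested parameter cannot be identified from this cohort."""


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient and its two-sided p-value.

    The p-value comes from the t-transform with n - 2 degrees of freedom.
    Constant input raises instead of silently returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"series must be equal-length 1-D, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant series has no defined correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def cohort_arrays(
    cohort: Cohort,
    params: IndexParams = DEFAULT_PARAMS,
    *,
    mls_missing: str = "zero",
):
    """Flatten a cohort into numpy arrays for vectorized index evaluation.

    Returns a dict of arrays: volumes, the pre-lysis weighting factor
    ``n_base`` per patient, rtPA flags, time factors and the MLS outcome.
    ``mls_missing`` is "zero" (missing shift counts as 0 mm) or "drop".
    """
    if mls_missing not in ("zero", "drop"):
        raise ValidationError(f"mls_missing must be 'zero' or 'drop', got {mls_missing!r}")
    rows = list(cohort)
    if mls_missing == "drop":
        rows = [p for p in rows if p.mls_max_mm is not None]
    no_lysis = replace(params, lambda_lysis=1.0)
    arr = {
        "core": np.array([p.volumes.v_core for p in rows], dtype=float),
        "penumbra": np.array([p.volumes.v_penumbra for p in rows], dtype=float),
        "mtt": np.array([p.volumes.v_mtt for p in rows], dtype=float),
        "mip": np.array([p.volumes.v_mip for p in rows], dtype=float),
        "n_base": np.array([weighting_factor_n(p.treatment, no_lysis) for p in rows], dtype=float),
        "rtpa": np.array([p.treatment.rtpa for p in rows], dtype=bool),
        "t": np.array([time_factor(p.treatment.onset_to_groin_hours) for p in rows], dtype=float),
        "mls": np.array(
            [0.0 if p.mls_max_mm is None else float(p.mls_max_mm) for p in rows], dtype=float
        ),
    }
    return arr


def _km_values(arr, m: float, lam: float) -> np.ndarray:
    n_eff = arr["n_base"] * np.where(arr["rtpa"], lam, 1.0)
    return (n_eff * (m * arr["core"] + arr["penumbra"]) + arr["mtt"]) / arr["mip"]


def _kmt_values(arr, m: float, lam_t: float) -> np.ndarray:
    n_eff = arr["n_base"] * np.where(arr["rtpa"], lam_t, 1.0)
    nt = n_eff ** arr["t"]
    return (m * nt * arr["core"] + nt * arr["penumbra"] + arr["mtt"]) / arr["mip"]


def _r(values: np.ndarray, mls: np.ndarray) -> float:
    if np.ptp(mls) == 0:
        raise DegenerateInputError("midline-shift outcome is constant across the cohort")
    if np.ptp(values) == 0:
        return -np.inf
    return float(stats.pearsonr(values, mls).statistic)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a correlation-maximizing parameter search."""

    m_ratio: float
    lambda_lysis: float
    pearson_r: float
    lambda_lysis_time: float | None = None
    trace: tuple[tuple[float, float, float], ...] = ()  # (m, lambda, r)
    tie_break: str = "smaller m, larger lambda"

    def to_json(self) -> str:
        return json.dumps(
            {
                "m_ratio": self.m_ratio,
                "lambda_lysis": self.lambda_lysis,
                "lambda_lysis_time": self.lambda_lysis_time,
                "pearson_r": self.pearson_r,
                "tie_break": self.tie_break,
                "trace": [list(t) for t in self.trace],
            },
            indent=2,
        )


def _require_mls(arr) -> None:
    if arr["mls"].size < 3:
        raise ValidationError("need at least 3 patients with an outcome to calibrate")


def _require_lysis_contrast(arr) -> None:
    if arr["rtpa"].all() or not arr["rtpa"].any():
        raise UnidentifiableError(
            "lambda is unidentifiable: cohort must contain both rtPA and non-rtPA patients"
        )


def default_m_grid() -> np.ndarray:
    """The original search interval for the swelling ratio, m = 0.1 ... 5.0."""
    return np.round(np.arange(0.1, 5.0 + 1e-9, 0.1), 10)


def grid_search_m(
    cohort: Cohort,
    grid=None,
    lam: float = DEFAULT_PARAMS.lambda_lysis,
    params: IndexParams = DEFAULT_PARAMS,
    *,
    mls_missing: str = "zero",
) -> CalibrationResult:
    """Best ``m_ratio`` on a grid at fixed lysis factor ``lam``."""
    arr = cohort_arrays(cohort, params, mls_missing=mls_missing)
    _require_mls(arr)
    grid = default_m_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("empty m grid")
    trace = []
    best_m, best_r = None, -np.inf
    for m in grid:
        r = _r(_km_values(arr, float(m), lam), arr["mls"])
        trace.append((float(m), lam, r))
        if r > best_r:  # strict: ties keep the smaller m seen first
            best_m, best_r = float(m), r
    return CalibrationResult(
        m_ratio=best_m, lambda_lysis=lam, pearson_r=best_r, trace=tuple(trace)
    )


def _refine_lambda(arr, values_fn, m: float, lo: float, hi: float, tol: float, trace: list):
    """Coarse grid then golden-section refinement of lambda on [lo, hi]."""
    coarse = np.linspace(lo, hi, 20)
    best_lam, best_r = None, -np.inf
    for lam in coarse:
        r = _r(values_fn(arr, m, float(lam)), arr["mls"])
        trace.append((m, float(lam), r))
        if r >= best_r:  # ties go to the larger lambda
            best_lam, best_r = float(lam), r
    step = float(coarse[1] - coarse[0])
    a = max(lo, best_lam - step)
    b = min(hi, best_lam + step)
    if b - a < tol:
        lam = 0.5 * (a + b)
        return lam, _r(values_fn(arr, m, lam), arr["mls"])
    c = b - GOLDEN * (b - a)
    d = a + GOLDEN * (b - a)
    fc = _r(values_fn(arr, m, c), arr["mls"])
    fd = _r(values_fn(arr, m, d), arr["mls"])
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - GOLDEN * (b - a)
            fc = _r(values_fn(arr, m, c), arr["mls"])
        else:
            a, c, fc = c, d, fd
            d = a + GOLDEN * (b - a)
            fd = _r(values_fn(arr, m, d), arr["mls"])
        trace.append((m, 0.5 * (a + b), max(fc, fd)))
    lam = 0.5 * (a + b)
    return lam, _r(values_fn(arr, m, lam), arr["mls"])


def optimize_lambda(
    cohort: Cohort,
    m: float = DEFAULT_PARAMS.m_ratio,
    interval: tuple[float, float] = (0.05, 1.0),
    tol: float = 1e-3,
    params: IndexParams = DEFAULT_PARAMS,
    *,
    mls_missing: str = "zero",
) -> CalibrationResult:
    """Best lysis factor ``lambda`` at fixed ``m`` by bracketed 1-D search."""
    arr = cohort_arrays(cohort, params, mls_missing=mls_missing)
    _require_mls(arr)
    _require_lysis_contrast(arr)
    lo, hi = interval
    if not (0 < lo <= hi <= 1):
        raise ValidationError(f"lambda interval must satisfy 0 < lo <= hi <= 1, got {interval}")
    trace: list[tuple[float, float, float]] = []
    if hi - lo < tol:
        lam = 0.5 * (lo + hi)
        return CalibrationResult(
            m_ratio=m, lambda_lysis=lam,
            pearson_r=_r(_km_values(arr, m, lam), arr["mls"]), trace=tuple(trace),
        )
    lam, r = _refine_lambda(arr, _km_values, m, lo, hi, tol, trace)
    return CalibrationResult(m_ratio=m, lambda_lysis=lam, pearson_r=r, trace=tuple(trace))


def calibrate(
    cohort: Cohort,
    m_grid=None,
    lambda_interval: tuple[float, float] = (0.05, 1.0),
    tol: float = 1e-3,
    sweeps: int = 2,
    params: IndexParams = DEFAULT_PARAMS,
    *,
    mls_missing: str = "zero",
) -> CalibrationResult:
    """Joint (m, lambda) calibration by coordinate search.

    Alternates the m grid and the lambda refinement for ``sweeps`` rounds;
    deterministic for a given cohort and grid.
    """
    arr = cohort_arrays(cohort, params, mls_missing=mls_missing)
    _require_mls(arr)
    _require_lysis_contrast(arr)
    grid = default_m_grid() if m_grid is None else np.asarray(m_grid, dtype=float)
    lam = params.lambda_lysis
    trace: list[tuple[float, float, float]] = []
    best_m, best_r = float(grid[0]), -np.inf
    for _ in range(sweeps):
        best_m, best_r = None, -np.inf
        for m in grid:
            r = _r(_km_values(arr, float(m), lam), arr["mls"])
            trace.append((float(m), lam, r))
            if r > best_r:
                best_m, best_r = float(m), r
        lam, best_r = _refine_lambda(arr, _km_values, best_m, *lambda_interval, tol, trace)
    return CalibrationResult(
        m_ratio=best_m, lambda_lysis=lam, pearson_r=best_r, trace=tuple(trace)
    )


def calibrate_time_variant(
    cohort: Cohort,
    m: float = DEFAULT_PARAMS.m_ratio,
    lambda_interval: tuple[float, float] = (0.05, 1.0),
    tol: float = 1e-3,
    params: IndexParams = DEFAULT_PARAMS,
    *,
    mls_missing: str = "zero",
) -> CalibrationResult:
    """Refit the lysis factor for the time-weighted KMT index.

    The time factor enters as an exponent on ``n``; patients with unknown
    onset time carry t = 1. Requires at least one patient with a known
    onset-to-groin time (otherwise the exponent never differs from 1 by
    construction of the cohort and the refit is meaningless).
    """
    arr = cohort_arrays(cohort, params, mls_missing=mls_missing)
    _require_mls(arr)
    _require_lysis_contrast(arr)
    if all(p.treatment.onset_to_groin_hours is UNKNOWN for p in cohort):
        raise ValidationError("no patients with a known onset time; cannot fit the time variant")
    trace: list[tuple[float, float, float]] = []
    lam_t, r = _refine_lambda(arr, _kmt_values, m, *lambda_interval, tol, trace)
    return CalibrationResult(
        m_ratio=m, lambda_lysis=params.lambda_lysis, lambda_lysis_time=lam_t,
        pearson_r=r, trace=tuple(trace),
    )
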