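"""Core KM / KMT index computation.

The KM index estimates the space-occupying burden of a middle-cerebral-artery
infarction relative to the intracranial capacity, from four CT-perfusion
volumes and the chosen therapy:

    KM = (n * (m * v_core + v_penumbra) + v_mtt) / v_mip

where ``m`` is the swelling potential of infarcted tissue, ``n`` the
probability that the penumbra proceeds to infarction (driven by the
thrombectomy result on the mTICI scale and reduced multiplicatively by
``lambda`` if intravenous rtPA lysis was given), and ``v_mtt / v_mip`` the
occupied-space (brain-parenchyma) term that credits protective atrophy.
Values above 1 indicate that the swollen tissue will exceed the free
intracranial space, i.e. herniation / midline-shift risk.

The time-weighted KMT variant raises ``n`` to a time factor ``t`` derived
from the onset-to-groin-puncture delay, with ``m`` following the t-th-root
relation so that the core term keeps its fixed swelling ratio.

This module is purely computational: no file I/O, all tunables live in
:class:`IndexParams`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "MTICI",
    "RiskClass",
    "PerfusionVolumes",
    "TreatmentRecord",
    "IndexParams",
    "KMResult",
    "ValidationError",
    "UNKNOWN",
    "weighting_factor_n",
    "time_factor",
    "km_index",
    "kmt_index",
    "km_score",
    "risk_class",
    "DEFAULT_PARAMS",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class _Unknown:
    """Sentinel for an unknown onset-to-groin time (wake-up / unclear onset)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNKNOWN"


#: Sentinel marking an unknown symptom-onset time.
UNKNOWN = _Unknown()


class MTICI(str, enum.Enum):
    """Modified Thrombolysis In Cerebral Infarction reperfusion grade."""

    G0 = "0"
    G1 = "1"
    G2A = "2a"
    G2B = "2b"
    G2C = "2c"
    G3 = "3"

    @classmethod
    def parse(cls, value: "str | MTICI") -> "MTICI":
        if isinstance(value, cls):
            return value
        text = str(value).strip().lower()
        for member in cls:
            if member.value == text:
                return member
        raise ValidationError(f"unknown mTICI grade {value!r}")


class RiskClass(str, enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    SEVERE = "severe"


@dataclass(frozen=True)
class PerfusionVolumes:
    """The four CT-perfusion volumes, in cm^3.

    ``v_mip`` (partial intracranial volume from the maximum-intensity
    projection) proxies the intracranial volume; ``v_mtt`` (mean-transit-time
    partial brain volume) the perfused parenchyma; core and penumbra come
    from the vendor's automated mismatch estimation and are disjoint here.
    """

    v_core: float
    v_penumbra: float
    v_mip: float
    v_mtt: float

    def __post_init__(self) -> None:
        for name in ("v_core", "v_penumbra", "v_mip", "v_mtt"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
        if self.v_mip <= 0:
            raise ValidationError(f"v_mip must be > 0, got {self.v_mip!r}")
        if self.v_mtt > self.v_mip + 1e-9:
            raise ValidationError(
                f"v_mtt ({self.v_mtt}) must not exceed v_mip ({self.v_mip})"
            )
        if self.v_core + self.v_penumbra > self.v_mtt + 1e-9:
            raise ValidationError(
                "v_core + v_penumbra "
                f"({self.v_core + self.v_penumbra}) must not exceed v_mtt ({self.v_mtt})"
            )

    @property
    def v_lesion(self) -> float:
        """Core + penumbra, for the inclusive penumbra convention."""
        return self.v_core + self.v_penumbra


@dataclass(frozen=True)
class TreatmentRecord:
    """Therapy actually delivered: thrombectomy result, lysis, delay."""

    thrombectomy_performed: bool
    mtici: MTICI | None = None
    rtpa: bool = False
    onset_to_groin_hours: "float | _Unknown" = UNKNOWN

    def __post_init__(self) -> None:
        if self.thrombectomy_performed and self.mtici is None:
            raise ValidationError("mTICI grade required when thrombectomy was performed")
        if not self.thrombectomy_performed and self.mtici is not None:
            raise ValidationError("mTICI grade given but no thrombectomy performed")
        h = self.onset_to_groin_hours
        if not isinstance(h, _Unknown):
            if not math.isfinite(float(h)) or float(h) < 0:
                raise ValidationError(f"onset_to_groin_hours must be >= 0, got {h!r}")


def _default_n_base() -> dict[MTICI, float]:
    # Linear mapping over the mTICI ladder: 1.0 at grade 0 down to 0.5 at grade 3.
    return {
        MTICI.G0: 1.0,
        MTICI.G1: 0.9,
        MTICI.G2A: 0.8,
        MTICI.G2B: 0.7,
        MTICI.G2C: 0.6,
        MTICI.G3: 0.5,
    }


@dataclass(frozen=True)
class IndexParams:
    """Tunable index parameters; defaults are the values fitted on the
    original 186-patient derivation cohort (Siemens Syngo.via volumetry).

    ``m_ratio``
        swelling factor of the infarct core relative to ``n`` (m = m_ratio * n).
    ``lambda_lysis``
        multiplicative reduction of ``n`` when rtPA was given (KM index).
    ``lambda_lysis_time``
        the analogous factor refitted for the time-weighted KMT index.
    ``n_base``
        mTICI grade -> penumbra-infarction probability ``n`` (pre-lysis).
    """

    m_ratio: float = 2.8
    lambda_lysis: float = 0.70
    lambda_lysis_time: float = 0.87
    n_base: dict[MTICI, float] = field(default_factory=_default_n_base)
    n_no_thrombectomy: float = 1.0

    def __post_init__(self) -> None:
        if not (self.m_ratio > 0 and math.isfinite(self.m_ratio)):
            raise ValidationError(f"m_ratio must be > 0, got {self.m_ratio!r}")
        for name in ("lambda_lysis", "lambda_lysis_time", "n_no_thrombectomy"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must lie in (0, 1], got {v!r}")
        order = [MTICI.G0, MTICI.G1, MTICI.G2A, MTICI.G2B, MTICI.G2C, MTICI.G3]
        values = [self.n_base[g] for g in order]
        if any(not (0 < v <= 1) for v in values):
            raise ValidationError("n_base values must lie in (0, 1]")
        if any(a <= b for a, b in zip(values, values[1:])):
            raise ValidationError("n_base must be strictly decreasing from mTICI 0 to 3")


DEFAULT_PARAMS = IndexParams()


@dataclass(frozen=True)
class KMResult:
    """Index value plus its discretization and component breakdown."""

    index: float
    score: int
    risk_class: RiskClass
    components: dict[str, float]


def weighting_factor_n(treatment: TreatmentRecord, params: IndexParams = DEFAULT_PARAMS) -> float:
    """Penumbra-infarction probability ``n`` for a treatment record.

    Thrombectomy maps the mTICI grade through ``params.n_base`` (1.0 at
    grade 0 falling linearly to 0.5 at grade 3); no thrombectomy means the
    whole penumbra is at risk (n = 1). Intravenous lysis multiplies the
    result by ``params.lambda_lysis`` regardless of thrombectomy status,
    modelling lysis as an independent penumbra-salvage factor.
    """
    if treatment.thrombectomy_performed:
        assert treatment.mtici is not None  # enforced by TreatmentRecord
        n = params.n_base[treatment.mtici]
    else:
        n = params.n_no_thrombectomy
    if treatment.rtpa:
        n *= params.lambda_lysis
    return n


def time_factor(onset_to_groin_hours: "float | _Unknown") -> int:
    """Time factor ``t`` from the onset-to-groin-puncture delay.

    3 for delays up to 4.5 h, 2 up to 8 h, 1 beyond. An unknown onset
    (wake-up stroke, unclear onset) maps to t = 1, the most conservative
    (highest-index) choice the table permits.
    """
    if isinstance(onset_to_groin_hours, _Unknown) or onset_to_groin_hours is None:
        return 1
    h = float(onset_to_groin_hours)
    if not math.isfinite(h) or h < 0:
        raise ValidationError(f"onset_to_groin_hours must be >= 0, got {h!r}")
    if h <= 4.5:
        return 3
    if h <= 8.0:
        return 2
    return 1


def km_score(index: float) -> int:
    """Discretize an index value to the integer KM score in [0, 20].

    Below 1.005 the score is 0; at or above 1.195 it saturates at 20;
    otherwise the score is the index's first two decimals, i.e.
    round(100 * (index - 1)) with half-away-from-zero rounding (1.14 -> 14).
    """
    if not math.isfinite(index):
        raise ValidationError(f"index must be finite, got {index!r}")
    if index < 1.005:
        return 0
    if index >= 1.195:
        return 20
    # round-half-away-from-zero; index > 1 here so floor(x + 0.5) suffices.
    # Snap to 9 decimals first so decimal inputs like 1.075 (binary 7.4999...96
    # after scaling) land on their intended half-way point.
    return int(math.floor(round(100.0 * (index - 1.0), 9) + 0.5))


_RISK_BINS = (
    (0, 2, RiskClass.LOW),
    (3, 7, RiskClass.MODERATE),
    (8, 13, RiskClass.HIGH),
    (14, 20, RiskClass.SEVERE),
)


def risk_class(score: int) -> RiskClass:
    """Map a KM score to its risk class (0-2 low, 3-7 moderate, 8-13 high,
    14-20 severe)."""
    if not isinstance(score, (int,)) or isinstance(score, bool):
        raise ValidationError(f"score must be an integer, got {score!r}")
    for lo, hi, cls in _RISK_BINS:
        if lo <= score <= hi:
            return cls
    raise ValidationError(f"score must lie in [0, 20], got {score!r}")


def _finish(index: float, components: dict[str, float]) -> KMResult:
    score = km_score(index)
    return KMResult(index=index, score=score, risk_class=risk_class(score), components=components)


def km_index(
    volumes: PerfusionVolumes,
    treatment: TreatmentRecord,
    params: IndexParams = DEFAULT_PARAMS,
) -> KMResult:
    """KM index for one patient.

    Computes (n * (m_ratio * v_core + v_penumbra) + v_mtt) / v_mip with the
    treatment-dependent ``n`` from :func:`weighting_factor_n`.
    """
    n = weighting_factor_n(treatment, params)
    index = (n * (params.m_ratio * volumes.v_core + volumes.v_penumbra) + volumes.v_mtt) / volumes.v_mip
    components = {
        "I": volumes.v_core / volumes.v_mip,
        "P": volumes.v_penumbra / volumes.v_mip,
        "B": volumes.v_mtt / volumes.v_mip,
        "n": n,
        "m": params.m_ratio * n,
    }
    return _finish(index, components)


def kmt_index(
    volumes: PerfusionVolumes,
    treatment: TreatmentRecord,
    params: IndexParams = DEFAULT_PARAMS,
    *,
    literal_grouping: bool = False,
) -> KMResult:
    """Time-weighted KMT index.

    ``n`` is computed with ``params.lambda_lysis_time`` in place of
    ``lambda_lysis`` and raised to the time factor ``t``; the core keeps its
    fixed swelling ratio, i.e. m^t = m_ratio * n^t (the t-th-root relation
    m = m_ratio^(1/t) * n):

        KMT = (m_ratio * n^t * v_core + n^t * v_penumbra + v_mtt) / v_mip

    With ``literal_grouping=True`` the alternative published grouping is
    used instead, scaling core and penumbra jointly:
    (m_ratio * n^t * (v_core + v_penumbra) + v_mtt) / v_mip.
    """
    t = time_factor(treatment.onset_to_groin_hours)
    time_params = replace(params, lambda_lysis=params.lambda_lysis_time)
    n = weighting_factor_n(treatment, time_params)
    nt = n**t
    if literal_grouping:
        index = (params.m_ratio * nt * (volumes.v_core + volumes.v_penumbra) + volumes.v_mtt) / volumes.v_mip
    else:
        index = (params.m_ratio * nt * volumes.v_core + nt * volumes.v_penumbra + volumes.v_mtt) / volumes.v_mip
    components = {
        "I": volumes.v_core / volumes.v_mip,
        "P": volumes.v_penumbra / volumes.v_mip,
        "B": volumes.v_mtt / volumes.v_mip,
        "n": n,
        "m": params.m_ratio * nt,
        "t": float(t),
    }
    return _finish(index, components)
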