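"""Seeded synthetic cohort generator.

Produces patient cohorts with the statistical structure of the original
186-patient MCA-infarction study so that calibration, evaluation and the
CLI can be exercised without clinical data: truncated-normal perfusion
volumes tied to a common head-size factor (so the MTT brain volume never
exceeds the MIP intracranial volume), the study's thrombectomy fraction and
mTICI distribution, its lysis rate, and a zero-inflated hinge model that
turns the latent (true-parameter) KM index into a maximum midline shift —
most patients shift 0 mm, a minority shift proportionally to how far their
index exceeds a herniation offset.

One RNG sub-stream per patient index: adding or removing patients never
changes the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .cohort import EXCLUSION_REASONS, VESSELS, Cohort, PatientRecord
from .core import (
    MTICI,
    UNKNOWN,
    IndexParams,
    PerfusionVolumes,
    TreatmentRecord,
    ValidationError,
    weighting_factor_n,
)

__all__ = ["GeneratorConfig", "generate_cohort"]

_MTICI_ORDER = (MTICI.G0, MTICI.G1, MTICI.G2A, MTICI.G2B, MTICI.G2C, MTICI.G3)


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-generator settings; defaults emulate the derivation cohort.

    Volume means/SDs are the printed cohort statistics (cm^3). The MTT
    volume is drawn as a fraction of the MIP volume (the shared head-size
    factor), keeping the nesting invariant valid by construction. The
    midline shift is ``max(0, slope * (KM_true - offset) + noise)`` with an
    extra zero-inflation coin, where KM_true uses the true parameters
    ``(m_true, lambda_true)``.
    """

    n: int = 186
    seed: int = 0

    # perfusion volumes, cm^3
    penumbra_mean: float = 87.77
    penumbra_sd: float = 37.15
    core_mean: float = 53.81
    core_sd: float = 49.71
    mip_mean: float = 1086.26
    mip_sd: float = 105.59
    mtt_over_mip_mean: float = 0.8748  # 950.27 / 1086.26
    mtt_over_mip_sd: float = 0.035
    mtt_over_mip_bounds: tuple[float, float] = (0.6, 0.995)

    # treatment
    thrombectomy_fraction: float = 132.0 / 186.0
    mtici_weights: tuple[float, ...] = (12, 2, 10, 33, 9, 66)
    rtpa_prob: float = 0.5053
    unknown_onset_prob: float = 51.0 / 186.0
    onset_gamma_shape: float = 2.0
    onset_gamma_scale_h: float = 2.0

    # true index parameters driving the outcome
    m_true: float = 2.8
    lambda_true: float = 0.70
    lambda_time_true: float = 0.87

    # midline-shift hinge model
    mls_slope_mm: float = 40.0
    mls_offset: float = 1.09
    mls_noise_sd_mm: float = 1.5
    mls_zero_inflation: float = 0.4

    # downstream outcomes
    dhc_mls_trigger_mm: float = 4.0
    dhc_prob: float = 0.8
    death_prob_dhc: float = 0.25
    death_prob_mls: float = 0.10
    death_prob_base: float = 0.02

    # demographics
    age_mean: float = 73.7
    age_sd: float = 17.9
    female_prob: float = 0.586
    nihss_mean: float = 9.5
    nihss_sd: float = 2.1
    vessel_weights: tuple[float, ...] = (4, 28, 13, 136, 28, 3, 26)
    age_atrophy_effect: float = 0.0  # >0 links higher age to lower occupied space

    # extra patients appended with exclusion flags, reason -> count
    exclusion_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError(f"n must be >= 0, got {self.n}")
        for name in ("thrombectomy_fraction", "rtpa_prob", "unknown_onset_prob",
                     "mls_zero_inflation", "dhc_prob", "death_prob_dhc",
                     "death_prob_mls", "death_prob_base", "female_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("penumbra_sd", "core_sd", "mip_sd", "mtt_over_mip_sd",
                     "age_sd", "nihss_sd", "mls_noise_sd_mm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if len(self.mtici_weights) != len(_MTICI_ORDER):
            raise ValidationError("mtici_weights needs one weight per mTICI grade")
        if len(self.vessel_weights) != len(VESSELS):
            raise ValidationError("vessel_weights needs one weight per vessel")
        lo, hi = self.mtt_over_mip_bounds
        if not (0 < lo < hi <= 1):
            raise ValidationError(f"mtt_over_mip_bounds must satisfy 0 < lo < hi <= 1")
        bad = set(self.exclusion_counts) - set(EXCLUSION_REASONS)
        if bad:
            raise ValidationError(f"unknown exclusion reasons {sorted(bad)}")
        if any(c < 0 for c in self.exclusion_counts.values()):
            raise ValidationError("exclusion counts must be >= 0")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float = -math.inf, hi: float = math.inf) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")  # pragma: no cover


@lru_cache(maxsize=64)
def _matched_truncnorm_params(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Pre-truncation (mu, sigma) of a normal truncated below at 0 whose
    POST-truncation mean and SD equal the targets.

    The printed cohort statistics are sample moments of non-negative data,
    so they must be matched after truncation; sampling a normal with the
    printed moments and rejecting negatives would inflate the mean (by
    ~13 cm^3 for the infarct core).
    """

    def residual(p):
        mu, sigma = p
        if sigma <= 0:
            return [1e6, 1e6]
        a = -mu / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [float(m) - target_mean, math.sqrt(float(v)) - target_sd]

    (mu, sigma), info, ier, msg = optimize.fsolve(
        residual, x0=[target_mean, target_sd], full_output=True
    )
    if ier != 1:  # pragma: no cover - defensive
        raise RuntimeError(f"truncated-normal moment matching failed: {msg}")
    return float(mu), float(sigma)


def _sample_matched(rng: np.random.Generator, target_mean: float, target_sd: float) -> float:
    """Inverse-CDF draw from the 0-truncated normal with matched moments.

    Rejection sampling is unusable here: a coefficient of variation near 1
    (the infarct core) pushes the fitted pre-truncation mean far below zero.
    """
    mu, sigma = _matched_truncnorm_params(target_mean, target_sd)
    a = -mu / sigma
    return float(stats.truncnorm.ppf(rng.random(), a, np.inf, loc=mu, scale=sigma))


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _draw_patient(cfg: GeneratorConfig, index: int,
                  flags: frozenset[str] = frozenset()) -> PatientRecord:
    rng = _patient_rng(cfg.seed, index)
    age = _trunc_normal(rng, cfg.age_mean, cfg.age_sd, 18.0, 100.0)
    sex = "f" if rng.random() < cfg.female_prob else "m"
    nihss = int(round(_trunc_normal(rng, cfg.nihss_mean, cfg.nihss_sd, 0.0, 42.0)))
    vw = np.asarray(cfg.vessel_weights, dtype=float)
    vessel = VESSELS[rng.choice(len(VESSELS), p=vw / vw.sum())]

    mip = _trunc_normal(rng, cfg.mip_mean, cfg.mip_sd, 500.0, math.inf)
    ratio_mean = cfg.mtt_over_mip_mean
    if cfg.age_atrophy_effect > 0:
        ratio_mean -= cfg.age_atrophy_effect * (age - cfg.age_mean) / cfg.age_sd
    lo, hi = cfg.mtt_over_mip_bounds
    mtt = mip * _trunc_normal(rng, ratio_mean, cfg.mtt_over_mip_sd, lo, hi)
    for _ in range(1000):
        core = _sample_matched(rng, cfg.core_mean, cfg.core_sd)
        pen = _sample_matched(rng, cfg.penumbra_mean, cfg.penumbra_sd)
        if core + pen <= mtt:
            break
    else:  # pragma: no cover - lesion larger than the brain is vanishingly rare
        raise RuntimeError("could not sample lesion volumes inside the MTT volume")
    volumes = PerfusionVolumes(v_core=core, v_penumbra=pen, v_mip=mip, v_mtt=mtt)

    thrombectomy = rng.random() < cfg.thrombectomy_fraction
    mtici = None
    if thrombectomy:
        mw = np.asarray(cfg.mtici_weights, dtype=float)
        mtici = _MTICI_ORDER[rng.choice(len(_MTICI_ORDER), p=mw / mw.sum())]
    rtpa = rng.random() < cfg.rtpa_prob
    if rng.random() < cfg.unknown_onset_prob:
        onset = UNKNOWN
    else:
        onset = float(rng.gamma(cfg.onset_gamma_shape, cfg.onset_gamma_scale_h))
    treatment = TreatmentRecord(
        thrombectomy_performed=thrombectomy, mtici=mtici, rtpa=rtpa,
        onset_to_groin_hours=onset,
    )

    true_params = IndexParams(m_ratio=cfg.m_true, lambda_lysis=cfg.lambda_true,
                              lambda_lysis_time=cfg.lambda_time_true)
    n_eff = weighting_factor_n(treatment, true_params)
    km_true = (n_eff * (cfg.m_true * core + pen) + mtt) / mip

    if rng.random() < cfg.mls_zero_inflation:
        mls = 0.0
    else:
        latent = cfg.mls_slope_mm * (km_true - cfg.mls_offset) + rng.normal(0.0, cfg.mls_noise_sd_mm)
        mls = max(0.0, round(latent, 1))

    dhc = mls >= cfg.dhc_mls_trigger_mm and rng.random() < cfg.dhc_prob
    if dhc:
        p_death = cfg.death_prob_dhc
    elif mls > 0:
        p_death = cfg.death_prob_mls
    else:
        p_death = cfg.death_prob_base
    death = rng.random() < p_death

    return PatientRecord(
        id=f"P{index:04d}", age=age, sex=sex, occluded_vessel=vessel, nihss=nihss,
        volumes=volumes, treatment=treatment, mls_max_mm=mls, dhc=dhc,
        death_7d=death, exclusion_flags=flags,
    )


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a reproducible synthetic cohort.

    Patients 0 ... n-1 are regular (no exclusion flags); any
    ``exclusion_counts`` are appended after them as additional flagged
    records, so a config with n = 186 and 40/6/29 flagged extras yields the
    261-patient pre-filter situation of the original study.
    """
    patients = [_draw_patient(config, i) for i in range(config.n)]
    index = config.n
    for reason in EXCLUSION_REASONS:
        for _ in range(config.exclusion_counts.get(reason, 0)):
            patients.append(_draw_patient(config, index, flags=frozenset({reason})))
            index += 1
    return Cohort(patients=tuple(patients), source=f"synthetic(seed={config.seed})")
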