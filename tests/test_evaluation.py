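"""Threshold reports, Mann-Whitney AUC/ROC identities, univariate and
risk-class tables."""

import dataclasses
import math

import numpy as np
import pytest

from kmindex.cohort import Cohort
from kmindex.core import MTICI, PerfusionVolumes, TreatmentRecord, ValidationError
from kmindex.evaluation import (
    auc_mann_whitney,
    cohort_indices,
    confusion_at_threshold,
    optimal_threshold,
    risk_table,
    roc_curve,
    threshold_sweep,
    univariate_table,
)
from kmindex.simulate import GeneratorConfig, generate_cohort


def brute_force_auc(pos, neg):
    """O(n^2) pair-counting oracle: wins + half-ties over all pairs."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def study_like_scores(rng, n_pos=24, n_neg=162, n_pos_above=22, n_neg_above=36,
                      threshold=1.021):
    """Index values reproducing given above/below-threshold counts."""
    pos = np.concatenate([
        rng.uniform(threshold + 0.001, 1.4, n_pos_above),
        rng.uniform(0.8, threshold - 0.001, n_pos - n_pos_above),
    ])
    neg = np.concatenate([
        rng.uniform(threshold + 0.001, 1.4, n_neg_above),
        rng.uniform(0.8, threshold - 0.001, n_neg - n_neg_above),
    ])
    values = np.concatenate([pos, neg])
    flags = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    return values, flags


class TestConfusion:
    def test_study_counts_reproduce_printed_rates(self, rng):
        """22 of 24 shifts above the 1.021 cut-off and 126 of 162 non-shifts
        below it give sensitivity 91.6% and specificity 77.8%."""
        values, flags = study_like_scores(rng)
        rep = confusion_at_threshold(values, flags, 1.021)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (22, 2, 126, 36)
        assert rep.sensitivity == 22 / 24
        assert rep.specificity == 126 / 162
        assert round(100 * rep.sensitivity, 1) == 91.7  # printed as 91.6 (truncated)
        assert round(100 * rep.specificity, 1) == 77.8

    def test_all_positives_above_threshold(self):
        rep = confusion_at_threshold([2.0, 2.0, 0.5], [True, True, False], 1.0)
        assert rep.sensitivity == 1.0

    def test_threshold_above_maximum(self):
        rep = confusion_at_threshold([0.9, 1.1, 1.2], [False, True, True], 5.0)
        assert rep.sensitivity == 0.0
        assert rep.specificity == 1.0

    def test_one_class_input_rejected(self):
        with pytest.raises(ValidationError):
            confusion_at_threshold([1.0, 2.0], [True, True], 1.5)

    def test_strict_versus_inclusive_comparison(self):
        values, flags = [1.0, 1.0], [True, False]
        assert confusion_at_threshold(values, flags, 1.0, strict=True).tp == 0
        assert confusion_at_threshold(values, flags, 1.0, strict=False).tp == 1

    def test_sensitivity_monotone_in_threshold(self, rng):
        values = rng.normal(1.0, 0.1, 200)
        flags = rng.random(200) < 0.3
        sweep = threshold_sweep(values, flags)
        assert (np.diff(sweep["sensitivity"]) <= 1e-12).all()
        assert (np.diff(sweep["specificity"]) >= -1e-12).all()


class TestAUC:
    def test_perfect_separation(self):
        auc, _, _ = auc_mann_whitney([3, 4, 5, 1, 2], [1, 1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _, _ = auc_mann_whitney([1.0] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        values = np.round(rng.normal(1.0, 0.1, 30), 2)  # rounding forces ties
        flags = rng.random(30) < 0.4
        if flags.all() or not flags.any():
            flags[0] = ~flags[0]
        auc, _, _ = auc_mann_whitney(values, flags)
        oracle = brute_force_auc(values[flags], values[~flags])
        assert auc == pytest.approx(oracle, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            auc_mann_whitney([1.0, 2.0], [False, False])


class TestROC:
    def test_single_positive_above_all_negatives_hits_corner(self):
        fpr, tpr = roc_curve([2.0, 0.1, 0.2, 0.3], [True, False, False, False])
        pts = set(zip(fpr.tolist(), tpr.tolist()))
        assert (0.0, 1.0) in pts

    def test_staircase_endpoints_and_monotonicity(self, rng):
        values = rng.normal(size=50)
        flags = rng.random(50) < 0.5
        fpr, tpr = roc_curve(values, flags)
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()

    def test_area_equals_mann_whitney_auc(self, rng):
        for trial in range(25):
            values = np.round(rng.normal(1.0, 0.1, 60), 2)
            flags = rng.random(60) < 0.3
            if flags.all() or not flags.any():
                flags[0] = ~flags[0]
            fpr, tpr = roc_curve(values, flags)
            area = float(np.trapezoid(tpr, fpr))
            auc, _, _ = auc_mann_whitney(values, flags)
            assert area == pytest.approx(auc, abs=1e-12)

    def test_reversed_scores_mirror_area(self, rng):
        values = rng.normal(size=40)
        flags = rng.random(40) < 0.5
        if flags.all() or not flags.any():
            flags[0] = ~flags[0]
        auc, _, _ = auc_mann_whitney(values, flags)
        auc_rev, _, _ = auc_mann_whitney(-values, flags)
        assert auc_rev == pytest.approx(1.0 - auc, abs=1e-12)


class TestOptimalThreshold:
    def test_selectors_on_separable_data(self):
        values = [0.9, 0.95, 1.0, 1.1, 1.2, 1.3]
        flags = [False, False, False, True, True, True]
        rep = optimal_threshold(values, flags, selector="youden")
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        rep2 = optimal_threshold(values, flags, selector="sensitivity_first")
        assert rep2.sensitivity >= 0.9


class TestUnivariate:
    def test_factor_identical_to_mls(self, small_cohort):
        table = univariate_table(
            small_cohort,
            factors={"mls_itself": lambda p, params: p.mls_max_mm or 0.0},
        )
        row = table.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["slope"] == pytest.approx(1.0)
        assert row["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_binary_factor_equals_point_biserial(self, small_cohort):
        """Pearson r of a 0/1 factor equals the closed-form point-biserial."""
        table = univariate_table(small_cohort, factors=["lysis"])
        mls = np.array([p.mls_max_mm or 0.0 for p in small_cohort])
        grp = np.array([p.treatment.rtpa for p in small_cohort])
        n = len(mls)
        rpb = ((mls[grp].mean() - mls[~grp].mean()) / mls.std()
               * math.sqrt(grp.mean() * (1 - grp.mean())))
        assert table.iloc[0]["r"] == pytest.approx(rpb, abs=1e-12)

    def test_core_fraction_correlates_positively(self):
        cohort = generate_cohort(GeneratorConfig(n=600, seed=13))
        table = univariate_table(cohort, factors=["I"])
        assert table.iloc[0]["r"] > 0

    def test_constant_factor_marked_degenerate(self):
        cohort = generate_cohort(GeneratorConfig(n=50, seed=3, rtpa_prob=0.0))
        table = univariate_table(cohort, factors=["lysis"])
        assert table.iloc[0]["significant"] == "NS"
        assert "degenerate" in table.iloc[0]["note"]


def _patient(i, index_target, mls, dhc, death):
    """No-thrombectomy patient engineered to hit a KM index value:
    index = (2.8*core + mtt)/mip with penumbra 0, mip 1000, mtt 900."""
    core = max(0.0, (index_target * 1000 - 900) / 2.8)
    return dataclasses.replace(
        _PATIENT_TEMPLATE,
        id=f"t{i}",
        volumes=PerfusionVolumes(v_core=core, v_penumbra=0.0, v_mtt=900.0, v_mip=1000.0),
        mls_max_mm=mls,
        dhc=dhc,
        death_7d=death,
    )


_PATIENT_TEMPLATE = None  # set lazily to avoid import-order clutter


def table6_cohort():
    """186 patients with the published class sizes and outcome counts:
    low 129 (2 MLS, 3 DHC, 2 deaths), moderate 26 (5, 5, 1),
    high 15 (4, 4, 1), severe 16 (13, 7, 3)."""
    global _PATIENT_TEMPLATE
    from kmindex.cohort import PatientRecord

    _PATIENT_TEMPLATE = PatientRecord(
        id="template", age=70.0, sex="f", occluded_vessel="M1",
        volumes=PerfusionVolumes(v_core=0, v_penumbra=0, v_mtt=900, v_mip=1000),
        treatment=TreatmentRecord(thrombectomy_performed=False),
    )
    spec_rows = [
        (0.98, 129, 2, 3, 2),   # low: score 0
        (1.05, 26, 5, 5, 1),    # moderate: score 5
        (1.10, 15, 4, 4, 1),    # high: score 10
        (1.25, 16, 13, 7, 3),   # severe: score 20
    ]
    patients, i = [], 0
    for index_target, size, n_mls, n_dhc, n_death in spec_rows:
        for k in range(size):
            patients.append(
                _patient(i, index_target, mls=6.0 if k < n_mls else 0.0,
                         dhc=k < n_dhc, death=k < n_death)
            )
            i += 1
    return Cohort(patients=tuple(patients))


class TestRiskTable:
    def test_published_class_rates(self):
        table = risk_table(table6_cohort()).table.set_index("risk_class")
        assert table.loc["low", "n"] == 129
        assert table.loc["low", "mls_rate"] == 2 / 129
        assert table.loc["moderate", "mls_rate"] == 5 / 26
        assert table.loc["high", "mls_rate"] == 4 / 15
        assert table.loc["severe", "mls_rate"] == 13 / 16
        assert round(100 * table.loc["severe", "mls_rate"]) == 81
        assert table.loc["severe", "dhc_count"] == 7
        assert int(table["death_count"].sum()) == 7

    def test_counts_sum_to_cohort_size(self, small_cohort):
        table = risk_table(small_cohort).table
        assert int(table["n"].sum()) == len(small_cohort)

    def test_empty_class_marked_explicitly(self):
        cohort = table6_cohort()
        only_low = Cohort(patients=cohort.patients[:129])
        table = risk_table(only_low).table.set_index("risk_class")
        assert bool(table.loc["severe", "empty"])
        assert table.loc["severe", "mls_rate"] is None or np.isnan(table.loc["severe", "mls_rate"])

    def test_mls_threshold_knob(self):
        table = risk_table(table6_cohort(), mls_threshold_mm=10.0).table
        assert int(table["mls_count"].sum()) == 0


class TestCohortIndices:
    def test_row_per_patient(self, small_cohort):
        table = cohort_indices(small_cohort)
        assert len(table) == len(small_cohort)
        assert set(table.columns) >= {"km_index", "km_score", "risk_class"}
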