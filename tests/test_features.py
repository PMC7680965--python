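import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdgait import preprocess
from pdgait.features import (
    SEVERITY_FEATURE_NAMES,
    asymmetry_index,
    diagnosis_feature_names,
    diagnosis_feature_vector,
    double_support_per_cycle,
    fmv,
    fmv_value,
    select_fmv_sensors,
    severity_feature_vector,
    spatiotemporal_features,
)
from pdgait.gait_events import CycleEvents, GaitCycle, ValidatedCycleSet
from pdgait.pipeline import process_record
from pdgait.config import PipelineConfig
from pdgait.synthetic_gait import GaitSimParams, simulate_record
from pdgait.vgrf_io import SubjectMeta, VGRFRecord

#: the printed per-sensor FMV row of the reference cohort
TABLE2_FMV = (0.69, 0.15, 2.45, 1.27, 2.12, 1.71, 2.22, 0.9)


class TestSpatiotemporal:
    def test_hand_arithmetic(self):
        cyc = [GaitCycle("LEFT", 0, 0.0, 0.65, 1.10)]
        row = spatiotemporal_features(cyc)[0]
        assert row.gct == pytest.approx(1.10)
        assert row.stance_time == pytest.approx(0.65)
        assert row.swing_time == pytest.approx(0.45)
        assert row.stance_ratio == pytest.approx(0.5909, abs=1e-4)
        assert row.swing_ratio == pytest.approx(0.45 / 1.10, abs=1e-9)
        assert row.swing_stance_ratio == pytest.approx(0.45 / 0.65, abs=1e-9)

    def test_ratios_sum_to_one_corrected(self):
        cyc = [GaitCycle("LEFT", 0, 0.0, 0.62, 1.05)]
        row = spatiotemporal_features(cyc, ratio_convention="CORRECTED")[0]
        assert row.stance_ratio + row.swing_ratio == pytest.approx(1.0, abs=1e-12)

    def test_literal_convention_swing_ratio(self):
        cyc = [GaitCycle("LEFT", 0, 0.0, 0.65, 1.10)]
        row = spatiotemporal_features(cyc, ratio_convention="PAPER_LITERAL")[0]
        assert row.swing_ratio == pytest.approx(1.10 / 0.65)

    def test_stride_length_from_speed(self):
        cyc = [GaitCycle("LEFT", 0, 0.0, 0.65, 1.10)]
        meta = SubjectMeta("s", "CONTROL", walking_speed_m_per_s=1.2)
        row = spatiotemporal_features(cyc, meta)[0]
        assert row.stride_length == pytest.approx(1.32)

    def test_missing_speed_warns_and_omits(self):
        cyc = [GaitCycle("LEFT", 0, 0.0, 0.65, 1.10)]
        meta = SubjectMeta("s", "CONTROL")
        with pytest.warns(UserWarning, match="speed"):
            row = spatiotemporal_features(cyc, meta)[0]
        assert row.stride_length is None

    def test_stance_plus_swing_equals_stride_exactly(self, clean_record, config,
                                                     default_meta):
        _, _, validated = process_record(clean_record.record, default_meta, config)
        for row in spatiotemporal_features(validated.cycles_left):
            assert row.stance_time + row.swing_time == pytest.approx(row.gct, abs=1e-12)


class TestAsymmetryIndex:
    def test_identical_series_zero(self):
        assert asymmetry_index([1.1, 1.2, 1.3], [1.1, 1.2, 1.3]) == 0.0

    def test_hand_arithmetic(self):
        assert asymmetry_index([1.2], [1.0]) == pytest.approx(0.16667, abs=1e-5)

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        left, right = [1.2, 1.0, 1.4], [1.0, 1.1, 1.3]
        a0 = asymmetry_index(left, right)
        a1 = asymmetry_index([c * v for v in left], [c * v for v in right])
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_zero_left_value_error(self):
        with pytest.raises(ValueError, match="zero"):
            asymmetry_index([0.0, 1.0], [1.0, 1.0])

    def test_empty_overlap_error(self):
        with pytest.raises(ValueError, match="empty"):
            asymmetry_index([], [1.0])


def _constant_record(left_level, right_level, n=300):
    t = np.arange(n) / 100.0
    left = np.full((n, 8), left_level)
    right = np.full((n, 8), right_level)
    return VGRFRecord("c", t, left, right, left.sum(axis=1), right.sum(axis=1))


class TestFMV:
    def test_identical_feet_zero(self):
        rec = _constant_record(100.0, 100.0)
        assert np.allclose(fmv(rec), 0.0)

    def test_hand_arithmetic(self):
        rec = _constant_record(100.0, 95.0)
        assert np.allclose(fmv(rec), 5.0)

    def test_unloaded_sensor_is_missing(self):
        rec = _constant_record(0.5, 0.5)  # below the 1 N floor
        assert np.all(np.isnan(fmv(rec)))

    def test_asymmetric_pair_ranks_first(self):
        gains = [1.0] * 8
        gains[4] = 0.75  # sensor 5 loaded 25% lighter on the right
        rec = simulate_record(
            GaitSimParams(n_steps=10, right_sensor_gain=tuple(gains), seed=5)
        ).record
        assert select_fmv_sensors(fmv(rec), 1) == [5]


class TestSensorSelection:
    def test_reference_fmv_row_selects_3_and_7(self):
        assert set(select_fmv_sensors(TABLE2_FMV, 2)) == {3, 7}

    def test_descending_order(self):
        assert select_fmv_sensors(TABLE2_FMV, 2) == [3, 7]

    def test_ties_break_to_lower_index(self):
        assert select_fmv_sensors([1.0] * 8, 2) == [1, 2]

    def test_k8_is_full_sort(self):
        got = select_fmv_sensors(TABLE2_FMV, 8)
        order = sorted(range(8), key=lambda i: (-TABLE2_FMV[i], i))
        assert got == [i + 1 for i in order]

    def test_missing_sensors_excluded_and_shortage_errors(self):
        vals = [np.nan] * 7 + [1.0]
        assert select_fmv_sensors(vals, 1) == [8]
        with pytest.raises(ValueError, match="defined FMV"):
            select_fmv_sensors(vals, 2)


class TestDiagnosisVector:
    def test_exactly_34_named_features(self, clean_record, config, default_meta):
        diag, _, _ = process_record(clean_record.record, default_meta, config)
        assert list(diag.values) == diagnosis_feature_names((3, 7))
        assert len(diag.values) == 34
        assert all(np.isfinite(v) for v in diag.values.values())

    def test_symmetric_gait_near_zero_asymmetry(self, clean_record, config,
                                                default_meta):
        diag, _, _ = process_record(clean_record.record, default_meta, config)
        assert diag.values["asymmetry_index"] < 0.05
        assert diag.values["fmv_sensor3"] < 1.0
        assert diag.values["fmv_sensor7"] < 1.0

    def test_time_shift_invariance(self, clean_record, config, default_meta):
        rec = clean_record.record
        shifted = dataclasses.replace(rec, time=rec.time + 7.0)
        a, _, _ = process_record(rec, default_meta, config)
        b, _, _ = process_record(shifted, default_meta, config)
        for name in a.values:
            assert b.values[name] == pytest.approx(a.values[name], rel=1e-9), name

    def test_missing_speed_flags_incomplete(self, clean_record, config):
        meta = SubjectMeta("s", "CONTROL", weight_kg=72.0)
        diag, _, _ = process_record(clean_record.record, meta, config)
        assert diag.incomplete
        assert "step_distance" in diag.imputed

    def test_missing_weight_falls_back_to_unit_peak(self, clean_record, config):
        meta = SubjectMeta("s", "CONTROL", walking_speed_m_per_s=1.2)
        diag, _, _ = process_record(clean_record.record, meta, config)
        assert not diag.incomplete
        assert diag.values["norm_agg_vgrf_left"] <= 1.0

    def test_step_distance_is_speed_times_half_stride(self, clean_record, config,
                                                      default_meta):
        diag, _, _ = process_record(clean_record.record, default_meta, config)
        mean_gct = (diag.values["stride_time_left"] + diag.values["stride_time_right"]) / 2
        assert diag.values["step_distance"] == pytest.approx(
            1.2 * mean_gct / 2, rel=1e-6
        )


def _toy_validated():
    """Three cycles with IDS 10% and TDS 15% of a 1.2 s stride."""
    aligned = []
    for j in range(3):
        t0 = 0.60 + 1.2 * j
        aligned.append(CycleEvents(
            ic_l=t0, tc_l=t0 + 0.75, ic_r=t0 + 0.57, tc_r=t0 + 1.32,
            ic_l_next=t0 + 1.2,
            prev_tc_r=None if j == 0 else t0 + 0.12,
            ic_l_mag=300.0, tc_l_mag=250.0, ic_r_mag=300.0, tc_r_mag=250.0,
        ))
    cycles = [GaitCycle("LEFT", j, 0.55 + 1.2 * j, 1.35 + 1.2 * j, 1.75 + 1.2 * j)
              for j in range(3)]
    ev = None
    return ValidatedCycleSet(cycles, cycles, ev, ev, aligned, 0, 3)


class TestSeverityFeatures:
    def test_ids_hand_arithmetic(self):
        per = double_support_per_cycle(_toy_validated())
        assert np.allclose(per["ids"], 10.0)   # 0.12 s of a 1.2 s stride
        assert np.allclose(per["tds"], 15.0)   # 0.75 - 0.57 = 0.18 s
        assert np.allclose(per["ds"], per["ids"] + per["tds"])
        assert np.allclose(per["limp"], 5.0)

    def test_ds_linearity_and_limp_zero_case(self, clean_record, config,
                                             default_meta):
        _, _, validated = process_record(clean_record.record, default_meta, config)
        per = double_support_per_cycle(validated)
        assert np.allclose(per["ds"], per["ids"] + per["tds"], atol=1e-9)
        assert np.all(per["limp"] >= 0.0)
        assert np.all((per["ids"] > 0) & (per["ids"] < 50))
        assert np.all((per["tds"] > 0) & (per["tds"] < 50))

    def test_severity_vector_names(self, pd_record, config):
        meta = SubjectMeta("p", "PD", hy_stage=2.5, weight_kg=70.0,
                           walking_speed_m_per_s=1.0)
        _, sev, _ = process_record(pd_record.record, meta, config)
        assert list(sev.values) == SEVERITY_FEATURE_NAMES
        assert sev.values["ds_mean"] == pytest.approx(
            sev.values["ids_mean"] + sev.values["tds_mean"], abs=1e-9
        )

    def test_ds_recovery_against_truth(self, config):
        rec = simulate_record(GaitSimParams(
            n_steps=20, severity=0.6, stance_fraction=0.668, flatten=0.36,
            asymmetry=0.3, seed=17,
        ))
        meta = SubjectMeta("p", "PD", hy_stage=2.5, weight_kg=70.0,
                           walking_speed_m_per_s=1.0)
        _, sev, _ = process_record(rec.record, meta, config)
        truth = rec.truth_double_support()
        assert sev.values["ds_mean"] == pytest.approx(truth["ds"], rel=0.10)

    def test_stationarity_of_halves(self, config, default_meta):
        """Two halves of a long stationary walk give near-identical features."""
        rec = simulate_record(GaitSimParams(n_steps=40, noise_sigma=1.0, seed=23)).record
        n = rec.n_samples // 2
        first = VGRFRecord("a", rec.time[:n], rec.left[:n], rec.right[:n],
                           rec.left_total[:n], rec.right_total[:n])
        second = VGRFRecord("b", rec.time[n:], rec.left[n:], rec.right[n:],
                            rec.left_total[n:], rec.right_total[n:])
        a, _, _ = process_record(first, default_meta, config)
        b, _, _ = process_record(second, default_meta, config)
        for name in ("stride_time_left", "stance_time_left", "swing_time_right",
                     "norm_agg_vgrf_left", "max_ic_force_left"):
            assert b.values[name] == pytest.approx(a.values[name], rel=0.10), name
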