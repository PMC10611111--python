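import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import dtw_bruteforce
from coordgait.cohort import CohortSpec, simulate_cohort
from coordgait.features import (ALL_FEATURES, GAIT_FEATURES, TANDEM_FEATURES,
                                FeatureConfig, build_feature_row,
                                complementary_pitch, curvature_feature,
                                dtw_distance, dtw_to_mean, feature_dictionary,
                                hip_flexion_extension_range, mean_cycle,
                                normalized_jerk, regularity, resample_cycle,
                                spatiotemporal_features)
from coordgait.pipeline import cohort_feature_table, extract_cohort_features, segment_participant

FS = 256.0

floats = st.floats(min_value=-50, max_value=50, allow_nan=False)
short_seq = st.lists(floats, min_size=1, max_size=6)


class TestDtw:
    def test_catalog_names(self):
        assert len(GAIT_FEATURES) == 24
        assert len(TANDEM_FEATURES) == 12
        assert len(set(ALL_FEATURES)) == 36
        for name in ("G_RHFE", "G_CURV_SHANK", "TG_DIS_DTW_MEAN_THIGH",
                     "TG_DIS_DTW_MEAN_SHANK"):
            assert name in ALL_FEATURES

    def test_identity_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        assert dtw_distance(a, a) == 0.0

    def test_small_example(self):
        # all monotone paths on the 3x2 grid enumerate to 1.0
        assert dtw_distance([0, 1, 2], [0, 2]) == pytest.approx(1.0)
        assert dtw_bruteforce([0, 1, 2], [0, 2]) == pytest.approx(1.0)

    def test_single_cell(self):
        assert dtw_distance([5.0], [3.0]) == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])

    @settings(max_examples=60, deadline=None)
    @given(short_seq, short_seq)
    def test_matches_bruteforce_oracle(self, a, b):
        assert dtw_distance(a, b) == pytest.approx(dtw_bruteforce(a, b),
                                                   abs=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(short_seq, short_seq)
    def test_symmetry_nonnegativity(self, a, b):
        d = dtw_distance(a, b)
        assert d >= 0.0
        assert d == pytest.approx(dtw_distance(b, a), abs=1e-12)


def make_cycle(shank_ml=None, thigh_ml=None, n=256, pid="P1", seed=0):
    """Minimal GaitCycle for feature unit tests."""
    from coordgait.segmentation import GaitCycle
    rng = np.random.default_rng(seed)
    if shank_ml is None:
        shank_ml = np.sin(2 * np.pi * np.arange(n) / n) * 100
    n = len(shank_ml)
    if thigh_ml is None:
        thigh_ml = 0.5 * np.asarray(shank_ml)
    shank_gyro = np.column_stack([0.1 * np.asarray(shank_ml),
                                  shank_ml, 0.05 * np.asarray(shank_ml)])
    thigh_gyro = np.column_stack([np.zeros(n), thigh_ml, np.zeros(n)])
    accel = np.column_stack([np.ones(n), np.zeros(n), np.zeros(n)])
    return GaitCycle(
        test="gait", side="L", participant_id=pid, fs=FS,
        start_s=0.0, end_s=n / FS, toe_off_s=0.25 * n / FS,
        mid_swing_s=0.5 * n / FS, heel_strike_s=0.75 * n / FS,
        shank_gyro=shank_gyro, shank_accel=accel + rng.normal(0, 1e-4, (n, 3)),
        thigh_gyro=thigh_gyro, thigh_accel=accel.copy(),
        trunk_accel=accel.copy(), trunk_gyro_ml=np.zeros(n),
        shank_gyro_ml_bp=np.asarray(shank_ml, dtype=float),
        thigh_gyro_ml_bp=np.asarray(thigh_ml, dtype=float))


class TestMeanCycle:
    def test_single_cycle_is_its_own_mean(self):
        c = make_cycle()
        ref = mean_cycle([c], "shank_ml")
        assert np.allclose(ref.waveform, resample_cycle(c.shank_gyro_ml_bp, 100))
        assert dtw_to_mean(c, ref) == pytest.approx(0.0, abs=1e-9)

    def test_opposite_cycles_cancel(self):
        x = np.sin(2 * np.pi * np.arange(200) / 200) * 80
        ref = mean_cycle([make_cycle(shank_ml=x), make_cycle(shank_ml=-x)],
                         "shank_ml")
        assert np.allclose(ref.waveform, 0.0, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_cycle([], "shank_ml")

    def test_degenerate_cohort_zero_distance(self, degenerate_cohort):
        # jitter-free, noise-free, fixed-duration cycles are identical
        p = degenerate_cohort.participants[0]
        seg = segment_participant(p)
        cycles = [c for c in seg.cycles["gait"] if c.side == "L"]
        assert len(cycles) >= 3
        ref = mean_cycle(cycles, "shank_ml")
        for c in cycles:
            assert dtw_to_mean(c, ref) == pytest.approx(0.0, abs=1e-6)

    def test_amplitude_scaling_increases_distance(self):
        rng = np.random.default_rng(5)
        cycles = [make_cycle(shank_ml=np.sin(2 * np.pi * np.arange(128) / 128)
                             * rng.uniform(60, 100)) for _ in range(4)]
        ref = mean_cycle(cycles, "shank_ml")
        base = dtw_to_mean(cycles[0], ref)
        doubled = make_cycle(shank_ml=2 * cycles[0].shank_gyro_ml_bp)
        assert dtw_to_mean(doubled, ref) > base


class TestHipAngle:
    def test_static_zero_range(self):
        n = 200
        zeros = np.zeros(n)
        accel = np.column_stack([np.ones(n), zeros, zeros])
        assert hip_flexion_extension_range(zeros, accel, zeros, accel, FS) \
            == pytest.approx(0.0, abs=1e-9)

    def test_oscillating_thigh_recovers_range(self):
        # thigh swings +-15 deg about a static pelvis -> range ~30 deg
        n = int(2 * FS)
        t = np.arange(n) / FS
        theta = 15.0 * np.sin(2 * np.pi * 1.0 * t)
        gyro = np.gradient(theta, 1 / FS)
        accel_thigh = np.column_stack([np.cos(np.deg2rad(theta)),
                                       np.zeros(n),
                                       np.sin(np.deg2rad(theta))])
        accel_pelvis = np.column_stack([np.ones(n), np.zeros(n), np.zeros(n)])
        rng_deg = hip_flexion_extension_range(gyro, accel_thigh,
                                              np.zeros(n), accel_pelvis, FS)
        assert rng_deg == pytest.approx(30.0, rel=0.10)

    def test_identical_motion_cancels(self):
        n = int(2 * FS)
        t = np.arange(n) / FS
        theta = 10.0 * np.sin(2 * np.pi * t)
        gyro = np.gradient(theta, 1 / FS)
        accel = np.column_stack([np.cos(np.deg2rad(theta)), np.zeros(n),
                                 np.sin(np.deg2rad(theta))])
        assert hip_flexion_extension_range(gyro, accel, gyro, accel, FS) \
            == pytest.approx(0.0, abs=0.5)

    def test_misaligned_slices_rejected(self):
        n = 100
        accel = np.column_stack([np.ones(n), np.zeros(n), np.zeros(n)])
        with pytest.raises(ValueError):
            hip_flexion_extension_range(np.zeros(n), accel,
                                        np.zeros(n - 5), accel[:-5], FS)


class TestCurvature:
    def test_circle_curvature_is_inverse_radius(self):
        r = 100.0
        t = np.arange(int(2 * FS)) / FS
        w = np.column_stack([r * np.cos(2 * np.pi * t),
                             r * np.sin(2 * np.pi * t),
                             np.zeros_like(t)])
        assert curvature_feature(w, FS) == pytest.approx(1 / r, rel=0.02)

    def test_straight_line_zero(self):
        t = np.arange(int(2 * FS)) / FS
        w = np.column_stack([10 * t, 5 * t, -2 * t])
        assert curvature_feature(w, FS) == pytest.approx(0.0, abs=1e-9)

    def test_constant_returns_zero(self):
        w = np.full((300, 3), 7.0)
        assert curvature_feature(w, FS) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            curvature_feature(np.zeros((4, 3)), FS)


class TestNormalizedJerk:
    def test_zero_range_zero(self):
        assert normalized_jerk(np.ones((100, 3)), FS) == 0.0

    def test_smoother_profile_scores_lower(self):
        t = np.arange(int(2 * FS)) / FS
        smooth = np.column_stack([1 + 0.1 * np.sin(2 * np.pi * t),
                                  np.zeros_like(t), np.zeros_like(t)])
        rough = smooth.copy()
        rough[:, 0] += 0.05 * np.sin(2 * np.pi * 20 * t)
        assert normalized_jerk(smooth, FS) < normalized_jerk(rough, FS)


class TestSpatiotemporal:
    def test_duration_and_cadence(self):
        c = make_cycle(n=int(1.2 * FS))
        vals, _ = spatiotemporal_features(c, None)
        assert vals["G_STRIDE_T"] == pytest.approx(1.2, abs=1 / FS)
        assert vals["G_CADENCE"] == pytest.approx(100.0, rel=0.01)

    def test_zero_rotation_zero_length(self):
        c = make_cycle(shank_ml=np.zeros(256), thigh_ml=np.zeros(256))
        vals, _ = spatiotemporal_features(c, None)
        assert vals["G_STRIDE_LEN"] == 0.0

    def test_generator_stride_length_recovered(self, degenerate_cohort):
        p = degenerate_cohort.participants[0]
        seg = segment_participant(p)
        cycles = [c for c in seg.cycles["gait"] if c.side == "L"]
        truth = p.truth.events["gait"]["L"].stride_length_m
        assert len(cycles) >= 3
        cfg = FeatureConfig()
        for c in cycles[1:-1]:
            vals, _ = spatiotemporal_features(c, None, cfg)
            # compare against the ground-truth value for the matching cycle
            errs = np.abs(truth - vals["G_STRIDE_LEN"]) / truth
            assert errs.min() < 0.15


class TestRegularity:
    def test_periodic_signal_stride_regularity_one(self):
        # biased estimator scales by (n - lag)/n, so use a long signal
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        assert regularity(x, int(FS)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=int(30 * FS))
        assert abs(regularity(x, int(FS))) < 0.1

    def test_bad_lag_nan(self):
        assert np.isnan(regularity(np.zeros(100), 200))


class TestBuildFeatureRow:
    def _tables(self, cohort):
        feats = extract_cohort_features(cohort)
        pid = next(iter(feats))
        return pid, feats

    def test_row_has_36_named_values(self, tiny_cohort):
        pid, feats = self._tables(tiny_cohort)
        gait_df, tandem_df, group = feats[pid]
        row = build_feature_row(gait_df.iloc[0], tandem_df.iloc[0],
                                pid, pid, pid, group)
        assert set(ALL_FEATURES) <= set(row)
        assert len([k for k in row if k in ALL_FEATURES]) == 36

    def test_cross_participant_rejected(self, tiny_cohort):
        pid, feats = self._tables(tiny_cohort)
        gait_df, tandem_df, group = feats[pid]
        with pytest.raises(ValueError):
            build_feature_row(gait_df.iloc[0], tandem_df.iloc[0],
                              pid, pid, "someone_else", group)

    def test_nonfinite_rejected(self, tiny_cohort):
        pid, feats = self._tables(tiny_cohort)
        gait_df, tandem_df, group = feats[pid]
        bad = gait_df.iloc[0].copy()
        bad["G_RHFE"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            build_feature_row(bad, tandem_df.iloc[0], pid, pid, pid, group)

    def test_degenerate_cohort_variability_zero(self, degenerate_cohort):
        feats = extract_cohort_features(degenerate_cohort)
        for pid, (gait_df, tandem_df, _) in feats.items():
            assert gait_df["G_DIS_DTW_MEAN_SHANK"].abs().max() < 1e-6
            assert tandem_df["TG_DIS_DTW_MEAN_SHANK"].abs().max() < 1e-6
            assert gait_df["G_DEV_STRIDE_T"].abs().max() < 1e-9


class TestTableShape:
    def test_table_row_and_column_counts(self, tiny_cohort):
        table = cohort_feature_table(tiny_cohort, seed=0)
        assert len(table.df) == 10 * 6
        assert table.df.shape[1] == 36 + 2
        counts = table.df["participant_id"].value_counts()
        assert (counts == 10).all()


class TestJitterMonotonicity:
    def test_more_jitter_not_less_dtw(self):
        sizes = {"EOA": 1, "DCD": 1, "CTRL": 1}
        med = {}
        for j in (0.03, 0.15):
            spec = CohortSpec(group_sizes=sizes, waveform_jitter=j, seed=21)
            feats = extract_cohort_features(simulate_cohort(spec))
            vals = pd.concat([g["G_DIS_DTW_MEAN_SHANK"]
                              for g, _, _ in feats.values()])
            med[j] = vals.median()
        assert med[0.15] >= med[0.03]


def test_feature_dictionary_complete():
    d = feature_dictionary()
    assert set(d) == set(ALL_FEATURES)
    assert all("unit" in v and "test" in v for v in d.values())
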