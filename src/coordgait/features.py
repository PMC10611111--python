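"""The 36-feature catalog: 24 gait features and 12 tandem-gait features per
delineated cycle.

Variability features are unnormalized DTW distances of each cycle's
band-passed mediolateral gyro (linearly resampled to a fixed length) to the
participant's pointwise mean cycle.  Segment pitch angles come from a
complementary filter fusing mediolateral gyro integration with
accelerometer inclination; the hip flexion-extension angle is thigh pitch
minus pelvis pitch.  Curvature treats the 3-D angular-velocity vector over
time as a space curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dtw import dtw_distance
from .preprocess import AX_AP, AX_ML, AX_V
from .segmentation import GaitCycle, GaitEvents

__all__ = [
    "GAIT_FEATURES", "TANDEM_FEATURES", "ALL_FEATURES", "FeatureConfig",
    "dtw_distance", "resample_cycle", "mean_cycle", "dtw_to_mean",
    "complementary_pitch", "hip_flexion_extension_range", "curvature_feature",
    "normalized_jerk", "regularity", "spatiotemporal_features",
    "trunk_and_regularity_features", "build_feature_row",
    "extract_participant_features", "feature_dictionary",
]

GAIT_FEATURES = (
    "G_STRIDE_T", "G_STANCE_T", "G_SWING_T", "G_SWING_STANCE_RATIO",
    "G_CADENCE", "G_STRIDE_LEN", "G_STRIDE_VEL",
    "G_RNG_GYRO_ML_SHANK", "G_RNG_GYRO_ML_THIGH", "G_RHFE",
    "G_RNG_PITCH_SHANK", "G_RNG_PITCH_THIGH",
    "G_DIS_DTW_MEAN_SHANK", "G_DIS_DTW_MEAN_THIGH",
    "G_DEV_STRIDE_T", "G_DEV_STRIDE_LEN",
    "G_CURV_SHANK", "G_CURV_THIGH", "G_NJERK_SHANK",
    "G_STEP_REG", "G_STRIDE_REG", "G_SYM_REG",
    "G_RMS_ACC_V_TRUNK", "G_RMS_ACC_ML_TRUNK",
)

TANDEM_FEATURES = (
    "TG_CYCLE_T", "TG_RNG_GYRO_ML_SHANK", "TG_RNG_GYRO_ML_THIGH",
    "TG_DIS_DTW_MEAN_SHANK", "TG_DIS_DTW_MEAN_THIGH",
    "TG_CURV_SHANK", "TG_CURV_THIGH", "TG_DEV_CYCLE_T", "TG_NJERK_SHANK",
    "TG_RNG_PITCH_TRUNK", "TG_RMS_ACC_V_TRUNK", "TG_RMS_ACC_ML_TRUNK",
)

ALL_FEATURES = GAIT_FEATURES + TANDEM_FEATURES

_UNITS = {
    "STRIDE_T": "s", "STANCE_T": "s", "SWING_T": "s", "CYCLE_T": "s",
    "SWING_STANCE_RATIO": "-", "CADENCE": "steps/min", "STRIDE_LEN": "m",
    "STRIDE_VEL": "m/s", "RNG_GYRO_ML_SHANK": "dps", "RNG_GYRO_ML_THIGH": "dps",
    "RHFE": "deg", "RNG_PITCH_SHANK": "deg", "RNG_PITCH_THIGH": "deg",
    "RNG_PITCH_TRUNK": "deg", "DIS_DTW_MEAN_SHANK": "dps",
    "DIS_DTW_MEAN_THIGH": "dps", "DEV_STRIDE_T": "s", "DEV_STRIDE_LEN": "m",
    "DEV_CYCLE_T": "s", "CURV_SHANK": "1/dps", "CURV_THIGH": "1/dps",
    "NJERK_SHANK": "-", "STEP_REG": "-", "STRIDE_REG": "-", "SYM_REG": "-",
    "RMS_ACC_V_TRUNK": "g", "RMS_ACC_ML_TRUNK": "g",
}


@dataclass(frozen=True)
class FeatureConfig:
    resample_len: int = 100
    pitch_alpha: float = 0.98       # complementary-filter constant
    thigh_length_m: float = 0.40
    shank_length_m: float = 0.40
    speed_floor_frac: float = 0.01  # curvature mask threshold


def feature_dictionary() -> dict[str, dict[str, str]]:
    """Name -> {unit, test} for every catalog feature."""
    out = {}
    for name in ALL_FEATURES:
        stem = name.split("_", 1)[1]
        out[name] = {"unit": _UNITS[stem],
                     "test": "gait" if name.startswith("G_") else "tandem"}
    return out


# ---------------------------------------------------------------------------
# cycle-shape variability

def resample_cycle(x: np.ndarray, n: int = 100) -> np.ndarray:
    """Linear resampling of a cycle channel to a fixed length."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot resample an empty cycle")
    if x.size == 1:
        return np.full(n, x[0])
    return np.interp(np.linspace(0.0, 1.0, n),
                     np.linspace(0.0, 1.0, x.size), x)


# DTW variability is measured on the acquired (unfiltered) ML gyro so that
# identical cycles give exactly zero distance; the band-passed slices are
# reserved for event-related uses.
_CHANNELS = {
    "shank_ml": lambda c: c.shank_gyro[:, AX_ML],
    "thigh_ml": lambda c: c.thigh_gyro[:, AX_ML],
}


@dataclass(frozen=True)
class MeanCycle:
    channel: str
    waveform: np.ndarray  # fixed length, finite


def mean_cycle(cycles: list[GaitCycle], channel: str,
               resample_len: int = 100) -> MeanCycle:
    """Pointwise mean of length-normalized cycle waveforms."""
    if not cycles:
        raise ValueError("mean_cycle requires at least one cycle")
    getter = _CHANNELS[channel]
    stack = np.stack([resample_cycle(getter(c), resample_len) for c in cycles])
    return MeanCycle(channel, stack.mean(axis=0))


def dtw_to_mean(cycle: GaitCycle, ref: MeanCycle) -> float:
    """Unnormalized DTW distance of one cycle to the reference waveform."""
    x = resample_cycle(_CHANNELS[ref.channel](cycle), ref.waveform.size)
    return dtw_distance(x, ref.waveform)


# ---------------------------------------------------------------------------
# segment angles

def complementary_pitch(gyro_ml_dps: np.ndarray, accel: np.ndarray, fs: float,
                        alpha: float = 0.98) -> np.ndarray:
    """Segment pitch (deg) fusing ML gyro integration with the accelerometer
    inclination atan2(AP, V)."""
    g = np.asarray(gyro_ml_dps, dtype=float)
    a = np.asarray(accel, dtype=float)
    incl = np.degrees(np.arctan2(a[:, AX_AP], a[:, AX_V]))
    dt = 1.0 / fs
    pitch = np.empty_like(g)
    pitch[0] = incl[0]
    for i in range(1, g.size):
        pitch[i] = alpha * (pitch[i - 1] + g[i] * dt) + (1.0 - alpha) * incl[i]
    return pitch


def hip_flexion_extension_range(thigh_gyro_ml: np.ndarray,
                                thigh_accel: np.ndarray,
                                pelvis_gyro_ml: np.ndarray,
                                pelvis_accel: np.ndarray,
                                fs: float, alpha: float = 0.98) -> float:
    """Range (deg) of thigh pitch minus pelvis pitch over one cycle."""
    if abs(thigh_gyro_ml.shape[0] - pelvis_gyro_ml.shape[0]) > 1:
        raise ValueError("thigh and pelvis cycle slices are misaligned")
    n = min(thigh_gyro_ml.shape[0], pelvis_gyro_ml.shape[0])
    thigh = complementary_pitch(thigh_gyro_ml[:n], thigh_accel[:n], fs, alpha)
    pelvis = complementary_pitch(pelvis_gyro_ml[:n], pelvis_accel[:n], fs, alpha)
    hip = thigh - pelvis
    return float(hip.max() - hip.min())


# ---------------------------------------------------------------------------
# smoothness / curvature

def curvature_feature(gyro3: np.ndarray, fs: float,
                      speed_floor_frac: float = 0.01) -> float:
    """Median local curvature of the 3-D angular-velocity space curve.

    kappa = |w' x w''| / |w'|^3 with central differences; samples where the
    speed |w'| falls below ``speed_floor_frac`` of its cycle maximum are
    masked out.  Degenerate (near-constant) cycles return 0.
    """
    w = np.asarray(gyro3, dtype=float)
    if w.shape[0] < 5:
        raise ValueError("curvature needs at least 5 samples")
    d1 = np.gradient(w, 1.0 / fs, axis=0)
    d2 = np.gradient(d1, 1.0 / fs, axis=0)
    speed = np.linalg.norm(d1, axis=1)
    floor = speed_floor_frac * speed.max()
    if speed.max() == 0.0:
        return 0.0
    mask = speed > floor
    if not mask.any():
        return 0.0
    cross = np.cross(d1[mask], d2[mask])
    kappa = np.linalg.norm(cross, axis=1) / speed[mask] ** 3
    return float(np.median(kappa))


def normalized_jerk(accel3: np.ndarray, fs: float) -> float:
    """Dimensionless jerk of the acceleration-magnitude profile.

    rms(d|a|/dt) * T / range(|a|): duration- and amplitude-normalized, so a
    smoother profile scores lower.  Zero-range profiles return 0.
    """
    a = np.linalg.norm(np.asarray(accel3, dtype=float), axis=1)
    rng = a.max() - a.min()
    if rng == 0.0 or a.size < 3:
        return 0.0
    d = np.gradient(a, 1.0 / fs)
    T = a.size / fs
    return float(np.sqrt(np.mean(d * d)) * T / rng)


# ---------------------------------------------------------------------------
# spatiotemporal

def step_time_from_contralateral(mid_swing_s: float,
                                 contra: GaitEvents | None) -> float | None:
    """Time from this side's mid-swing to the next contralateral mid-swing."""
    if contra is None or contra.n_peaks == 0:
        return None
    later = contra.mid_swing[contra.mid_swing > mid_swing_s]
    if later.size == 0:
        return None
    return float(later[0] - mid_swing_s)


def stride_length_estimate(cycle: GaitCycle, thigh_m: float,
                           shank_m: float) -> float:
    """Double-pendulum chord sum over the swing: segment rotation angles are
    the time-integrals of the (raw) ML gyro between toe-off and heel-strike."""
    fs = cycle.fs
    j0 = max(int(round((cycle.toe_off_s - cycle.start_s) * fs)), 0)
    j1 = min(int(round((cycle.heel_strike_s - cycle.start_s) * fs)),
             cycle.n - 1)
    if j1 <= j0:
        return 0.0
    dt = 1.0 / fs
    th = np.trapezoid(cycle.thigh_gyro[j0:j1 + 1, AX_ML], dx=dt)
    sh = np.trapezoid(cycle.shank_gyro[j0:j1 + 1, AX_ML], dx=dt)
    a = abs(np.deg2rad(th))
    b = abs(np.deg2rad(sh))
    return float(2.0 * (thigh_m * np.sin(min(a, np.pi) / 2.0)
                        + shank_m * np.sin(min(b, np.pi) / 2.0)))


def spatiotemporal_features(cycle: GaitCycle,
                            contralateral_events: GaitEvents | None,
                            cfg: FeatureConfig = FeatureConfig()
                            ) -> tuple[dict[str, float], bool]:
    """Temporal and pendulum-model spatial features for one gait cycle.

    Returns (values, used_fallback); the fallback flag is set when the
    contralateral event stream could not supply a step time.
    """
    stride_t = cycle.duration_s
    stance_t = cycle.toe_off_s - cycle.start_s
    swing_t = cycle.heel_strike_s - cycle.toe_off_s
    stride_len = stride_length_estimate(cycle, cfg.thigh_length_m,
                                        cfg.shank_length_m)
    step_t = step_time_from_contralateral(cycle.mid_swing_s,
                                          contralateral_events)
    fallback = step_t is None or not (0.0 < step_t < stride_t)
    if fallback:
        step_t = stride_t / 2.0
    vals = {
        "G_STRIDE_T": stride_t,
        "G_STANCE_T": stance_t,
        "G_SWING_T": swing_t,
        "G_SWING_STANCE_RATIO": swing_t / stance_t if stance_t > 0 else np.nan,
        "G_CADENCE": 120.0 / stride_t,
        "G_STRIDE_LEN": stride_len,
        "G_STRIDE_VEL": stride_len / stride_t,
        "_STEP_T": step_t,
    }
    return vals, fallback


# ---------------------------------------------------------------------------
# trunk and regularity

def regularity(x: np.ndarray, lag_samples: int) -> float:
    """Biased, r(0)-normalized autocorrelation of a demeaned signal at a lag."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0 or not (0 < lag_samples < x.size):
        return np.nan
    return float(np.dot(x[:-lag_samples], x[lag_samples:]) / denom)


def trunk_and_regularity_features(cycle: GaitCycle,
                                  full_trunk_v: np.ndarray,
                                  step_t: float,
                                  prefix: str = "G") -> dict[str, float]:
    """Within-cycle trunk RMS plus test-long step/stride regularity.

    Raises ValueError when the test-long trunk signal is shorter than two
    strides (regularity undefined).
    """
    fs = cycle.fs
    stride_lag = int(round(cycle.duration_s * fs))
    if full_trunk_v.size < 2 * stride_lag:
        raise ValueError("test-long trunk signal shorter than 2 strides")
    acc_v = cycle.trunk_accel[:, AX_V]
    acc_ml = cycle.trunk_accel[:, AX_ML]
    step_reg = regularity(full_trunk_v, int(round(step_t * fs)))
    stride_reg = regularity(full_trunk_v, stride_lag)
    sym = step_reg / stride_reg if stride_reg not in (0.0,) and \
        np.isfinite(stride_reg) and abs(stride_reg) > 1e-12 else np.nan
    return {
        f"{prefix}_RMS_ACC_V_TRUNK": float(np.sqrt(np.mean((acc_v - acc_v.mean()) ** 2))),
        f"{prefix}_RMS_ACC_ML_TRUNK": float(np.sqrt(np.mean((acc_ml - acc_ml.mean()) ** 2))),
        f"{prefix}_STEP_REG": step_reg,
        f"{prefix}_STRIDE_REG": stride_reg,
        f"{prefix}_SYM_REG": sym,
    }


# ---------------------------------------------------------------------------
# per-cycle assembly

def _range(x: np.ndarray) -> float:
    return float(np.max(x) - np.min(x))


def gait_cycle_features(cycle: GaitCycle, refs: dict[str, MeanCycle],
                        contralateral_events: GaitEvents | None,
                        full_trunk_v: np.ndarray,
                        cfg: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """All per-cycle gait features except the participant-level deviation
    features (added at table-assembly time)."""
    st, _ = spatiotemporal_features(cycle, contralateral_events, cfg)
    step_t = st.pop("_STEP_T")
    vals = dict(st)
    vals["G_RNG_GYRO_ML_SHANK"] = _range(cycle.shank_gyro[:, AX_ML])
    vals["G_RNG_GYRO_ML_THIGH"] = _range(cycle.thigh_gyro[:, AX_ML])
    vals["G_RHFE"] = hip_flexion_extension_range(
        cycle.thigh_gyro[:, AX_ML], cycle.thigh_accel,
        cycle.trunk_gyro_ml, cycle.trunk_accel, cycle.fs, cfg.pitch_alpha)
    vals["G_RNG_PITCH_SHANK"] = _range(complementary_pitch(
        cycle.shank_gyro[:, AX_ML], cycle.shank_accel, cycle.fs,
        cfg.pitch_alpha))
    vals["G_RNG_PITCH_THIGH"] = _range(complementary_pitch(
        cycle.thigh_gyro[:, AX_ML], cycle.thigh_accel, cycle.fs,
        cfg.pitch_alpha))
    vals["G_DIS_DTW_MEAN_SHANK"] = dtw_to_mean(cycle, refs["shank_ml"])
    vals["G_DIS_DTW_MEAN_THIGH"] = dtw_to_mean(cycle, refs["thigh_ml"])
    vals["G_CURV_SHANK"] = curvature_feature(cycle.shank_gyro, cycle.fs,
                                             cfg.speed_floor_frac)
    vals["G_CURV_THIGH"] = curvature_feature(cycle.thigh_gyro, cycle.fs,
                                             cfg.speed_floor_frac)
    vals["G_NJERK_SHANK"] = normalized_jerk(cycle.shank_accel, cycle.fs)
    vals.update(trunk_and_regularity_features(cycle, full_trunk_v, step_t, "G"))
    return vals


def tandem_cycle_features(cycle: GaitCycle, refs: dict[str, MeanCycle],
                          full_trunk_v: np.ndarray,
                          cfg: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    acc_v = cycle.trunk_accel[:, AX_V]
    acc_ml = cycle.trunk_accel[:, AX_ML]
    vals = {
        "TG_CYCLE_T": cycle.duration_s,
        "TG_RNG_GYRO_ML_SHANK": _range(cycle.shank_gyro[:, AX_ML]),
        "TG_RNG_GYRO_ML_THIGH": _range(cycle.thigh_gyro[:, AX_ML]),
        "TG_DIS_DTW_MEAN_SHANK": dtw_to_mean(cycle, refs["shank_ml"]),
        "TG_DIS_DTW_MEAN_THIGH": dtw_to_mean(cycle, refs["thigh_ml"]),
        "TG_CURV_SHANK": curvature_feature(cycle.shank_gyro, cycle.fs,
                                           cfg.speed_floor_frac),
        "TG_CURV_THIGH": curvature_feature(cycle.thigh_gyro, cycle.fs,
                                           cfg.speed_floor_frac),
        "TG_NJERK_SHANK": normalized_jerk(cycle.shank_accel, cycle.fs),
        "TG_RNG_PITCH_TRUNK": _range(complementary_pitch(
            cycle.trunk_gyro_ml, cycle.trunk_accel, cycle.fs, cfg.pitch_alpha)),
        "TG_RMS_ACC_V_TRUNK": float(np.sqrt(np.mean((acc_v - acc_v.mean()) ** 2))),
        "TG_RMS_ACC_ML_TRUNK": float(np.sqrt(np.mean((acc_ml - acc_ml.mean()) ** 2))),
    }
    return vals


def extract_participant_features(
        gait_cycles: list[GaitCycle], tandem_cycles: list[GaitCycle],
        trunk_v_gait: np.ndarray, trunk_v_tandem: np.ndarray,
        contralateral: dict[str, GaitEvents] | None = None,
        cfg: FeatureConfig = FeatureConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cycle feature tables (gait: 24 columns, tandem: 12) for one
    participant, deviation features included."""
    if not gait_cycles or not tandem_cycles:
        raise ValueError("participant needs at least one usable cycle per test")
    refs_g = {ch: mean_cycle(gait_cycles, ch, cfg.resample_len)
              for ch in ("shank_ml", "thigh_ml")}
    refs_t = {ch: mean_cycle(tandem_cycles, ch, cfg.resample_len)
              for ch in ("shank_ml", "thigh_ml")}
    contralateral = contralateral or {}

    g_rows = []
    for c in gait_cycles:
        contra = contralateral.get("R" if c.side == "L" else "L")
        g_rows.append(gait_cycle_features(c, refs_g, contra, trunk_v_gait, cfg))
    gait_df = pd.DataFrame(g_rows)
    gait_df["G_DEV_STRIDE_T"] = (gait_df["G_STRIDE_T"]
                                 - gait_df["G_STRIDE_T"].mean()).abs()
    gait_df["G_DEV_STRIDE_LEN"] = (gait_df["G_STRIDE_LEN"]
                                   - gait_df["G_STRIDE_LEN"].mean()).abs()
    gait_df = gait_df[list(GAIT_FEATURES)]

    t_rows = [tandem_cycle_features(c, refs_t, trunk_v_tandem, cfg)
              for c in tandem_cycles]
    tandem_df = pd.DataFrame(t_rows)
    tandem_df["TG_DEV_CYCLE_T"] = (tandem_df["TG_CYCLE_T"]
                                   - tandem_df["TG_CYCLE_T"].mean()).abs()
    tandem_df = tandem_df[list(TANDEM_FEATURES)]
    return gait_df, tandem_df


def build_feature_row(gait_values: dict[str, float] | pd.Series,
                      tandem_values: dict[str, float] | pd.Series,
                      participant_id: str, gait_participant: str,
                      tandem_participant: str, group: str) -> dict:
    """Assemble one 'combined movement' row: 24 gait + 12 tandem values."""
    if gait_participant != participant_id or tandem_participant != participant_id:
        raise ValueError("gait and tandem cycles must come from the same participant")
    row: dict = {"participant_id": participant_id, "group": group}
    for name in GAIT_FEATURES:
        row[name] = float(gait_values[name])
    for name in TANDEM_FEATURES:
        row[name] = float(tandem_values[name])
    bad = [k for k in ALL_FEATURES if not np.isfinite(row[k])]
    if bad:
        raise ValueError(f"non-finite feature values: {bad}")
    return row


def write_feature_dictionary(path) -> None:
    with open(path, "w") as fh:
        json.dump(feature_dictionary(), fh, indent=1)
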