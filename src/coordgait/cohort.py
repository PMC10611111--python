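"""Synthetic multi-sensor IMU cohorts with known ground-truth gait events.

Each participant gets six sensor recordings (sternum, L3, both thighs, both
shanks) per test (gait, tandem).  The shank mediolateral angular velocity is
a concatenation of template cycles - a positive mid-swing lobe flanked by
two negative valleys (toe-off before, heel-strike after) - with per-cycle
duration drawn from a lognormal and per-cycle shape perturbations scaled by
a group-specific jitter.  Thigh channels follow a sagittal pendulum angle
whose per-cycle excursion is the group's hip-range parameter; trunk
channels are a low-pass mixture of the two shank signals.  All generating
event times, per-cycle stride lengths and hip-angle ranges are recorded as
ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import AX_AP, AX_ML, AX_V, ImuRecording

GROUPS = ("EOA", "DCD", "CTRL")

# template landmark phases within one cycle segment
PHASE_TO, PHASE_MS, PHASE_HS = 0.15, 0.40, 0.65
VALLEY_DEPTH = 0.35          # valley amplitude relative to mid-swing peak
LOBE_HALF_WIDTH = 0.15       # mid-swing lobe half-width (phase units)
VALLEY_HALF_WIDTH = 0.07     # valley half-width (phase units)
LEAD_S = 0.5                 # quiet lead-in/out around the cycle train


def _per_group(value) -> dict[str, float]:
    if isinstance(value, dict):
        return {g: float(value[g]) for g in GROUPS}
    return {g: float(value) for g in GROUPS}


@dataclass
class CohortSpec:
    """Generator configuration; all per-group fields map group -> value."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"EOA": 18, "DCD": 13, "CTRL": 29})
    cycle_duration_mean: dict[str, float] = field(
        default_factory=lambda: {"EOA": 1.15, "DCD": 1.10, "CTRL": 1.05})
    cycle_duration_cv: dict[str, float] = field(
        default_factory=lambda: {"EOA": 0.05, "DCD": 0.04, "CTRL": 0.03})
    amplitude_mean: dict[str, float] = field(
        default_factory=lambda: {"EOA": 170.0, "DCD": 190.0, "CTRL": 210.0})
    waveform_jitter: dict[str, float] = field(
        default_factory=lambda: {"EOA": 0.12, "DCD": 0.07, "CTRL": 0.03})
    hip_range_mean: dict[str, float] = field(
        default_factory=lambda: {"EOA": 38.0, "DCD": 32.0, "CTRL": 27.0})
    gyro_noise_sd: float = 1.5       # dps per channel
    accel_noise_sd: float = 0.015    # g per channel
    n_cycles_gait: int = 12
    n_cycles_tandem: int = 12
    fs: float = 256.0
    seed: int = 0
    tandem_duration_factor: float = 1.3
    tandem_amplitude_factor: float = 0.6
    tandem_jitter_factor: float = 1.5
    thigh_length_m: float = 0.40
    shank_length_m: float = 0.40

    def __post_init__(self) -> None:
        for name in ("group_sizes", "cycle_duration_mean", "cycle_duration_cv",
                     "amplitude_mean", "waveform_jitter", "hip_range_mean"):
            setattr(self, name, _per_group(getattr(self, name)))
        self.group_sizes = {g: int(v) for g, v in self.group_sizes.items()}
        self.validate()

    def validate(self) -> None:
        if any(v < 1 for v in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 1")
        if any(v <= 0 for v in self.cycle_duration_mean.values()):
            raise ValueError("cycle_duration_mean must be positive")
        if any(v < 0 for v in self.cycle_duration_cv.values()):
            raise ValueError("cycle_duration_cv must be nonnegative")
        if any(v < 0 for v in self.waveform_jitter.values()):
            raise ValueError("waveform_jitter must be nonnegative")
        if self.gyro_noise_sd < 0 or self.accel_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.n_cycles_gait < 1 or self.n_cycles_tandem < 1:
            raise ValueError("cycle counts must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @classmethod
    def default(cls) -> "CohortSpec":
        return cls()

    @classmethod
    def degenerate(cls, **overrides) -> "CohortSpec":
        """Noise-free, jitter-free, fixed-duration cycles: every cycle is an
        exact repetition of the template.

        Cycle durations are whole multiples of the decimation block (16
        samples at 256 Hz) so detected cycle boundaries fall on the same
        within-cycle sample for every cycle.
        """
        kw = dict(
            cycle_duration_cv={g: 0.0 for g in GROUPS},
            waveform_jitter={g: 0.0 for g in GROUPS},
            gyro_noise_sd=0.0,
            accel_noise_sd=0.0,
            cycle_duration_mean={g: 1.0 for g in GROUPS},
            tandem_duration_factor=1.25,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def parameter_recovery(cls, n_per_group: dict[str, int] | None = None,
                           seed: int = 0) -> "CohortSpec":
        """Groups separated only by waveform jitter (3x / 2x / 1x) and
        hip-range offsets; all other parameters shared."""
        sizes = n_per_group or {"EOA": 12, "DCD": 10, "CTRL": 14}
        base = 0.05
        return cls(
            group_sizes=sizes,
            cycle_duration_mean=1.10,
            cycle_duration_cv=0.03,
            amplitude_mean=200.0,
            waveform_jitter={"EOA": 3 * base, "DCD": 2 * base, "CTRL": base},
            hip_range_mean={"EOA": 40.0, "DCD": 33.0, "CTRL": 26.0},
            seed=seed,
        )

    @classmethod
    def null(cls, n_per_group: dict[str, int] | None = None,
             seed: int = 0) -> "CohortSpec":
        """Identical generator parameters for all groups (chance-level)."""
        sizes = n_per_group or {"EOA": 8, "DCD": 6, "CTRL": 10}
        return cls(
            group_sizes=sizes,
            cycle_duration_mean=1.10,
            cycle_duration_cv=0.04,
            amplitude_mean=200.0,
            waveform_jitter=0.07,
            hip_range_mean=32.0,
            seed=seed,
        )


@dataclass
class SideTruth:
    """Ground truth for one test/side: generating event times and per-cycle
    spatial quantities (stride length over each delineated cycle's swing,
    hip-angle excursion over each cycle)."""

    toe_off: np.ndarray
    mid_swing: np.ndarray
    heel_strike: np.ndarray
    stride_length_m: np.ndarray
    hip_range_deg: np.ndarray

    def validate(self) -> None:
        for arr in (self.toe_off, self.mid_swing, self.heel_strike):
            if (np.diff(arr) <= 0).any():
                raise ValueError("event lists must be strictly increasing")
        if not ((self.toe_off < self.mid_swing).all()
                and (self.mid_swing < self.heel_strike).all()):
            raise ValueError("event ordering toe-off < mid-swing < heel-strike violated")


@dataclass
class GroundTruth:
    """events[test][side] -> SideTruth."""

    events: dict[str, dict[str, SideTruth]]

    def to_json(self) -> str:
        payload = {
            test: {
                side: {k: np.asarray(v).tolist()
                       for k, v in dataclasses.asdict(st).items()}
                for side, st in sides.items()
            }
            for test, sides in self.events.items()
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls({
            test: {side: SideTruth(**{k: np.asarray(v) for k, v in st.items()})
                   for side, st in sides.items()}
            for test, sides in raw.items()
        })


@dataclass
class Participant:
    participant_id: str
    group: str
    recordings: dict[str, dict[str, ImuRecording]]  # test -> site -> recording
    truth: GroundTruth


@dataclass
class Cohort:
    spec: CohortSpec
    participants: list[Participant]

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"participant_id": [p.participant_id for p in self.participants],
             "group": [p.group for p in self.participants],
             "age": [np.nan] * len(self.participants)}
        )


def _raised_cos(phase: np.ndarray, center: float, half_width: float,
                amp: float) -> np.ndarray:
    d = (phase - center) / half_width
    out = np.zeros_like(phase)
    m = np.abs(d) < 1.0
    out[m] = amp * 0.5 * (1.0 + np.cos(np.pi * d[m]))
    return out


def _lognormal_durations(rng: np.random.Generator, mean: float, cv: float,
                         n: int) -> np.ndarray:
    if cv == 0.0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _side_seed(spec: CohortSpec, pidx: int, test: str, stream: int
               ) -> np.random.Generator:
    # stable sub-seeding: one independent stream per participant/test/signal
    key = (pidx, 0 if test == "gait" else 1, stream)
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=key))


def _simulate_side(spec: CohortSpec, group: str, rng: np.random.Generator,
                   test: str, n_total: int, start_sample: int, n_cycles: int):
    """Shank ML gyro cycle train + thigh pitch trajectory for one side.

    Returns (shank_ml, theta_deg, truth) on the common n_total grid.
    """
    fs = spec.fs
    dur_mean = spec.cycle_duration_mean[group]
    amp = spec.amplitude_mean[group]
    jit = spec.waveform_jitter[group]
    hip_range = spec.hip_range_mean[group]
    if test == "tandem":
        dur_mean *= spec.tandem_duration_factor
        amp *= spec.tandem_amplitude_factor
        jit *= spec.tandem_jitter_factor

    durations = _lognormal_durations(rng, dur_mean, spec.cycle_duration_cv[group],
                                     n_cycles)
    n_samp = np.maximum(np.round(durations * fs).astype(int),
                        int(0.5 * dur_mean * fs))

    shank = np.zeros(n_total)
    theta = np.zeros(n_total)   # thigh pitch, degrees
    to, ms, hs, hips = [], [], [], []
    s = start_sample
    for i in range(n_cycles):
        n_i = n_samp[i]
        if s + n_i > n_total:
            break
        phase = np.arange(n_i) / n_i
        z = rng.standard_normal(6) if jit > 0 else np.zeros(6)
        a_i = amp * (1.0 + jit * z[0])
        v1 = VALLEY_DEPTH * amp * (1.0 + jit * z[1])
        v2 = VALLEY_DEPTH * amp * (1.0 + jit * z[2])
        wl = LOBE_HALF_WIDTH * (1.0 + 0.5 * jit * z[3])
        r_i = hip_range * (1.0 + jit * z[4])
        cyc = (_raised_cos(phase, PHASE_MS, wl, a_i)
               - _raised_cos(phase, PHASE_TO, VALLEY_HALF_WIDTH, v1)
               - _raised_cos(phase, PHASE_HS, VALLEY_HALF_WIDTH, v2))
        shank[s:s + n_i] += cyc
        # thigh pitch: zero-mean sinusoid, continuous across cycle borders
        theta[s:s + n_i] = 0.5 * r_i * np.sin(2.0 * np.pi * phase)
        to.append((s + PHASE_TO * n_i) / fs)
        ms.append((s + PHASE_MS * n_i) / fs)
        hs.append((s + PHASE_HS * n_i) / fs)
        hips.append(r_i)
        s += n_i

    to, ms, hs = np.asarray(to), np.asarray(ms), np.asarray(hs)

    # ground-truth stride length for each delineated cycle i (between event
    # triplets i and i+1): double-pendulum chord sum over the swing
    # [toe-off, heel-strike] of triplet i+1, from the noise-free signals.
    stride = []
    t_grid = np.arange(n_total) / fs
    dtheta = np.gradient(theta, 1.0 / fs)
    for i in range(len(ms) - 1):
        j0 = int(round(to[i + 1] * fs))
        j1 = int(round(hs[i + 1] * fs))
        stride.append(stride_length_pendulum(
            np.trapezoid(dtheta[j0:j1 + 1], t_grid[j0:j1 + 1]),
            np.trapezoid(shank[j0:j1 + 1], t_grid[j0:j1 + 1]),
            spec.thigh_length_m, spec.shank_length_m))
    # hip-angle excursion over each delineated gait cycle (heel-strike to
    # heel-strike window; tandem uses toe-off to toe-off)
    hip_rng = []
    bounds = hs if test == "gait" else to
    for i in range(len(bounds) - 1):
        j0 = int(round(bounds[i] * fs))
        j1 = int(round(bounds[i + 1] * fs))
        seg = theta[j0:j1 + 1]
        hip_rng.append(float(seg.max() - seg.min()))

    truth = SideTruth(to, ms, hs, np.asarray(stride), np.asarray(hip_rng))
    truth.validate()
    return shank, theta, truth


def stride_length_pendulum(dtheta_thigh_deg: float, dtheta_shank_deg: float,
                           thigh_m: float, shank_m: float) -> float:
    """Chord-sum stride length from segment rotation angles over swing."""
    a = abs(np.deg2rad(dtheta_thigh_deg))
    b = abs(np.deg2rad(dtheta_shank_deg))
    return float(2.0 * (thigh_m * np.sin(min(a, np.pi) / 2.0)
                        + shank_m * np.sin(min(b, np.pi) / 2.0)))


def _lowpass(x: np.ndarray, fs: float, fc: float = 3.0) -> np.ndarray:
    sos = sps.butter(2, fc, btype="lowpass", fs=fs, output="sos")
    return np.asarray(sps.sosfiltfilt(sos, x))


def _noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(shape)
    return rng.normal(0.0, sd, size=shape)


def simulate_participant(spec: CohortSpec, group: str, participant_id: str,
                         pidx: int) -> tuple[dict[str, dict[str, ImuRecording]],
                                             GroundTruth]:
    """Six recordings per test plus the generating ground truth.

    ``pidx`` is the participant's slot in the cohort and anchors the
    deterministic sub-seeding (same spec.seed -> bit-identical signals).
    """
    if group not in spec.group_sizes:
        raise ValueError(f"unknown group {group!r}")
    fs = spec.fs
    recordings: dict[str, dict[str, ImuRecording]] = {}
    truth_events: dict[str, dict[str, SideTruth]] = {}

    for test in ("gait", "tandem"):
        n_cycles = spec.n_cycles_gait if test == "gait" else spec.n_cycles_tandem
        dur = spec.cycle_duration_mean[group]
        if test == "tandem":
            dur *= spec.tandem_duration_factor
        lead = int(round(LEAD_S * fs))
        half = int(round(0.5 * dur * fs))
        # grid long enough for both sides incl. jitter headroom and tail lead
        n_total = int(lead + half + (n_cycles * dur * fs) * 1.6 + lead)

        rng_L = _side_seed(spec, pidx, test, 0)
        rng_R = _side_seed(spec, pidx, test, 1)
        shank_L, theta_L, truth_L = _simulate_side(
            spec, group, rng_L, test, n_total, lead, n_cycles)
        shank_R, theta_R, truth_R = _simulate_side(
            spec, group, rng_R, test, n_total, lead + half, n_cycles)
        truth_events[test] = {"L": truth_L, "R": truth_R}

        t = np.arange(n_total) / fs
        amp_ref = max(spec.amplitude_mean[group], 1e-9)
        recs: dict[str, ImuRecording] = {}

        for side, shank_ml, theta in (("L", shank_L, theta_L),
                                      ("R", shank_R, theta_R)):
            nz = _side_seed(spec, pidx, test, 2 if side == "L" else 3)
            # shank gyro: ML template train; V/AP small correlated residue
            gyro = np.zeros((n_total, 3))
            gyro[:, AX_ML] = shank_ml + _noise(nz, spec.gyro_noise_sd, n_total)
            gyro[:, AX_V] = 0.15 * shank_ml + _noise(nz, spec.gyro_noise_sd, n_total)
            gyro[:, AX_AP] = 0.10 * shank_ml + _noise(nz, spec.gyro_noise_sd, n_total)
            # pendulum-consistent accel: gravity baseline on the vertical axis
            dml = np.gradient(shank_ml, 1.0 / fs)
            accel = np.zeros((n_total, 3))
            accel[:, AX_V] = 1.0 + 0.04 * shank_ml / amp_ref \
                + _noise(nz, spec.accel_noise_sd, n_total)
            accel[:, AX_ML] = _noise(nz, spec.accel_noise_sd, n_total)
            accel[:, AX_AP] = 0.03 * dml / (amp_ref * 2.0 * np.pi / dur) \
                + _noise(nz, spec.accel_noise_sd, n_total)
            recs[f"shank_{side}"] = ImuRecording(f"shank_{side}", test, fs, t,
                                                 accel, gyro)

            # thigh: ML gyro is the pitch derivative; accel encodes inclination
            nz = _side_seed(spec, pidx, test, 4 if side == "L" else 5)
            th_rad = np.deg2rad(theta)
            gyro_t = np.zeros((n_total, 3))
            gyro_t[:, AX_ML] = np.gradient(theta, 1.0 / fs) \
                + _noise(nz, spec.gyro_noise_sd, n_total)
            gyro_t[:, AX_V] = _noise(nz, spec.gyro_noise_sd, n_total)
            gyro_t[:, AX_AP] = _noise(nz, spec.gyro_noise_sd, n_total)
            accel_t = np.zeros((n_total, 3))
            accel_t[:, AX_V] = np.cos(th_rad) + _noise(nz, spec.accel_noise_sd, n_total)
            accel_t[:, AX_AP] = np.sin(th_rad) + _noise(nz, spec.accel_noise_sd, n_total)
            accel_t[:, AX_ML] = _noise(nz, spec.accel_noise_sd, n_total)
            recs[f"thigh_{side}"] = ImuRecording(f"thigh_{side}", test, fs, t,
                                                 accel_t, gyro_t)

        # trunk sites: low-pass mixture of both shank trains + own noise;
        # pelvis pitch is kept near zero so the hip angle tracks the thigh
        summed = _lowpass(shank_L + shank_R, fs)
        diff = _lowpass(shank_L - shank_R, fs)
        for stream, site, gain in ((6, "L3", 0.04), (7, "sternum", 0.03)):
            nz = _side_seed(spec, pidx, test, stream)
            accel_k = np.zeros((n_total, 3))
            accel_k[:, AX_V] = 1.0 + gain * summed / amp_ref \
                + _noise(nz, spec.accel_noise_sd, n_total)
            accel_k[:, AX_ML] = 0.75 * gain * diff / amp_ref \
                + _noise(nz, spec.accel_noise_sd, n_total)
            accel_k[:, AX_AP] = _noise(nz, spec.accel_noise_sd, n_total)
            gyro_k = _noise(nz, spec.gyro_noise_sd, (n_total, 3))
            recs[site] = ImuRecording(site, test, fs, t, accel_k, gyro_k)

        recordings[test] = recs

    return recordings, GroundTruth(truth_events)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """One participant per requested slot; deterministic given spec.seed."""
    spec.validate()
    participants = []
    pidx = 0
    for group in GROUPS:
        for k in range(spec.group_sizes.get(group, 0)):
            pid = f"{group}{k + 1:02d}"
            recs, truth = simulate_participant(spec, group, pid, pidx)
            participants.append(Participant(pid, group, recs, truth))
            pidx += 1
    return Cohort(spec, participants)


# ---------------------------------------------------------------------------
# plain-text cohort I/O (one CSV per sensor per test + manifest + truth JSON)

_COLUMNS = ["t_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps"]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.participants:
        pdir = out / p.participant_id
        pdir.mkdir(exist_ok=True)
        files = {}
        for test, recs in p.recordings.items():
            for site, rec in recs.items():
                path = pdir / f"{test}_{site}.csv"
                df = pd.DataFrame(
                    np.column_stack([rec.t, rec.accel, rec.gyro]),
                    columns=_COLUMNS)
                df.to_csv(path, index=False, float_format="%.6f")
                files[f"{test}_{site}"] = str(path.relative_to(out))
        (pdir / "ground_truth.json").write_text(p.truth.to_json())
        rows.append({"participant_id": p.participant_id, "group": p.group,
                     "age": "", **files})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out


def load_cohort(in_dir: str | Path, fs: float = 256.0) -> Cohort:
    root = Path(in_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    participants = []
    for _, row in manifest.iterrows():
        pid, group = str(row["participant_id"]), str(row["group"])
        recordings: dict[str, dict[str, ImuRecording]] = {"gait": {}, "tandem": {}}
        for key, rel in row.items():
            if key in ("participant_id", "group", "age") or not isinstance(rel, str):
                continue
            test, site = key.split("_", 1)
            df = pd.read_csv(root / rel)
            recordings[test][site] = ImuRecording(
                site, test, fs, df["t_s"].to_numpy(),
                df[["ax_g", "ay_g", "az_g"]].to_numpy(),
                df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy())
        truth = GroundTruth.from_json((root / pid / "ground_truth.json").read_text())
        participants.append(Participant(pid, group, recordings, truth))
    spec = CohortSpec(group_sizes={g: max(1, sum(manifest["group"] == g)) for g in GROUPS})
    return Cohort(spec, participants)
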