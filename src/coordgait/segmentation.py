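"""Gait-event detection on shank mediolateral angular velocity and cycle
delineation.

Mid-swing events are the positive peaks of the decimated, band-passed shank
ML gyro; the valley inside the 0.5 s window before a peak is toe-off and the
valley inside the 0.5 s window after it is heel-strike.  Only cycles for
which all three events were found are used.  Gait cycles span heel-strike to
heel-strike; tandem cycles span toe-off to toe-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import (AX_ML, FilterSpec, ImuRecording, bandpass_zero_phase,
                         decimate_denoise, decimate_time)

EVENT_WINDOW_S = 0.5   # valley search window on each side of mid-swing
DECIMATION_FACTOR = 16 # two effective bits of resolution for white noise


@dataclass
class GaitEvents:
    """Detected events for one side; arrays are aligned per detected peak,
    with NaN where a valley could not be found inside its window."""

    side: str
    mid_swing: np.ndarray
    toe_off: np.ndarray
    heel_strike: np.ndarray
    complete: np.ndarray  # bool per peak: all three events found

    @property
    def n_peaks(self) -> int:
        return self.mid_swing.shape[0]

    @property
    def n_complete(self) -> int:
        return int(self.complete.sum())

    def complete_triplets(self) -> np.ndarray:
        """(m, 3) array of [toe_off, mid_swing, heel_strike] times plus the
        original peak index, for complete cycles only."""
        idx = np.flatnonzero(self.complete)
        return np.column_stack([self.toe_off[idx], self.mid_swing[idx],
                                self.heel_strike[idx], idx.astype(float)])


@dataclass
class GaitCycle:
    """One delineated cycle with full-rate channel slices."""

    test: str
    side: str
    participant_id: str
    fs: float
    start_s: float
    end_s: float
    toe_off_s: float      # toe-off of the swing inside this cycle
    mid_swing_s: float
    heel_strike_s: float
    shank_gyro: np.ndarray       # (n, 3) raw full-rate
    shank_accel: np.ndarray      # (n, 3)
    thigh_gyro: np.ndarray       # (n, 3)
    thigh_accel: np.ndarray      # (n, 3)
    trunk_accel: np.ndarray      # (n, 3)
    trunk_gyro_ml: np.ndarray    # (n,)
    shank_gyro_ml_bp: np.ndarray # (n,) band-passed ML channel
    thigh_gyro_ml_bp: np.ndarray # (n,)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n(self) -> int:
        return self.shank_gyro.shape[0]


def adaptive_prominence(x: np.ndarray) -> float:
    """Amplitude-scale-free peak prominence: half the 95th percentile of the
    positive part of the signal."""
    pos = x[x > 0]
    if pos.size == 0:
        return np.inf
    return 0.5 * float(np.percentile(pos, 95))


def detect_events(ml_gyro: np.ndarray, fs_dec: float,
                  min_prominence: float | None = None,
                  t: np.ndarray | None = None,
                  side: str = "L") -> GaitEvents:
    """Detect mid-swing peaks and flanking valleys on a decimated, filtered
    shank ML channel.

    ``t`` gives the timestamps of the decimated samples (defaults to
    ``arange(n)/fs_dec``) so event times land on the original time base.
    """
    x = np.asarray(ml_gyro, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if x.size < int(2 * fs_dec):
        raise ValueError("need at least 2 s of signal for event detection")
    if t is None:
        t = np.arange(x.size) / fs_dec
    if min_prominence is None:
        min_prominence = adaptive_prominence(x)

    peaks, _ = sps.find_peaks(x, prominence=min_prominence)
    if peaks.size == 0:
        empty = np.array([])
        return GaitEvents(side, empty, empty, empty, np.array([], dtype=bool))

    valleys, _ = sps.find_peaks(-x)
    win = int(round(EVENT_WINDOW_S * fs_dec))

    to = np.full(peaks.size, np.nan)
    hs = np.full(peaks.size, np.nan)
    for k, p in enumerate(peaks):
        before = valleys[(valleys > p - win) & (valleys < p)]
        after = valleys[(valleys > p) & (valleys < p + win)]
        if before.size:
            # deepest valley; ties broken toward the sample nearest the peak
            order = np.lexsort((-before, x[before]))
            to[k] = t[before[order[0]]]
        if after.size:
            order = np.lexsort((after, x[after]))
            hs[k] = t[after[order[0]]]

    complete = ~np.isnan(to) & ~np.isnan(hs)
    return GaitEvents(side, t[peaks], to, hs, complete)


def delineate_cycles(events: GaitEvents, test: str,
                     recs: dict[str, ImuRecording],
                     participant_id: str = "",
                     filter_spec: FilterSpec = FilterSpec()) -> list[GaitCycle]:
    """Cut consecutive complete cycles out of synchronized full-rate
    recordings.

    ``recs`` must provide "shank", "thigh" and "trunk" recordings for the
    matching side.  Cycles bridging an incomplete event triplet are dropped.
    """
    if test not in ("gait", "tandem"):
        raise ValueError(f"unknown test {test!r}")
    trip = events.complete_triplets()
    if trip.shape[0] < 2:
        return []

    shank, thigh, trunk = recs["shank"], recs["thigh"], recs["trunk"]
    fs = shank.fs
    t0 = shank.t[0]
    shank_bp = bandpass_zero_phase(shank.gyro[:, AX_ML], fs, filter_spec)
    thigh_bp = bandpass_zero_phase(thigh.gyro[:, AX_ML], fs, filter_spec)

    cycles: list[GaitCycle] = []
    for a, b in zip(trip[:-1], trip[1:]):
        if int(b[3]) != int(a[3]) + 1:
            continue  # an incomplete peak sits between the two triplets
        if test == "gait":
            start, end = a[2], b[2]              # heel-strike -> heel-strike
            to_s, ms_s, hs_s = b[0], b[1], b[2]  # swing of the next triplet
        else:
            start, end = a[0], b[0]              # toe-off -> toe-off
            to_s, ms_s, hs_s = a[0], a[1], a[2]
        i0 = int(round((start - t0) * fs))
        i1 = int(round((end - t0) * fs))
        if i0 < 0 or i1 >= shank.n or i1 - i0 < 4:
            continue
        cycles.append(GaitCycle(
            test=test, side=events.side, participant_id=participant_id,
            fs=fs, start_s=float(start), end_s=float(end),
            toe_off_s=float(to_s), mid_swing_s=float(ms_s),
            heel_strike_s=float(hs_s),
            shank_gyro=shank.gyro[i0:i1 + 1],
            shank_accel=shank.accel[i0:i1 + 1],
            thigh_gyro=thigh.gyro[i0:i1 + 1],
            thigh_accel=thigh.accel[i0:i1 + 1],
            trunk_accel=trunk.accel[i0:i1 + 1],
            trunk_gyro_ml=trunk.gyro[i0:i1 + 1, AX_ML],
            shank_gyro_ml_bp=shank_bp[i0:i1 + 1],
            thigh_gyro_ml_bp=thigh_bp[i0:i1 + 1],
        ))
    return cycles


def quality_gate(events: GaitEvents, rec_duration_s: float,
                 min_complete: int = 3,
                 min_complete_rate: float = 0.5) -> tuple[bool, str]:
    """Automated surrogate for visual signal triage."""
    if events.n_peaks == 0:
        return False, "no mid-swing peaks detected"
    rate = events.n_complete / events.n_peaks
    if events.n_complete < min_complete:
        return False, (f"only {events.n_complete} complete cycles "
                       f"(minimum {min_complete})")
    if rate < min_complete_rate:
        return False, (f"complete-cycle rate {rate:.0%} below "
                       f"{min_complete_rate:.0%}")
    return True, (f"{events.n_complete}/{events.n_peaks} complete cycles")


def segment_recording(shank: ImuRecording, thigh: ImuRecording,
                      trunk: ImuRecording, test: str, side: str,
                      participant_id: str = "",
                      filter_spec: FilterSpec = FilterSpec(),
                      decimation: int = DECIMATION_FACTOR,
                      min_prominence: float | None = None
                      ) -> tuple[GaitEvents, list[GaitCycle], tuple[bool, str]]:
    """Decimate + filter the shank ML channel, detect events, gate quality
    and delineate full-rate cycles.  Convenience wrapper for one side."""
    fs_dec = shank.fs / decimation
    dec = decimate_denoise(shank.gyro[:, AX_ML], decimation)
    t_dec = decimate_time(shank.t, decimation)
    filt = bandpass_zero_phase(dec, fs_dec, filter_spec)
    events = detect_events(filt, fs_dec, min_prominence=min_prominence,
                           t=t_dec, side=side)
    qc = quality_gate(events, shank.t[-1] - shank.t[0])
    cycles = (delineate_cycles(events, test,
                               {"shank": shank, "thigh": thigh, "trunk": trunk},
                               participant_id, filter_spec)
              if qc[0] else [])
    return events, cycles, qc
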