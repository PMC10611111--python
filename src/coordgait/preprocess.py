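"""IMU recording container, axis standardization, synchronization,
block-average decimation and zero-phase band-pass filtering.

Axis convention after standardization: channel 0 = vertical, channel 1 =
mediolateral, channel 2 = anterior-posterior.  Acceleration is in g,
angular velocity in degrees per second.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

log = logging.getLogger(__name__)

SITES = ("sternum", "L3", "thigh_L", "thigh_R", "shank_L", "shank_R")
TESTS = ("gait", "tandem")

#: channel indices after standardization
AX_V, AX_ML, AX_AP = 0, 1, 2


@dataclass
class ImuRecording:
    """One sensor site, one test: uniformly sampled tri-axial accel/gyro."""

    site: str
    test: str
    fs: float
    t: np.ndarray          # (n,) seconds
    accel: np.ndarray      # (n, 3) in g
    gyro: np.ndarray       # (n, 3) in dps
    mag: np.ndarray | None = None
    standardized: bool = True

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.t.shape[0]
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("accel/gyro must be (n, 3) matching t")
        if n >= 2:
            dt = np.diff(self.t)
            if (dt <= 0).any():
                raise ValueError("timestamps must be strictly increasing")
            if np.abs(dt - 1.0 / self.fs).max() > 1e-6:
                raise ValueError("timestamps must be uniform at fs")

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass Butterworth applied forward-backward (zero phase)."""

    band: tuple[float, float] = (0.5, 5.0)
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not (0.0 < lo < hi < fs / 2.0):
            raise ValueError(f"band {self.band} infeasible for fs={fs}")


def _check_mapping(mapping: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(mapping, dtype=int)
    if m.shape != (3,) or sorted(abs(m)) != [1, 2, 3]:
        raise ValueError(
            "mapping must be a signed permutation of (1, 2, 3), e.g. (2, -1, 3)"
        )
    return np.abs(m) - 1, np.sign(m).astype(float)


def standardize_axes(rec: ImuRecording, mapping: Sequence[int]) -> ImuRecording:
    """Reorder/sign-flip channels so output channel i = sign*input channel.

    ``mapping[i]`` is the signed 1-based source axis for output axis ``i``;
    identity is ``(1, 2, 3)``.  Warns when the vertical accelerometer channel
    does not carry a positive gravity baseline.
    """
    idx, sign = _check_mapping(mapping)
    out = replace(
        rec,
        accel=rec.accel[:, idx] * sign,
        gyro=rec.gyro[:, idx] * sign,
        mag=None if rec.mag is None else rec.mag[:, idx] * sign,
        standardized=True,
    )
    if out.n and np.mean(out.accel[:, AX_V]) <= 0:
        warnings.warn(
            f"{rec.site}/{rec.test}: vertical accel mean is not positive after "
            "standardization; check the axis mapping",
            stacklevel=2,
        )
    return out


def synchronize(recs: Iterable[ImuRecording], start: float,
                end: float) -> list[ImuRecording]:
    """Crop all recordings to [start, end] with nearest-sample alignment.

    No resampling: each recording keeps its own grid, cut at the samples
    nearest to the window bounds.
    """
    recs = list(recs)
    if end <= start:
        raise ValueError("synchronization window must satisfy start < end")
    out = []
    for rec in recs:
        lo, hi = rec.span
        if start < lo - 0.5 / rec.fs or end > hi + 0.5 / rec.fs:
            raise ValueError(
                f"window [{start}, {end}] s outside recording span of "
                f"sensor {rec.site!r} ({lo:.3f}-{hi:.3f} s)"
            )
        i0 = int(np.argmin(np.abs(rec.t - start)))
        i1 = int(np.argmin(np.abs(rec.t - end)))
        out.append(
            replace(
                rec,
                t=rec.t[i0:i1 + 1],
                accel=rec.accel[i0:i1 + 1],
                gyro=rec.gyro[i0:i1 + 1],
                mag=None if rec.mag is None else rec.mag[i0:i1 + 1],
            )
        )
    return out


def decimate_denoise(x: np.ndarray, factor: int) -> np.ndarray:
    """Block-average decimation: consecutive `factor`-sample means.

    Averaging 4 samples gains one effective bit for white noise, so the
    default factor 16 gains two bits (noise SD reduced 4x).  A tail shorter
    than one block is trimmed.
    """
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    x = np.asarray(x, dtype=float)
    if factor == 1:
        return x.copy()
    n = (x.shape[0] // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)


def decimate_time(t: np.ndarray, factor: int) -> np.ndarray:
    """Timestamps of block means: the block-mean of the time vector."""
    return decimate_denoise(t, factor)


def bandpass_zero_phase(x: np.ndarray, fs: float,
                        spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Forward-backward Butterworth band-pass (zero net group delay).

    The input is reflect-padded by up to 3 s before filtering and trimmed
    afterwards to suppress edge transients.
    """
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("signal too short to filter")
    sos = sps.butter(spec.order, spec.band, btype="bandpass", fs=fs, output="sos")
    pad = min(int(round(3.0 * fs)), x.shape[0] - 1)
    xp = np.pad(x, pad, mode="reflect") if pad > 0 else x
    if spec.zero_phase:
        y = sps.sosfiltfilt(sos, xp)
    else:
        y = sps.sosfilt(sos, xp)
    return np.asarray(y[pad:pad + x.shape[0]])
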