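"""Inertial-signal preprocessing: calibration, denoising, gravity removal,
orientation estimation and sliding-window segmentation.

The raw input is a tri-axial acceleration series in g units sampled at
``fs`` Hz (100 Hz for the target device).  The processing order is fixed:

1. calibrate (per-axis bias/scale from nine static postures, Gauss-Newton);
2. third-order median filter (artifactual high-frequency noise);
3. body acceleration = signal minus its 1 Hz low-pass (gravity) component;
   a separate 0.5-15 Hz band-pass copy is kept for the orientation variant;
4. orientation angles (deg) from the closed forms

       O_roll  = atan2(Acc_x, sign(Acc_z)*Acc_z + 0.01*Acc_x^2) * 180/pi
       O_pitch = atan2(-Acc_x, sqrt(Acc_y^2 + Acc_z^2)) * 180/pi
       O_tilt  = atan(Acc_z / ||Acc||) * 180/pi

   with sign(0) = +1; the 0.01*Acc_x^2 term regularizes the roll
   denominator away from zero.

By default orientation is computed from the calibrated-denoised signal so
that static postures keep their DC orientation; ``orientation_source=
"bandpassed"`` reproduces the band-pass-then-estimate reading instead.

5. sliding windows of 3 s with 1 s overlap (2 s hop); trailing partial
   windows are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy.ndimage import median_filter

from .tags import ActivityTag, as_tag

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationParams",
    "SignalFrame",
    "Window",
    "calibrate",
    "apply_calibration",
    "denoise",
    "remove_gravity",
    "bandpass",
    "estimate_orientation",
    "preprocess",
    "window",
    "read_signal_csv",
    "write_signal_csv",
    "read_labels_csv",
    "write_labels_csv",
]

WIN_S_DEFAULT = 3.0
OVERLAP_S_DEFAULT = 1.0


@dataclass(frozen=True)
class CalibrationParams:
    """Per-axis accelerometer bias (g) and scale (dimensionless)."""

    bias: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bias", np.asarray(self.bias, dtype=float).reshape(3))
        object.__setattr__(self, "scale", np.asarray(self.scale, dtype=float).reshape(3))
        if not (self.scale > 0).all():
            raise ValueError("calibration scale components must be strictly positive")


@dataclass
class SignalFrame:
    """Calibrated tri-axial acceleration plus derived channels.

    ``acc``, ``body_acc`` are (N, 3) arrays in g; ``orientation`` is (N, 3)
    degrees with columns (roll, pitch, tilt); ``time`` is seconds.
    """

    time: np.ndarray
    acc: np.ndarray
    body_acc: np.ndarray
    orientation: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("acc", "body_acc", "orientation"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3), got {arr.shape}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class Window:
    """A 3-second slice of a SignalFrame, optionally carrying a ground-truth tag."""

    start_s: float
    end_s: float
    sl: slice
    frame: SignalFrame
    tag: ActivityTag | None = None

    @property
    def body_acc(self) -> np.ndarray:
        return self.frame.body_acc[self.sl]

    @property
    def orientation(self) -> np.ndarray:
        return self.frame.orientation[self.sl]


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate(static_segments: Sequence[np.ndarray], max_std_g: float = 0.1) -> CalibrationParams:
    """Estimate bias/scale from >= 9 static recordings (Gauss-Newton).

    Each segment is an (n_i, 3) array recorded in a distinct static posture.
    Minimizes sum over segments of (||scale*(mean - bias)|| - 1)^2 so that
    calibrated static means have unit gravity norm.
    """
    if len(static_segments) < 9:
        raise ValueError(
            f"calibration needs at least 9 static segments, got {len(static_segments)}"
        )
    means = []
    for i, seg in enumerate(static_segments):
        seg = np.asarray(seg, dtype=float)
        if seg.ndim != 2 or seg.shape[1] != 3:
            raise ValueError(f"static segment {i} must be (n, 3)")
        if seg.shape[0] > 1 and seg.std(axis=0).max() > max_std_g:
            raise ValueError(f"static segment {i} is not static (std > {max_std_g} g)")
        means.append(seg.mean(axis=0))
    M = np.vstack(means)

    def residuals(p: np.ndarray) -> np.ndarray:
        bias, scale = p[:3], p[3:]
        return np.linalg.norm(scale * (M - bias), axis=1) - 1.0

    p0 = np.concatenate([np.zeros(3), np.ones(3)])
    sol = optimize.least_squares(residuals, p0, method="lm")
    if not sol.success:
        raise RuntimeError(
            f"calibration optimizer did not converge (residual {np.abs(sol.fun).max():.3g})"
        )
    final = np.abs(sol.fun).max()
    if final > 0.05:
        logger.warning("calibration residual %.3g g exceeds 0.05 g", final)
    return CalibrationParams(bias=sol.x[:3], scale=np.abs(sol.x[3:]))


def apply_calibration(acc: np.ndarray, params: CalibrationParams) -> np.ndarray:
    """Map raw readings to calibrated g units: scale * (acc - bias)."""
    return params.scale * (np.asarray(acc, dtype=float) - params.bias)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def denoise(acc: np.ndarray) -> np.ndarray:
    """Third-order (kernel 3) per-axis median filter; replicate-padded ends."""
    acc = np.asarray(acc, dtype=float)
    if acc.shape[0] < 3:
        raise ValueError("denoise needs at least 3 samples")
    return median_filter(acc, size=(3, 1), mode="nearest")


def _butter_filtfilt(acc: np.ndarray, fs: float, Wn, btype: str) -> np.ndarray:
    sos = signal.butter(4, Wn, btype=btype, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, acc, axis=0)


def remove_gravity(acc: np.ndarray, fs: float) -> np.ndarray:
    """Body acceleration: signal minus its 1 Hz low-pass (gravity) component."""
    if fs <= 2.0:
        raise ValueError("remove_gravity requires fs > 2 Hz")
    gravity = _butter_filtfilt(np.asarray(acc, dtype=float), fs, 1.0, "lowpass")
    return acc - gravity


def bandpass(acc: np.ndarray, fs: float, lo: float = 0.5, hi: float = 15.0) -> np.ndarray:
    """0.5-15 Hz band-pass (4th-order Butterworth, zero phase)."""
    if fs <= 2 * hi:
        raise ValueError(f"bandpass requires fs > {2 * hi} Hz")
    return _butter_filtfilt(np.asarray(acc, dtype=float), fs, (lo, hi), "bandpass")


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def estimate_orientation(acc: np.ndarray, fs: float) -> np.ndarray:
    """Per-sample (roll, pitch, tilt) in degrees from tri-axial acceleration."""
    if fs <= 30.0:
        raise ValueError("estimate_orientation requires fs > 30 Hz")
    acc = np.asarray(acc, dtype=float)
    ax, ay, az = acc[:, 0], acc[:, 1], acc[:, 2]
    sign_z = np.where(az >= 0, 1.0, -1.0)
    roll = np.degrees(np.arctan2(ax, sign_z * az + 0.01 * ax**2))
    pitch = np.degrees(np.arctan2(-ax, np.hypot(ay, az)))
    norm = np.linalg.norm(acc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tilt = np.degrees(np.arctan(az / norm))
    zero = norm == 0
    if zero.any():
        logger.warning("estimate_orientation: %d zero-magnitude samples, tilt set to 0", zero.sum())
        tilt = np.where(zero, 0.0, tilt)
    return np.column_stack([roll, pitch, tilt])


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def preprocess(
    acc: np.ndarray,
    fs: float,
    calibration: CalibrationParams | None = None,
    time: np.ndarray | None = None,
    orientation_source: str = "denoised",
) -> SignalFrame:
    """Run the full fixed-order preprocessing pipeline on raw acceleration.

    ``orientation_source`` is ``"denoised"`` (default: orientation from the
    calibrated-denoised signal, preserving static DC posture) or
    ``"bandpassed"`` (orientation from the 0.5-15 Hz band-passed copy).
    """
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("acc must be (N, 3)")
    if orientation_source not in ("denoised", "bandpassed"):
        raise ValueError(f"unknown orientation_source {orientation_source!r}")
    if calibration is not None:
        acc = apply_calibration(acc, calibration)
    clean = denoise(acc)
    body = remove_gravity(clean, fs)
    src = bandpass(clean, fs) if orientation_source == "bandpassed" else clean
    orient = estimate_orientation(src, fs)
    if time is None:
        time = np.arange(len(clean)) / fs
    return SignalFrame(time=time, acc=clean, body_acc=body, orientation=orient, fs=fs)


def window(
    frame: SignalFrame,
    win_s: float = WIN_S_DEFAULT,
    overlap_s: float = OVERLAP_S_DEFAULT,
) -> list[Window]:
    """Cut sliding windows (default 3 s, 1 s overlap -> 2 s hop).

    count = floor((N - win_s*fs) / (hop*fs)) + 1; trailing partial windows
    are discarded.
    """
    if overlap_s >= win_s:
        raise ValueError("overlap must be shorter than the window")
    n_win = int(round(win_s * frame.fs))
    hop = int(round((win_s - overlap_s) * frame.fs))
    n = len(frame)
    if n < n_win:
        raise ValueError(f"signal ({n} samples) shorter than one window ({n_win})")
    count = (n - n_win) // hop + 1
    out = []
    for i in range(count):
        a = i * hop
        out.append(
            Window(
                start_s=float(frame.time[a]),
                end_s=float(frame.time[a] + win_s),
                sl=slice(a, a + n_win),
                frame=frame,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

SIGNAL_COLUMNS = ["time_s", "acc_x_g", "acc_y_g", "acc_z_g"]


def read_signal_csv(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a signal CSV -> (time (s), acc (N,3) in g, fs inferred from time)."""
    df = pd.read_csv(path)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"signal CSV {path} missing columns {missing}")
    time = df["time_s"].to_numpy(dtype=float)
    acc = df[SIGNAL_COLUMNS[1:]].to_numpy(dtype=float)
    if len(time) < 2:
        raise ValueError("signal CSV must contain at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(time)))
    return time, acc, fs


def write_signal_csv(path, time: np.ndarray, acc: np.ndarray) -> None:
    pd.DataFrame(
        {"time_s": time, "acc_x_g": acc[:, 0], "acc_y_g": acc[:, 1], "acc_z_g": acc[:, 2]}
    ).to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    """Read interval labels CSV (start_s, end_s, tag); validates tag strings."""
    df = pd.read_csv(path)
    missing = [c for c in ("start_s", "end_s", "tag") if c not in df.columns]
    if missing:
        raise ValueError(f"label CSV {path} missing columns {missing}")
    df["tag"] = [as_tag(t) for t in df["tag"]]
    return df


def write_labels_csv(path, intervals: Sequence[tuple[float, float, ActivityTag]]) -> None:
    pd.DataFrame(
        [(a, b, as_tag(t).value) for a, b, t in intervals],
        columns=["start_s", "end_s", "tag"],
    ).to_csv(path, index=False)
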