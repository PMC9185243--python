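"""Gait-cycle segmentation and the 11 gait features.

One *step* of each leg is treated as a motion cycle: cycles are delimited by
successive local minima (deepest flexion) of that leg's knee-angle series.
From the cycles and the knee-angle kinematics, eleven features are computed
per recording:

========  ==================================================================
LSS, RSS  left/right step length (input units), corrected step-length model
LLK, LRK  lowest left/right knee angle (deg), mean of per-cycle minima
AS        average stride length = LSS + RSS (one left plus one right step)
APT       average pace time: mean interval between successive steps (s)
AST       average stride time: mean duration of a full per-leg cycle (s)
VOR, VOL  variance of the right/left knee-angle series (deg^2)
KAV       mean absolute knee angular velocity, both legs pooled (deg/s)
KAA       mean absolute knee angular acceleration, both legs pooled (deg/s^2)
========  ==================================================================

The step-length model: at the frame of deepest knee flexion, with thigh
length ``G1``, calf length ``G2``, lowest knee angle ``alpha_min`` and calf
tilt from the image vertical ``beta_min``, the simple estimate is

    l_a1 = G1 * cos(alpha_min - 90 deg)

and the corrected estimate subtracts the backward offset of the ankle
behind the knee,

    l_a2 = G1 * cos(alpha_min - 90 deg) - G2 * sin(beta_min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import DomainError, InsufficientDataError, UndefinedAngleError
from .geometry import (
    KneeAngleSeries,
    LimbCalibration,
    calibrate_from_standing,
    reconstruct_series,
)
from .io import FEATURE_COLUMNS, GaitRecording, LowerLimbFrame, SIDES

# Cycle-detection constants (seconds / degrees); exposed for configuration.
SMOOTH_WINDOW_S = 0.15
MIN_PROMINENCE_DEG = 5.0
MIN_SEPARATION_S = 0.4


@dataclass(frozen=True)
class GaitCycle:
    """One per-leg gait cycle between successive knee-angle minima."""

    side: str
    start: int
    end: int
    duration: float
    min_knee_angle: float
    beta_at_min: float
    min_index: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("cycle end must follow its start")
        if self.duration <= 0:
            raise ValueError("cycle duration must be positive")


@dataclass(frozen=True)
class StepEstimate:
    """Simple and corrected step-length estimates for one cycle."""

    thigh_len: float
    calf_len: float
    l_simple: float
    l_corrected: float
    clamped: bool = False


@dataclass(frozen=True)
class FeatureVector:
    """The 11 gait features of one recording, in fixed order."""

    LSS: float
    RSS: float
    LLK: float
    LRK: float
    AS: float
    APT: float
    AST: float
    VOR: float
    VOL: float
    KAV: float
    KAA: float

    NAMES = FEATURE_COLUMNS

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_COLUMNS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_COLUMNS])


def beta_min(frame: LowerLimbFrame, side: str) -> float:
    """Angle between the calf (knee→ankle) and the image vertical, degrees.

    Folded into [0, 90] by absolute value; 0 means a vertical calf.
    """
    knee = frame.get(side, "knee")
    ankle = frame.get(side, "ankle")
    dx = ankle.x - knee.x
    dy = ankle.y - knee.y
    if dx == 0 and dy == 0:
        raise UndefinedAngleError(f"zero-length {side} calf")
    return float(np.degrees(np.arctan2(abs(dx), abs(dy))))


def step_length_simple(thigh_len: float, alpha_min: float) -> float:
    """Step length from thigh length and lowest knee angle alone."""
    if thigh_len <= 0:
        raise DomainError("thigh length must be positive")
    if not 90.0 <= alpha_min <= 180.0:
        raise DomainError(
            f"alpha_min={alpha_min:.3f} deg outside [90, 180] "
            "(flexion beyond the step-length model's validity)"
        )
    return thigh_len * float(np.cos(np.radians(alpha_min - 90.0)))


def step_length_corrected(
    thigh_len: float, calf_len: float, alpha_min: float, beta_min: float
) -> float:
    """Step length corrected by the calf's backward tilt (clamped at 0)."""
    est = step_estimate(thigh_len, calf_len, alpha_min, beta_min)
    return est.l_corrected


def step_estimate(
    thigh_len: float, calf_len: float, alpha_min: float, beta_min: float
) -> StepEstimate:
    if calf_len <= 0:
        raise DomainError("calf length must be positive")
    if not 0.0 <= beta_min <= 90.0:
        raise DomainError(f"beta_min={beta_min:.3f} deg outside [0, 90]")
    l1 = step_length_simple(thigh_len, alpha_min)
    l2 = l1 - calf_len * float(np.sin(np.radians(beta_min)))
    clamped = l2 < 0
    return StepEstimate(
        thigh_len=thigh_len,
        calf_len=calf_len,
        l_simple=l1,
        l_corrected=max(l2, 0.0),
        clamped=clamped,
    )


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.copy()
    kernel = np.ones(width)
    # edge-normalised moving average (no phase shift, no edge droop)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _fill_nan(x: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if bad.all():
        return np.zeros_like(x)
    out = x.copy()
    idx = np.arange(len(x))
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def segment_cycles(
    series: KneeAngleSeries,
    side: str,
    rec: GaitRecording | None = None,
    angle: str = "3d",
    start_index: int = 0,
    smooth_window_s: float = SMOOTH_WINDOW_S,
    prominence_deg: float = MIN_PROMINENCE_DEG,
    min_separation_s: float = MIN_SEPARATION_S,
) -> list[GaitCycle]:
    """Delimit per-leg cycles at successive knee-angle minima.

    Minima are located on a moving-average-smoothed copy of the series with
    a minimum prominence and a minimum separation; each cycle's
    ``min_knee_angle`` is the *unsmoothed* minimum within the cycle, and
    ``beta_at_min`` is the calf tilt at that frame (NaN unless ``rec`` is
    given).  Returns an empty list when no oscillation is found.
    """
    arr = series.angle_3d[side] if angle == "3d" else series.angle_2d[side]
    arr = arr[start_index:]
    times = series.times[start_index:]
    filled = _fill_nan(arr)
    width = max(1, int(round(smooth_window_s * series.fps)))
    smoothed = _moving_average(filled, width)
    distance = max(1, int(round(min_separation_s * series.fps)))
    minima, _ = find_peaks(-smoothed, prominence=prominence_deg, distance=distance)
    cycles: list[GaitCycle] = []
    for a, b in zip(minima[:-1], minima[1:]):
        span = filled[a : b + 1]
        rel = int(np.argmin(span))
        i_min = a + rel
        beta = np.nan
        if rec is not None:
            beta = beta_min(rec.frame(start_index + i_min), side)
        cycles.append(
            GaitCycle(
                side=side,
                start=start_index + int(a),
                end=start_index + int(b),
                duration=float(times[b] - times[a]),
                min_knee_angle=float(filled[i_min]),
                beta_at_min=beta,
                min_index=start_index + i_min,
            )
        )
    return cycles


def angular_kinematics(
    series: KneeAngleSeries, side: str, start_index: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Knee angular velocity (deg/s) and acceleration (deg/s^2).

    Central finite differences on the 3D angle series; one-sided at the
    endpoints.  NaN gaps are linearly bridged before differentiation.
    """
    arr = _fill_nan(series.angle_3d[side][start_index:])
    times = series.times[start_index:]
    if len(arr) < 3:
        raise InsufficientDataError("need at least 3 frames for kinematics")
    vel = np.gradient(arr, times)
    acc = np.gradient(vel, times)
    return vel, acc


def _cycle_alpha_beta(
    cycles: list[GaitCycle],
    series: KneeAngleSeries,
    rec: GaitRecording,
    side: str,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (alpha_min, beta_min) in the requested 2d/3d mode."""
    if mode == "3d":
        return (
            np.array([c.min_knee_angle for c in cycles]),
            np.array([c.beta_at_min for c in cycles]),
        )
    arr = _fill_nan(series.angle_2d[side])
    alphas, betas = [], []
    for c in cycles:
        span = arr[c.start : c.end + 1]
        i_min = c.start + int(np.argmin(span))
        alphas.append(float(arr[i_min]))
        betas.append(beta_min(rec.frame(i_min), side))
    return np.array(alphas), np.array(betas)


def extract_features(
    rec: GaitRecording,
    calib: LimbCalibration,
    mode: str = "3d",
    start_time: float | None = None,
    series: KneeAngleSeries | None = None,
    **cycle_kwargs,
) -> FeatureVector:
    """Compute the 11 gait features of one recording.

    ``mode`` selects whether the four reconstructed features (LSS, RSS, LLK,
    LRK) are taken from the 3D-reconstructed or the raw planar knee angles;
    the remaining seven features always use the 3D series.  ``start_time``
    excludes an initial segment (e.g. the standing calibration pose) from
    the analysis.  Step lengths use the calibrated real thigh/calf lengths.
    """
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    if series is None:
        series = reconstruct_series(rec, calib)
    i0 = 0
    if start_time is not None:
        i0 = int(np.searchsorted(series.times, start_time))

    cycles = {}
    for side in SIDES:
        cyc = segment_cycles(
            series, side, rec=rec, angle="3d", start_index=i0, **cycle_kwargs
        )
        if len(cyc) < 2:
            raise InsufficientDataError(
                f"fewer than 2 gait cycles detected on the {side} side"
            )
        cycles[side] = cyc

    step_len = {}
    lowest = {}
    for side in SIDES:
        alphas, betas = _cycle_alpha_beta(cycles[side], series, rec, side, mode)
        g1, g2 = calib.thigh(side), calib.calf(side)
        steps = [
            step_length_corrected(g1, g2, a, b) for a, b in zip(alphas, betas)
        ]
        step_len[side] = float(np.mean(steps))
        lowest[side] = float(np.mean(alphas))

    durations = [c.duration for side in SIDES for c in cycles[side]]
    ast = float(np.mean(durations))
    # step events = the cycle-delimiting minima of both legs, interleaved
    trough_times = np.sort(
        np.unique(
            [series.times[c.start] for side in SIDES for c in cycles[side]]
            + [series.times[cycles[side][-1].end] for side in SIDES]
        )
    )
    apt = float(np.mean(np.diff(trough_times)))

    variances = {
        side: float(np.nanvar(series.angle_3d[side][i0:])) for side in SIDES
    }
    speeds, accels = [], []
    for side in SIDES:
        vel, acc = angular_kinematics(series, side, start_index=i0)
        speeds.append(np.abs(vel))
        accels.append(np.abs(acc))
    kav = float(np.mean(np.concatenate(speeds)))
    kaa = float(np.mean(np.concatenate(accels)))

    return FeatureVector(
        LSS=step_len["left"],
        RSS=step_len["right"],
        LLK=lowest["left"],
        LRK=lowest["right"],
        AS=step_len["left"] + step_len["right"],
        APT=apt,
        AST=ast,
        VOR=variances["right"],
        VOL=variances["left"],
        KAV=kav,
        KAA=kaa,
    )


# -- batch helpers ---------------------------------------------------------

#: Seconds allowed after the standing segment for the gait to settle before
#: frames enter the feature window.
SETTLE_S = 0.2


def process_recording(
    rec: GaitRecording,
    mode: str = "3d",
    standing_window: tuple[int, int] | None = None,
    settle_s: float = SETTLE_S,
) -> FeatureVector:
    """Calibrate from the standing segment, reconstruct, extract features.

    The standing window defaults to ``rec.meta['standing_frames']`` (set by
    the simulator and by the CLI config); feature extraction starts just
    after it.
    """
    if standing_window is None:
        standing_window = rec.meta.get("standing_frames")
    if standing_window is None:
        raise ValueError(
            "no standing window given and none recorded in rec.meta"
        )
    calib = calibrate_from_standing(rec, standing_window)
    start_time = float(rec.times[min(standing_window[1], rec.n_frames - 1)])
    return extract_features(rec, calib, mode=mode, start_time=start_time + settle_s)


def build_feature_table(
    recordings, labels=None, mode: str = "3d"
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Feature matrix (one row per recording) plus aligned labels."""
    rows = [process_recording(rec, mode=mode).as_dict() for rec in recordings]
    X = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    y = None if labels is None else pd.Series(list(labels), name="label")
    return X, y
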