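"""Limb calibration and monocular 3D knee-angle reconstruction.

A monocular camera sees the walking plane at an out-of-plane tilt, so the
projected thigh and calf are foreshortened and the knee angle measured in
the image (the "false" planar angle) is biased.  With the *real* segment
lengths known from a standing pose — a vertical segment is not foreshortened
by a rotation about the vertical axis, so standing hip–knee and knee–ankle
distances equal the true lengths — the true 3D knee angle can be recovered
from the three projected distances alone.

Notation (all lengths in input units, angles in degrees):

* ``L1``, ``L2``, ``L5`` — projected hip–knee, knee–ankle and hip–ankle
  distances measured in the image;
* ``L3``, ``L4`` — real thigh and calf lengths from standing calibration;
* ``theta2`` — the reconstructed 3D knee angle.

Under orthographic projection the out-of-image depth components of the
thigh and calf are ``d1 = sqrt(L3^2 - L1^2)`` and ``d2 = sqrt(L4^2 - L2^2)``.
Writing the knee-centred dot product of the hip and ankle vectors in terms
of in-image and depth parts gives

    cos(theta2) = (L1^2 + L2^2 - L5^2 + 2*d1*d2) / (2 * L3 * L4)

for the case where hip and ankle lie on the same depth side of the knee
(the configuration of a leg whose sagittal plane is tilted about the
vertical).  When nothing is foreshortened (``L1 = L3``, ``L2 = L4``) the
depth terms vanish and the formula reduces exactly to the planar law of
cosines, i.e. the 2D image angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, MissingJointError, UndefinedAngleError
from .io import GaitRecording, LowerLimbFrame, SIDES

#: Relative tolerance by which a projected length may exceed the calibrated
#: real length before it is treated as a calibration inconsistency (keypoint
#: jitter routinely produces L1 slightly greater than L3).
PROJECTION_TOLERANCE = 0.05


@dataclass(frozen=True)
class LimbCalibration:
    """Real (unforeshortened) thigh and calf lengths per side."""

    left_thigh: float
    left_calf: float
    right_thigh: float
    right_calf: float

    def __post_init__(self) -> None:
        for name in ("left_thigh", "left_calf", "right_thigh", "right_calf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def thigh(self, side: str) -> float:
        return self.left_thigh if side == "left" else self.right_thigh

    def calf(self, side: str) -> float:
        return self.left_calf if side == "left" else self.right_calf


@dataclass(frozen=True)
class ProjectedLengths:
    """Image-plane hip–knee (L1), knee–ankle (L2) and hip–ankle (L5) distances."""

    thigh_proj: float
    calf_proj: float
    span_proj: float

    def __post_init__(self) -> None:
        l1, l2, l5 = self.thigh_proj, self.calf_proj, self.span_proj
        if min(l1, l2, l5) < 0:
            raise ValueError("projected lengths must be non-negative")
        tol = 1e-9 * max(l1, l2, l5, 1.0)
        if not (abs(l1 - l2) - tol <= l5 <= l1 + l2 + tol):
            raise ValueError("projected lengths violate the triangle inequality")


@dataclass
class KneeAngleSeries:
    """Per-frame left/right knee angles, planar and 3D-reconstructed.

    Frames where a joint is missing (or the reconstruction is inconsistent
    with the calibration) carry NaN.  ``clamp_flags`` marks frames where a
    numerical clamp (cosine outside [-1, 1] or projected length slightly
    above the real length) was applied.
    """

    times: np.ndarray
    fps: float
    angle_2d: dict[str, np.ndarray]
    angle_3d: dict[str, np.ndarray]
    clamp_flags: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.times)
        for side in SIDES:
            for d in (self.angle_2d, self.angle_3d, self.clamp_flags):
                if len(d[side]) != n:
                    raise ValueError("series arrays must match times in length")

    @property
    def n_frames(self) -> int:
        return len(self.times)


def _joint_xy(frame: LowerLimbFrame, side: str, joint: str) -> np.ndarray:
    kp = frame.get(side, joint)
    if kp.missing:
        raise MissingJointError(f"{side} {joint} not detected in this frame")
    return np.array([kp.x, kp.y])


def projected_lengths(frame: LowerLimbFrame, side: str) -> ProjectedLengths:
    """Euclidean image distances hip–knee (L1), knee–ankle (L2), hip–ankle (L5)."""
    hip = _joint_xy(frame, side, "hip")
    knee = _joint_xy(frame, side, "knee")
    ankle = _joint_xy(frame, side, "ankle")
    return ProjectedLengths(
        thigh_proj=float(np.linalg.norm(hip - knee)),
        calf_proj=float(np.linalg.norm(knee - ankle)),
        span_proj=float(np.linalg.norm(hip - ankle)),
    )


def knee_angle_2d(frame: LowerLimbFrame, side: str) -> float:
    """Interior image-plane angle at the knee, in degrees within [0, 180].

    This is the "false" knee angle measured directly on the projected
    skeleton; it equals the true angle only when the leg's plane is parallel
    to the image plane.
    """
    hip = _joint_xy(frame, side, "hip")
    knee = _joint_xy(frame, side, "knee")
    ankle = _joint_xy(frame, side, "ankle")
    u = hip - knee
    v = ankle - knee
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedAngleError(f"zero-length segment at the {side} knee")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class ReconstructedAngle:
    """A reconstructed 3D knee angle plus its numerical-clamp flag."""

    degrees: float
    clamped: bool = False

    def __float__(self) -> float:
        return self.degrees


def knee_angle_3d(
    proj: ProjectedLengths,
    calib: LimbCalibration,
    side: str,
    tol: float = PROJECTION_TOLERANCE,
) -> ReconstructedAngle:
    """Reconstruct the true 3D knee angle from projected and real lengths.

    Raises :class:`CalibrationError` if a projected segment exceeds its real
    length by more than ``tol`` (relative); smaller excesses are clamped to
    the real length and flagged.
    """
    l1, l2, l5 = proj.thigh_proj, proj.calf_proj, proj.span_proj
    l3, l4 = calib.thigh(side), calib.calf(side)
    clamped = False
    for name, lp, lr in (("thigh", l1, l3), ("calf", l2, l4)):
        if lp > lr * (1.0 + tol):
            raise CalibrationError(
                f"projected {name} length {lp:.6g} exceeds calibrated real "
                f"length {lr:.6g} beyond tolerance on the {side} side"
            )
    if l1 > l3:
        l1, clamped = l3, True
    if l2 > l4:
        l2, clamped = l4, True
    d1 = np.sqrt(l3 * l3 - l1 * l1)
    d2 = np.sqrt(l4 * l4 - l2 * l2)
    cos_t2 = (l1 * l1 + l2 * l2 - l5 * l5 + 2.0 * d1 * d2) / (2.0 * l3 * l4)
    if abs(cos_t2) > 1.0:
        clamped = True
        cos_t2 = float(np.clip(cos_t2, -1.0, 1.0))
    return ReconstructedAngle(float(np.degrees(np.arccos(cos_t2))), clamped)


def calibrate_from_standing(
    rec: GaitRecording, standing_window: tuple[int, int]
) -> LimbCalibration:
    """Estimate real limb lengths from a standing segment.

    During quiet standing the legs are vertical, so their projected lengths
    equal the real lengths (a rotation of the walking direction about the
    vertical does not foreshorten vertical segments).  Per side, the real
    thigh (L3) and calf (L4) lengths are the medians of the per-frame
    hip–knee and knee–ankle distances over frames of ``standing_window``
    (half-open frame-index range) in which all six joints are detected.
    """
    a, b = standing_window
    sl = slice(a, b)
    conf = rec.coords[sl, :, :, 2]
    complete = np.all(conf > 0, axis=(1, 2))
    if not np.any(complete):
        raise CalibrationError(
            "no frame with all six joints detected in the standing window"
        )
    xy = rec.coords[sl, :, :, :2][complete]
    lengths = {}
    for si, side in enumerate(SIDES):
        hip, knee, ankle = xy[:, si, 0], xy[:, si, 1], xy[:, si, 2]
        lengths[(side, "thigh")] = float(
            np.median(np.linalg.norm(hip - knee, axis=1))
        )
        lengths[(side, "calf")] = float(
            np.median(np.linalg.norm(knee - ankle, axis=1))
        )
    return LimbCalibration(
        left_thigh=lengths[("left", "thigh")],
        left_calf=lengths[("left", "calf")],
        right_thigh=lengths[("right", "thigh")],
        right_calf=lengths[("right", "calf")],
    )


def reconstruct_series(
    rec: GaitRecording,
    calib: LimbCalibration,
    tol: float = PROJECTION_TOLERANCE,
) -> KneeAngleSeries:
    """Compute planar and 3D knee angles for every frame and side.

    Per-frame problems (missing joints, calibration-inconsistent
    projections, degenerate geometry) become NaN entries; the series is
    never aborted.
    """
    n = rec.n_frames
    angle_2d: dict[str, np.ndarray] = {}
    angle_3d: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for si, side in enumerate(SIDES):
        hip = rec.coords[:, si, 0, :2]
        knee = rec.coords[:, si, 1, :2]
        ankle = rec.coords[:, si, 2, :2]
        conf = rec.coords[:, si, :, 2]
        ok = np.all(conf > 0, axis=1)

        l1 = np.linalg.norm(hip - knee, axis=1)
        l2 = np.linalg.norm(knee - ankle, axis=1)
        l5 = np.linalg.norm(hip - ankle, axis=1)
        l3, l4 = calib.thigh(side), calib.calf(side)

        with np.errstate(invalid="ignore", divide="ignore"):
            cos2d = (l1**2 + l2**2 - l5**2) / (2.0 * l1 * l2)
        a2 = np.degrees(np.arccos(np.clip(cos2d, -1.0, 1.0)))
        a2[~ok | (l1 == 0) | (l2 == 0)] = np.nan

        bad = ~ok | (l1 > l3 * (1 + tol)) | (l2 > l4 * (1 + tol))
        c1 = np.minimum(l1, l3)
        c2 = np.minimum(l2, l4)
        clamp = ok & ((l1 > l3) | (l2 > l4))
        d1 = np.sqrt(np.maximum(l3**2 - c1**2, 0.0))
        d2 = np.sqrt(np.maximum(l4**2 - c2**2, 0.0))
        cos3d = (c1**2 + c2**2 - l5**2 + 2.0 * d1 * d2) / (2.0 * l3 * l4)
        clamp |= ok & (np.abs(cos3d) > 1.0)
        a3 = np.degrees(np.arccos(np.clip(cos3d, -1.0, 1.0)))
        a3[bad] = np.nan

        angle_2d[side] = a2
        angle_3d[side] = a3
        flags[side] = clamp & ~bad

    return KneeAngleSeries(
        times=rec.times.copy(),
        fps=rec.fps,
        angle_2d=angle_2d,
        angle_3d=angle_3d,
        clamp_flags=flags,
    )
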