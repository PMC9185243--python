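"""Synthetic ground-truthed gait recordings for the six gait classes.

The generator builds a 3D kinematic skeleton of the lower limbs, walks it
along a straight route whose sagittal plane is tilted by an angle ``theta1``
out of the image plane, orthographically projects the joints, converts to
pixels and adds Gaussian keypoint noise.  A one-second standing segment is
prepended for limb-length calibration.

Knee-flexion waveform: per leg, ``angle(t) = baseline - A * sin^2(pi*u + phi)``
where ``u`` is the stride phase (``cadence/2`` cycles per second, cadence
counted in steps/s pooled over both feet) and the legs are half a stride
apart — one flexion trough per step, matching the single-trough morphology
of normal walking knee-angle curves.  Class-specific modulations:

* ``mop`` — left/right flexion amplitudes in a fixed asymmetry ratio;
* ``drunk`` — large smoothed angle jitter plus lateral hip sway;
* ``intermittent`` — random pauses between strides freeze the pose;
* ``magnetic`` — amplitude and cadence scaled down (small, slow, stiff steps);
* ``scissor`` — reduced amplitude plus inward calf adduction (crossed legs).

Thigh/calf orientations are driven so the knee angle matches the programmed
waveform exactly while the calf trails behind the vertical at peak flexion
(the landing-like configuration the step-length model assumes).  The hip
advances by one nominal step length per step, where the nominal step is the
horizontal hip-to-ankle reach of the skeleton at peak flexion; the recorded
true per-step displacement is therefore an honest kinematic quantity of the
generated motion, independent of the pipeline's estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import GAIT_CLASSES, GaitRecording, SIDES

DEFAULT_PX_PER_M = 500.0
HIP_HALF_WIDTH_M = 0.09


@dataclass(frozen=True)
class GaitArchetype:
    """Generative parameters of one gait class."""

    gait_class: str
    cadence: float                 # steps/s, both feet pooled
    amplitude: float               # knee-flexion amplitude, deg (right leg)
    baseline: float = 170.0        # knee angle between flexions, deg
    asymmetry: float = 1.0         # left amplitude = asymmetry * amplitude
    jitter_deg: float = 0.5        # sd of smoothed knee-angle jitter
    pause_prob: float = 0.0        # probability of a pause after each stride
    pause_duration_s: float = 0.0
    sway_amp_m: float = 0.0        # lateral hip sway amplitude
    adduction_deg: float = 0.0     # inward calf rotation (scissor)
    step_scale: float = 1.0        # forward advance scale (magnetic < 1)
    thigh_len_m: float = 0.45
    calf_len_m: float = 0.42
    calf_trail_frac: float = 1.0 / 3.0  # beta at peak flexion = frac * amplitude

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 < self.asymmetry <= 1:
            raise ValueError("asymmetry ratio must lie in (0, 1]")
        for name in ("jitter_deg", "pause_prob", "pause_duration_s",
                     "sway_amp_m", "adduction_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.thigh_len_m <= 0 or self.calf_len_m <= 0:
            raise ValueError("segment lengths must be positive")

    def leg_amplitude(self, side: str) -> float:
        return self.amplitude * (self.asymmetry if side == "left" else 1.0)


_DEFAULTS: dict[str, dict] = {
    "standard": dict(cadence=1.8, amplitude=60.0, jitter_deg=0.5),
    "mop": dict(cadence=1.6, amplitude=60.0, asymmetry=0.5, jitter_deg=1.0),
    "drunk": dict(cadence=1.7, amplitude=60.0, asymmetry=0.9, jitter_deg=6.0,
                  sway_amp_m=0.06),
    "intermittent": dict(cadence=1.8, amplitude=60.0, pause_prob=0.35,
                         pause_duration_s=0.7, jitter_deg=1.0),
    "magnetic": dict(cadence=1.1, amplitude=24.0, jitter_deg=0.8,
                     step_scale=0.7),
    "scissor": dict(cadence=1.5, amplitude=42.0, adduction_deg=10.0,
                    jitter_deg=1.0),
}


def make_archetype(gait_class: str, **overrides) -> GaitArchetype:
    """Default generative parameters for one of the six gait classes."""
    if gait_class not in GAIT_CLASSES:
        raise ValueError(
            f"unknown gait class {gait_class!r}; expected one of {GAIT_CLASSES}"
        )
    params = dict(_DEFAULTS[gait_class])
    params.update(overrides)
    return GaitArchetype(gait_class=gait_class, **params)


@dataclass
class GroundTruth:
    """Generative truth accompanying one simulated recording."""

    alpha_min: dict[str, float]        # programmed trough knee angle, deg
    beta_min: dict[str, float]         # calf tilt at the trough, deg
    step_length_m: dict[str, float]    # true per-step displacement, m
    cadence: float
    thigh_len_m: float
    calf_len_m: float
    theta1_deg: float
    px_per_m: float
    true_angles: dict[str, np.ndarray]  # per-frame true 3D knee angle, deg
    times: np.ndarray
    # world-frame (X forward, Y up, Z lateral) joint trajectories, (n, 3)
    # per (side, joint); kept in memory only, not serialised
    joints3d: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def step_length_px(self) -> dict[str, float]:
        return {s: v * self.px_per_m for s, v in self.step_length_m.items()}

    def to_dict(self) -> dict:
        return {
            "alpha_min": self.alpha_min,
            "beta_min": self.beta_min,
            "step_length_m": self.step_length_m,
            "cadence": self.cadence,
            "thigh_len_m": self.thigh_len_m,
            "calf_len_m": self.calf_len_m,
            "theta1_deg": self.theta1_deg,
            "px_per_m": self.px_per_m,
            "true_angles": {s: a.tolist() for s, a in self.true_angles.items()},
            "times": self.times.tolist(),
        }


def _stride_phase(
    n: int, fps: float, cadence: float, pause_prob: float,
    pause_duration_s: float, rng: np.random.Generator, u0: float = 0.25,
) -> np.ndarray:
    """Stride phase u(t); pauses freeze the phase between strides."""
    du = (cadence / 2.0) / fps
    u = np.empty(n)
    cur = u0
    pause_left = 0
    n_pause = int(round(pause_duration_s * fps))
    for i in range(n):
        u[i] = cur
        if pause_left > 0:
            pause_left -= 1
            continue
        nxt = cur + du
        if np.floor(nxt - u0 + 1e-12) > np.floor(cur - u0 + 1e-12):
            if pause_prob > 0 and rng.random() < pause_prob:
                pause_left = n_pause
        cur = nxt
    return u


def _smooth_jitter(
    n: int, sd_deg: float, fps: float, rng: np.random.Generator
) -> np.ndarray:
    """Low-pass Gaussian angle jitter with the requested standard deviation."""
    raw = rng.normal(0.0, 1.0, n)
    if sd_deg == 0 or n < 4:
        return np.zeros(n)
    smooth = gaussian_filter1d(raw, sigma=max(1.0, 0.1 * fps))
    sd = smooth.std()
    if sd == 0:
        return np.zeros(n)
    return smooth / sd * sd_deg


def _nominal_step_m(arch: GaitArchetype, side: str) -> float:
    """Horizontal hip-to-ankle reach at peak flexion, scaled by step_scale."""
    flex = np.radians(arch.leg_amplitude(side))
    beta = np.radians(arch.calf_trail_frac * arch.leg_amplitude(side))
    reach = arch.thigh_len_m * np.sin(flex - beta) - arch.calf_len_m * np.sin(beta)
    return float(max(reach, 0.0) * arch.step_scale)


def simulate_recording(
    arch: GaitArchetype,
    duration_s: float = 10.0,
    fps: float = 30.0,
    theta1_deg: float = 0.0,
    noise_px: float = 1.0,
    seed: int = 0,
    px_per_m: float = DEFAULT_PX_PER_M,
    standing_s: float = 1.0,
    meta: dict | None = None,
) -> tuple[GaitRecording, GroundTruth]:
    """Simulate one recording: standing segment then a straight walk."""
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    rng = np.random.default_rng(seed)
    n_stand = int(round(standing_s * fps))
    n_walk = int(round(duration_s * fps))
    n = n_stand + n_walk
    times = np.arange(n) / fps

    g1, g2 = arch.thigh_len_m, arch.calf_len_m
    hip_y = g1 + g2

    u = _stride_phase(
        n_walk, fps, arch.cadence, arch.pause_prob, arch.pause_duration_s, rng
    )
    phases = {"left": np.pi / 2.0, "right": 0.0}
    step_m = {s: _nominal_step_m(arch, s) for s in SIDES}
    stride_m = step_m["left"] + step_m["right"]
    x_hip = stride_m * (u - u[0])
    sway = arch.sway_amp_m * np.sin(np.pi * u)

    # world frame: X forward along the route, Y up, Z lateral (camera depth
    # mixes in through the walking-direction tilt theta1)
    joints3d = {}  # (side, joint) -> (n, 3)
    jitters = {}
    for side in SIDES:
        amp = arch.leg_amplitude(side)
        arg = np.pi * u + phases[side]
        flex = amp * np.sin(arg) ** 2
        jit = _smooth_jitter(n_walk, arch.jitter_deg, fps, rng)
        jitters[side] = jit
        theta = np.clip(arch.baseline - flex + jit, 92.0, 179.9)
        beta_prog = arch.calf_trail_frac * amp * np.sin(arg) ** 2
        phi_c = -np.radians(beta_prog)                  # calf trails backward
        phi_t = phi_c + np.radians(180.0 - theta)       # knee angle exact

        z0 = -HIP_HALF_WIDTH_M if side == "left" else HIP_HALF_WIDTH_M
        hip = np.column_stack([x_hip, np.full(n_walk, hip_y), z0 + sway])
        knee = hip + g1 * np.column_stack(
            [np.sin(phi_t), -np.cos(phi_t), np.zeros(n_walk)]
        )
        # calf with inward adduction: rotate about the forward axis,
        # preserving segment length
        delta = np.radians(arch.adduction_deg) * (-1.0 if side == "left" else 1.0)
        cy = -g2 * np.cos(phi_c)
        ankle = knee + np.column_stack(
            [g2 * np.sin(phi_c), cy * np.cos(delta), -cy * np.sin(delta)]
        )

        # prepend the standing pose: straight vertical leg at the origin
        stand_hip = np.tile([0.0, hip_y, z0], (n_stand, 1))
        stand_knee = np.tile([0.0, hip_y - g1, z0], (n_stand, 1))
        stand_ankle = np.tile([0.0, hip_y - g1 - g2, z0], (n_stand, 1))
        joints3d[(side, "hip")] = np.vstack([stand_hip, hip])
        joints3d[(side, "knee")] = np.vstack([stand_knee, knee])
        joints3d[(side, "ankle")] = np.vstack([stand_ankle, ankle])

    # true 3D knee angles from the actual joint positions
    true_angles = {}
    for side in SIDES:
        v1 = joints3d[(side, "hip")] - joints3d[(side, "knee")]
        v2 = joints3d[(side, "ankle")] - joints3d[(side, "knee")]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        true_angles[side] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    # orthographic projection at tilt theta1, then pixels (y down)
    th = np.radians(theta1_deg)
    ox, oy = 200.0, 1200.0
    coords = np.zeros((n, 2, 3, 3))
    for si, side in enumerate(SIDES):
        for ji, joint in enumerate(("hip", "knee", "ankle")):
            p = joints3d[(side, joint)]
            x_img = px_per_m * (p[:, 0] * np.cos(th) + p[:, 2] * np.sin(th)) + ox
            y_img = oy - px_per_m * p[:, 1]
            coords[:, si, ji, 0] = x_img
            coords[:, si, ji, 1] = y_img
    if noise_px > 0:
        coords[..., :2] += rng.normal(0.0, noise_px, size=(n, 2, 3, 2))
    coords[..., 2] = rng.uniform(0.55, 0.95, size=(n, 2, 3))

    full_meta = {
        "gait": arch.gait_class,
        "units": "pixels",
        "standing_frames": (0, n_stand),
        "theta1_deg": theta1_deg,
        "px_per_m": px_per_m,
    }
    if meta:
        full_meta.update(meta)
    rec = GaitRecording(times, coords, fps, full_meta)

    truth = GroundTruth(
        alpha_min={
            s: arch.baseline - arch.leg_amplitude(s) for s in SIDES
        },
        beta_min={
            s: arch.calf_trail_frac * arch.leg_amplitude(s) for s in SIDES
        },
        step_length_m=step_m,
        cadence=arch.cadence,
        thigh_len_m=g1,
        calf_len_m=g2,
        theta1_deg=theta1_deg,
        px_per_m=px_per_m,
        true_angles=true_angles,
        times=times.copy(),
        joints3d=joints3d,
    )
    return rec, truth


def simulate_dataset(
    n_per_class: int = 40,
    seed: int = 0,
    unbalanced: dict[str, float] | None = None,
    duration_s: float = 10.0,
    fps: float = 30.0,
    noise_px: float = 1.0,
    n_subjects: int = 8,
    trials_per_subject: int = 5,
    classes: tuple[str, ...] = GAIT_CLASSES,
    theta1_range: tuple[float, float] = (5.0, 25.0),
    archetype_overrides: dict[str, dict] | None = None,
) -> tuple[list[GaitRecording], list[str], list[GroundTruth]]:
    """Generate a labelled dataset of simulated recordings.

    ``n_per_class`` recordings per gait class (default 8 synthetic subjects
    x 5 trials = 40), with per-subject body-size/cadence/amplitude variation
    shared across classes and small per-trial variation on top.  If
    ``unbalanced`` multipliers are given, the inflated classes are
    undersampled back to the minimum class count (seeded), mirroring
    balancing by random undersampling.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = [
        {
            "height": rng.uniform(0.9, 1.1),
            "cadence_f": 1.0 + rng.normal(0.0, 0.06),
            "amp_f": 1.0 + rng.normal(0.0, 0.06),
        }
        for _ in range(n_subjects)
    ]
    overrides = archetype_overrides or {}

    recordings: list[GaitRecording] = []
    labels: list[str] = []
    truths: list[GroundTruth] = []
    for cls in classes:
        base = make_archetype(cls, **overrides.get(cls, {}))
        mult = (unbalanced or {}).get(cls, 1.0)
        n_cls = max(1, int(round(n_per_class * mult)))
        for k in range(n_cls):
            subj = k % n_subjects
            s = subjects[subj]
            cad = base.cadence * s["cadence_f"] * (1.0 + rng.normal(0.0, 0.02))
            amp = base.amplitude * s["amp_f"] * (1.0 + rng.normal(0.0, 0.02))
            amp = float(np.clip(amp, 5.0, base.baseline - 95.0))
            arch = replace(
                base,
                cadence=float(max(cad, 0.5)),
                amplitude=amp,
                thigh_len_m=base.thigh_len_m * s["height"],
                calf_len_m=base.calf_len_m * s["height"],
            )
            theta1 = float(rng.uniform(*theta1_range))
            rec_seed = int(rng.integers(0, 2**31 - 1))
            rec, truth = simulate_recording(
                arch,
                duration_s=duration_s,
                fps=fps,
                theta1_deg=theta1,
                noise_px=noise_px,
                seed=rec_seed,
                meta={"subject": subj, "trial": k // n_subjects},
            )
            recordings.append(rec)
            labels.append(cls)
            truths.append(truth)

    if unbalanced:
        # balance by random undersampling to the minimum class count
        labels_arr = np.array(labels)
        counts = {c: int((labels_arr == c).sum()) for c in classes}
        floor = min(counts.values())
        keep: list[int] = []
        for c in classes:
            idx = np.flatnonzero(labels_arr == c)
            chosen = rng.choice(idx, size=floor, replace=False)
            keep.extend(sorted(int(i) for i in chosen))
        keep.sort()
        recordings = [recordings[i] for i in keep]
        truths = [truths[i] for i in keep]
        labels = [labels[i] for i in keep]
    return recordings, labels, truths
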