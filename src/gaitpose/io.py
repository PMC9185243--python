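"""Keypoint trajectory and feature-table I/O.

The pipeline's raw input is a time-ordered sequence of 2D lower-limb
keypoints (hip, knee, ankle per side) as produced by a pose-estimation
network.  Two on-disk dialects are supported: per-frame JSON documents in
the standard 25-keypoint body layout ("people" list with a flat
``pose_keypoints_2d`` array of x, y, confidence triples) and a long-format
trajectory CSV.  Extracted gait features round-trip through a fixed
11-column CSV schema.

Image coordinate convention: x increases rightward, y increases downward
(standard image frame).  A missing detection is encoded as confidence 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

SIDES = ("left", "right")
JOINTS = ("hip", "knee", "ankle")

#: Fixed order of the 11 gait features.
FEATURE_COLUMNS = (
    "LSS", "RSS", "LLK", "LRK", "AS", "APT", "AST", "VOR", "VOL", "KAV", "KAA",
)

#: The six gait classes (normal walking plus five abnormal phenotypes).
GAIT_CLASSES = (
    "standard", "mop", "drunk", "intermittent", "magnetic", "scissor",
)

#: Joint indices of the lower limb in the 25-keypoint body layout.
BODY25_INDICES = {
    ("right", "hip"): 9,
    ("right", "knee"): 10,
    ("right", "ankle"): 11,
    ("left", "hip"): 12,
    ("left", "knee"): 13,
    ("left", "ankle"): 14,
}

_N_BODY25 = 25


@dataclass(frozen=True)
class Keypoint2D:
    """One detected joint: image position plus detection confidence."""

    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence!r} outside [0, 1]")
        if self.confidence > 0 and not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("non-finite coordinates with positive confidence")

    @property
    def missing(self) -> bool:
        return self.confidence == 0.0


@dataclass(frozen=True)
class LowerLimbFrame:
    """The six lower-limb keypoints of one video frame."""

    time: float
    keypoints: Mapping[tuple[str, str], Keypoint2D]

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("frame time must be >= 0")
        expected = {(s, j) for s in SIDES for j in JOINTS}
        if set(self.keypoints) != expected:
            raise ValueError("a frame must carry exactly six lower-limb keypoints")

    def get(self, side: str, joint: str) -> Keypoint2D:
        return self.keypoints[(side, joint)]


class GaitRecording:
    """A time-ordered 2D lower-limb keypoint trajectory.

    Internally a ``(n_frames, 2 sides, 3 joints, 3)`` float array holding
    (x, y, confidence), with sides ordered (left, right) and joints
    (hip, knee, ankle).  Frame times must be strictly increasing and
    consistent with ``fps`` to within 10%.
    """

    def __init__(
        self,
        times: np.ndarray,
        coords: np.ndarray,
        fps: float,
        meta: dict | None = None,
        _validate: bool = True,
    ) -> None:
        self.times = np.asarray(times, dtype=float)
        self.coords = np.asarray(coords, dtype=float)
        self.fps = float(fps)
        self.meta = dict(meta) if meta else {}
        if _validate:
            self._validate()

    def _validate(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        n = self.times.shape[0]
        if n < 2:
            raise ValueError("a recording needs at least two frames")
        if self.coords.shape != (n, 2, 3, 3):
            raise ValueError(f"coords must have shape ({n}, 2, 3, 3)")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("frame times must be strictly increasing")
        nominal = 1.0 / self.fps
        if np.any(np.abs(dt - nominal) > 0.1 * nominal):
            raise ValueError("frame spacing inconsistent with fps (>10% off)")
        conf = self.coords[..., 2]
        if conf.min() < 0 or conf.max() > 1:
            raise ValueError("confidences must lie in [0, 1]")
        xy = self.coords[..., :2]
        detected = conf > 0
        if not np.all(np.isfinite(xy[detected])):
            raise ValueError("non-finite coordinates with positive confidence")

    # -- accessors ---------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    def side_joint(self, side: str, joint: str) -> np.ndarray:
        """(n_frames, 3) array of (x, y, confidence) for one joint."""
        return self.coords[:, SIDES.index(side), JOINTS.index(joint), :]

    def frame(self, i: int) -> LowerLimbFrame:
        kps = {
            (s, j): Keypoint2D(*self.coords[i, si, ji])
            for si, s in enumerate(SIDES)
            for ji, j in enumerate(JOINTS)
        }
        return LowerLimbFrame(time=float(self.times[i]), keypoints=kps)

    def frames(self) -> Iterable[LowerLimbFrame]:
        return (self.frame(i) for i in range(self.n_frames))

    def copy(self) -> "GaitRecording":
        return GaitRecording(
            self.times.copy(), self.coords.copy(), self.fps, dict(self.meta),
            _validate=False,
        )

    def mirrored(self) -> "GaitRecording":
        """Swap the left and right legs (left/right exchange symmetry)."""
        out = self.copy()
        out.coords = out.coords[:, ::-1].copy()
        out.meta["mirrored"] = not self.meta.get("mirrored", False)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GaitRecording):
            return NotImplemented
        return (
            self.fps == other.fps
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.coords, other.coords)
        )

    def __repr__(self) -> str:
        label = self.meta.get("gait", "?")
        return (
            f"<GaitRecording {self.n_frames} frames @ {self.fps:g} fps, "
            f"gait={label}>"
        )


# -- OpenPose-style per-frame JSON ----------------------------------------


def _extract_person(doc: dict, frame_name: str) -> np.ndarray:
    """Pull the six lower-limb keypoints out of one frame document."""
    out = np.zeros((2, 3, 3))
    try:
        people = doc["people"]
    except (TypeError, KeyError) as exc:
        raise ParseError(f"frame {frame_name!r}: no 'people' list") from exc
    if not people:
        return out
    arrays = []
    for person in people:
        kp = np.asarray(person.get("pose_keypoints_2d", ()), dtype=float)
        if kp.size != 3 * _N_BODY25:
            raise ParseError(
                f"frame {frame_name!r}: expected {3 * _N_BODY25} keypoint "
                f"values, got {kp.size}"
            )
        arrays.append(kp.reshape(_N_BODY25, 3))
    if len(arrays) > 1:
        warnings.warn(
            f"frame {frame_name!r}: {len(arrays)} people detected; "
            "keeping the highest-confidence one",
            stacklevel=3,
        )
    best = max(arrays, key=lambda a: a[:, 2].sum())
    for (side, joint), idx in BODY25_INDICES.items():
        out[SIDES.index(side), JOINTS.index(joint)] = best[idx]
    return out


def read_openpose_json(
    source, fps: float = 30.0, meta: dict | None = None
) -> GaitRecording:
    """Read per-frame JSON keypoint documents into a :class:`GaitRecording`.

    ``source`` may be a directory of ``*.json`` files (frame order follows
    sorted filenames), an explicit sequence of file paths, or a single JSON
    file containing a list of frame documents.  Frames with an empty
    ``people`` list yield six all-zero-confidence keypoints.
    """
    docs: list[tuple[str, dict]] = []
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.is_dir():
            files = sorted(path.glob("*.json"))
            if not files:
                raise ParseError(f"no JSON files under {path}")
            for f in files:
                docs.append((f.name, _load_json(f)))
        else:
            payload = _load_json(path)
            if not isinstance(payload, list):
                raise ParseError(f"{path}: expected a JSON list of frame documents")
            docs = [(f"{path.name}[{i}]", d) for i, d in enumerate(payload)]
    else:
        for f in source:
            f = Path(f)
            docs.append((f.name, _load_json(f)))

    n = len(docs)
    if n < 2:
        raise ParseError("need at least two frame documents")
    coords = np.zeros((n, 2, 3, 3))
    for i, (name, doc) in enumerate(docs):
        coords[i] = _extract_person(doc, name)
    times = np.arange(n) / fps
    return GaitRecording(times, coords, fps, meta)


def _load_json(path: Path):
    try:
        with open(path, "r", encoding="utf-8") as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON in frame {path.name!r}: {exc}") from exc


def write_openpose_json(rec: GaitRecording, directory) -> list[Path]:
    """Write one 25-keypoint JSON document per frame (non-limb joints zero)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(rec.n_frames):
        flat = np.zeros((_N_BODY25, 3))
        for (side, joint), idx in BODY25_INDICES.items():
            flat[idx] = rec.coords[i, SIDES.index(side), JOINTS.index(joint)]
        doc = {"people": [{"pose_keypoints_2d": flat.ravel().tolist()}]}
        p = directory / f"frame_{i:06d}_keypoints.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
        paths.append(p)
    return paths


# -- trajectory CSV --------------------------------------------------------

_CSV_COLUMNS = ["frame", "time_s"] + [
    f"{side}_{joint}_{comp}"
    for side in SIDES
    for joint in JOINTS
    for comp in ("x", "y", "conf")
]


def write_trajectory_csv(rec: GaitRecording, path) -> None:
    data = {"frame": np.arange(rec.n_frames), "time_s": rec.times}
    for si, side in enumerate(SIDES):
        for ji, joint in enumerate(JOINTS):
            for ci, comp in enumerate(("x", "y", "conf")):
                data[f"{side}_{joint}_{comp}"] = rec.coords[:, si, ji, ci]
    pd.DataFrame(data, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_trajectory_csv(path, fps: float | None = None, meta: dict | None = None) -> GaitRecording:
    """Read a trajectory CSV.  Rows are sorted by time on read.

    If ``fps`` is omitted it is inferred from the median time step.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trajectory CSV missing columns: {', '.join(missing)}")
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    n = len(df)
    coords = np.zeros((n, 2, 3, 3))
    for si, side in enumerate(SIDES):
        for ji, joint in enumerate(JOINTS):
            for ci, comp in enumerate(("x", "y", "conf")):
                coords[:, si, ji, ci] = df[f"{side}_{joint}_{comp}"].to_numpy()
    times = df["time_s"].to_numpy(dtype=float)
    if fps is None:
        fps = 1.0 / float(np.median(np.diff(times)))
    return GaitRecording(times, coords, fps, meta)


# -- missing-detection interpolation ---------------------------------------


def interpolate_missing(rec: GaitRecording, max_gap: int) -> GaitRecording:
    """Fill short runs of missing detections by linear interpolation.

    Runs of confidence-0 frames of length <= ``max_gap`` are replaced by a
    linear interpolation between the flanking detections; the interpolated
    confidence is the minimum of the flanks.  Longer (or unflanked) runs are
    left untouched and listed in ``meta['unfilled_gaps']``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = rec.copy()
    unfilled: list[dict] = []
    for si, side in enumerate(SIDES):
        for ji, joint in enumerate(JOINTS):
            track = out.coords[:, si, ji, :]
            conf = track[:, 2]
            missing = conf == 0.0
            i = 0
            n = len(conf)
            while i < n:
                if not missing[i]:
                    i += 1
                    continue
                j = i
                while j < n and missing[j]:
                    j += 1
                run = j - i
                flanked = i > 0 and j < n
                if flanked and run <= max_gap:
                    t0, t1 = rec.times[i - 1], rec.times[j]
                    w = (rec.times[i:j] - t0) / (t1 - t0)
                    for ci in range(2):
                        a, b = track[i - 1, ci], track[j, ci]
                        track[i:j, ci] = a + w * (b - a)
                    track[i:j, 2] = min(conf[i - 1], conf[j])
                elif run > 0:
                    unfilled.append(
                        {"side": side, "joint": joint, "start": i, "length": run}
                    )
                i = j
    if unfilled:
        out.meta["unfilled_gaps"] = unfilled
    return out


# -- feature table ---------------------------------------------------------


def _row_dict(row) -> dict:
    if hasattr(row, "as_dict"):
        row = row.as_dict()
    row = dict(row)
    if set(row) != set(FEATURE_COLUMNS):
        extra = sorted(set(row) - set(FEATURE_COLUMNS))
        missing = sorted(set(FEATURE_COLUMNS) - set(row))
        raise SchemaError(
            f"feature row schema mismatch (missing={missing}, extra={extra})"
        )
    return row


def write_feature_table(
    features: Sequence, labels: Sequence[str] | None, path
) -> None:
    """Write one row per recording: the 11 features plus a label column."""
    rows = [_row_dict(f) for f in features]
    if labels is None:
        labels = [""] * len(rows)
    if len(labels) != len(rows):
        raise SchemaError("labels and feature rows differ in length")
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    df["label"] = list(labels)
    # full precision so that write/read round-trips to 1e-12
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a feature table CSV, returning (features, labels)."""
    df = pd.read_csv(path)
    missing = [c for c in (*FEATURE_COLUMNS, "label") if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {', '.join(missing)}")
    X = df[list(FEATURE_COLUMNS)]
    y = df["label"].astype(str)
    return X, y
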