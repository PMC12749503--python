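"""Read, validate and write pose-keypoint sequences.

The on-disk format is a JSON envelope produced by markerless pose trackers:
a ``Timeline`` of per-frame items, each holding the 33 landmarks of the
standard full-body pose topology as normalized ``(x, y, z)`` coordinates
plus a visibility confidence, together with video metadata (``Width``,
``Height``, ``AverageFPS``, ``TotalNumberOfFrames``).  The machine-readable
schema lives in ``data/pose_schema.json``.

Coordinates follow the image convention: ``x`` is a fraction of the frame
width, ``y`` a fraction of the frame height and increases downward.  ``z``
(relative depth) is read and preserved for round-tripping but unused by all
downstream computation, which is strictly planar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

N_LANDMARKS = 33

#: Names of the 33 landmarks in topology order (nose .. right foot index).
LANDMARK_NAMES = [
    "nose", "left_eye_inner", "left_eye", "left_eye_outer", "right_eye_inner",
    "right_eye", "right_eye_outer", "left_ear", "right_ear", "mouth_left",
    "mouth_right", "left_shoulder", "right_shoulder", "left_elbow",
    "right_elbow", "left_wrist", "right_wrist", "left_pinky", "right_pinky",
    "left_index", "right_index", "left_thumb", "right_thumb", "left_hip",
    "right_hip", "left_knee", "right_knee", "left_ankle", "right_ankle",
    "left_heel", "right_heel", "left_foot_index", "right_foot_index",
]


class PoseIOError(Exception):
    """Base error for pose-file reading problems."""


class SchemaError(PoseIOError):
    """A required key is missing or has the wrong type."""


class StructuralError(PoseIOError):
    """A frame violates the structural contract (e.g. landmark count)."""


@dataclass
class Landmark:
    """One tracked anatomical point in one frame."""

    x: float
    y: float
    z: float | None = None
    visibility: float = 1.0


@dataclass
class PoseFrame:
    """All 33 landmarks of one frame, 0-based ``index``."""

    index: int
    landmarks: list[Landmark]


@dataclass
class PoseSequence:
    """An ordered landmark time series with its video metadata.

    ``total_frames`` counts frames with valid keypoints and must equal
    ``len(frames)`` after validation.  Timestamps are ``index / fps``.
    """

    frames: list[PoseFrame]
    width: int
    height: int
    fps: float

    @property
    def total_frames(self) -> int:
        return len(self.frames)

    def coords(self):
        """Normalized coordinates as a ``(n_frames, 33, 2)`` float array."""
        import numpy as np

        return np.array(
            [[[lm.x, lm.y] for lm in fr.landmarks] for fr in self.frames],
            dtype=float,
        ).reshape(len(self.frames), N_LANDMARKS, 2)

    def visibility(self):
        """Visibility confidences as a ``(n_frames, 33)`` float array."""
        import numpy as np

        return np.array(
            [[lm.visibility for lm in fr.landmarks] for fr in self.frames],
            dtype=float,
        ).reshape(len(self.frames), N_LANDMARKS)


@dataclass
class ValidationIssue:
    frame: int | None
    landmark: int | None
    code: str
    message: str
    severity: str = "error"  # "error" | "warning"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"missing required key {key!r} in {where}")
    return mapping[key]


def _as_number(value, what: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise StructuralError(f"non-numeric {what}: {value!r}")
    return float(value)


def read_pose_json(path: str | Path) -> PoseSequence:
    """Read a pose-keypoint JSON file into a :class:`PoseSequence`.

    Raises :class:`SchemaError` naming the missing key, or
    :class:`StructuralError` citing the offending frame, rather than
    returning a partially populated object.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)

    timeline = _require(doc, "Timeline", "document root")
    width = int(_as_number(_require(doc, "Width", "document root"), "Width"))
    height = int(_as_number(_require(doc, "Height", "document root"), "Height"))
    fps = _as_number(_require(doc, "AverageFPS", "document root"), "AverageFPS")
    _require(timeline, "TotalNumberOfFrames", "Timeline")
    items = _require(timeline, "Items", "Timeline")

    frames: list[PoseFrame] = []
    for i, item in enumerate(items):
        lms_raw = _require(item, "Landmarks", f"Timeline.Items[{i}]")
        if len(lms_raw) != N_LANDMARKS:
            raise StructuralError(
                f"frame {i}: expected {N_LANDMARKS} landmarks, got {len(lms_raw)}"
            )
        landmarks = []
        for j, lm in enumerate(lms_raw):
            x = _as_number(_require(lm, "x", f"frame {i} landmark {j}"),
                           f"x (frame {i}, landmark {j})")
            y = _as_number(_require(lm, "y", f"frame {i} landmark {j}"),
                           f"y (frame {i}, landmark {j})")
            z = lm.get("z")
            if z is not None:
                z = _as_number(z, f"z (frame {i}, landmark {j})")
            vis = _as_number(lm.get("visibility", 1.0),
                             f"visibility (frame {i}, landmark {j})")
            landmarks.append(Landmark(x=x, y=y, z=z, visibility=vis))
        frames.append(PoseFrame(index=int(item.get("Index", i)), landmarks=landmarks))

    return PoseSequence(frames=frames, width=width, height=height, fps=fps)


def write_pose_json(seq: PoseSequence, path: str | Path) -> None:
    """Write ``seq`` so that :func:`read_pose_json` round-trips it exactly."""
    items = []
    for fr in seq.frames:
        lms = []
        for lm in fr.landmarks:
            rec = {"x": lm.x, "y": lm.y, "visibility": lm.visibility}
            if lm.z is not None:
                rec["z"] = lm.z
            lms.append(rec)
        items.append({"Index": fr.index, "Landmarks": lms})
    doc = {
        "Timeline": {"TotalNumberOfFrames": seq.total_frames, "Items": items},
        "Width": seq.width,
        "Height": seq.height,
        "AverageFPS": seq.fps,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def validate_sequence(seq: PoseSequence) -> ValidationReport:
    """Check every declared invariant; report, never raise.

    Checked: landmark count per frame, coordinate finiteness, visibility
    range, strictly increasing frame indices, metadata positivity.
    Coordinates slightly outside [0, 1] are flagged as warnings only — a
    landmark may legitimately leave the frame.
    """
    report = ValidationReport()
    add = report.issues.append

    if seq.width <= 0:
        add(ValidationIssue(None, None, "bad_width", f"width must be > 0, got {seq.width}"))
    if seq.height <= 0:
        add(ValidationIssue(None, None, "bad_height", f"height must be > 0, got {seq.height}"))
    if seq.fps <= 0:
        add(ValidationIssue(None, None, "bad_fps", f"fps must be > 0, got {seq.fps}"))

    prev_index = -1
    for fi, fr in enumerate(seq.frames):
        if fr.index <= prev_index:
            add(ValidationIssue(fi, None, "index_order",
                                f"frame index {fr.index} not strictly increasing"))
        prev_index = fr.index
        if len(fr.landmarks) != N_LANDMARKS:
            add(ValidationIssue(fi, None, "landmark_count",
                                f"expected {N_LANDMARKS} landmarks, got {len(fr.landmarks)}"))
            continue
        for li, lm in enumerate(fr.landmarks):
            if not (math.isfinite(lm.x) and math.isfinite(lm.y)):
                add(ValidationIssue(fi, li, "nonfinite_coordinate",
                                    f"coordinate not finite: ({lm.x}, {lm.y})"))
            if not (0.0 <= lm.visibility <= 1.0):
                add(ValidationIssue(fi, li, "visibility_range",
                                    f"visibility {lm.visibility} outside [0, 1]"))
            if math.isfinite(lm.x) and math.isfinite(lm.y):
                if not (-0.5 <= lm.x <= 1.5 and -0.5 <= lm.y <= 1.5):
                    add(ValidationIssue(fi, li, "coordinate_out_of_frame",
                                        f"coordinate ({lm.x:.3f}, {lm.y:.3f}) far outside frame",
                                        severity="warning"))
    return report


def sequence_from_arrays(coords, visibility, width: int, height: int,
                         fps: float, z=None) -> PoseSequence:
    """Build a :class:`PoseSequence` from ``(n, 33, 2)`` normalized coords."""
    frames = []
    n = len(coords)
    for i in range(n):
        landmarks = [
            Landmark(
                x=float(coords[i, j, 0]),
                y=float(coords[i, j, 1]),
                z=(float(z[i, j]) if z is not None else 0.0),
                visibility=float(visibility[i, j]),
            )
            for j in range(N_LANDMARKS)
        ]
        frames.append(PoseFrame(index=i, landmarks=landmarks))
    return PoseSequence(frames=frames, width=width, height=height, fps=fps)


def schema_path() -> Path:
    """Path of the shipped machine-readable schema document."""
    return Path(__file__).parent / "data" / "pose_schema.json"


def check_against_schema(doc: dict) -> list[str]:
    """Validate a parsed JSON document against the shipped schema.

    A deliberately small structural validator (required keys, JSON types,
    fixed landmark count); returns a list of human-readable problems,
    empty when the document conforms.
    """
    with open(schema_path()) as fh:
        schema = json.load(fh)
    problems: list[str] = []

    for key, spec in schema["properties"].items():
        if key in schema.get("required", []) and key not in doc:
            problems.append(f"missing top-level key {key!r}")
    if problems:
        return problems

    if not isinstance(doc["Timeline"], dict):
        problems.append("Timeline must be an object")
        return problems
    for key in schema["properties"]["Timeline"].get("required", []):
        if key not in doc["Timeline"]:
            problems.append(f"missing Timeline key {key!r}")
    if problems:
        return problems

    items = doc["Timeline"]["Items"]
    if not isinstance(items, list):
        problems.append("Timeline.Items must be an array")
        return problems
    for i, item in enumerate(items):
        lms = item.get("Landmarks")
        if not isinstance(lms, list) or len(lms) != N_LANDMARKS:
            problems.append(f"Items[{i}].Landmarks must hold exactly {N_LANDMARKS} entries")
            continue
        for j, lm in enumerate(lms):
            for key in ("x", "y", "visibility"):
                if not isinstance(lm.get(key), (int, float)) or isinstance(lm.get(key), bool):
                    problems.append(f"Items[{i}].Landmarks[{j}].{key} must be a number")
    return problems
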