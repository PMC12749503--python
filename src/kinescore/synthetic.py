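"""Ground-truth-known synthetic motion: angle cycles driven through a
planar skeleton into the 33-landmark pose layout.

The generator exists so that every pipeline stage can be tested against
known parameters without any recorded video: repetitions are raised-cosine
joint-angle cycles (so each trajectory starts and ends at its trough,
making trough-peak-trough segmentation exact at the boundaries), rendered
by planar forward kinematics over an anthropometric skeleton, and
optionally corrupted with the disturbance taxonomy of real pose tracking —
per-landmark Gaussian jitter, shared global drift, and bursty visibility
dropout.  Everything is seeded and reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .keypoint_io import N_LANDMARKS, PoseSequence, sequence_from_arrays

# Landmark indices used by the planar skeleton.
NOSE = 0
L_SHOULDER, R_SHOULDER = 11, 12
L_ELBOW, R_ELBOW = 13, 14
L_WRIST, R_WRIST = 15, 16
L_PINKY, R_PINKY = 17, 18
L_INDEX, R_INDEX = 19, 20
L_THUMB, R_THUMB = 21, 22
L_HIP, R_HIP = 23, 24
L_KNEE, R_KNEE = 25, 26
L_ANKLE, R_ANKLE = 27, 28
L_HEEL, R_HEEL = 29, 30
L_FOOT, R_FOOT = 31, 32

_SIDE_IDX = {
    "left": dict(shoulder=L_SHOULDER, elbow=L_ELBOW, wrist=L_WRIST,
                 pinky=L_PINKY, index=L_INDEX, thumb=L_THUMB, hip=L_HIP,
                 knee=L_KNEE, ankle=L_ANKLE, heel=L_HEEL, foot=L_FOOT,
                 other_hip=R_HIP),
    "right": dict(shoulder=R_SHOULDER, elbow=R_ELBOW, wrist=R_WRIST,
                  pinky=R_PINKY, index=R_INDEX, thumb=R_THUMB, hip=R_HIP,
                  knee=R_KNEE, ankle=R_ANKLE, heel=R_HEEL, foot=R_FOOT,
                  other_hip=L_HIP),
}

#: Driveable joints and the skeleton degree of freedom each one controls.
DRIVEABLE = {
    "left_shoulder": ("left", "shoulder"),
    "right_shoulder": ("right", "shoulder"),
    "left_elbow": ("left", "elbow"),
    "right_elbow": ("right", "elbow"),
    "left_hip_sagittal": ("left", "hip_sagittal"),
    "right_hip_sagittal": ("right", "hip_sagittal"),
    "left_hip_frontal": ("left", "hip_frontal"),
    "right_hip_frontal": ("right", "hip_frontal"),
    "left_knee": ("left", "knee"),
    "right_knee": ("right", "knee"),
}


class SpecError(ValueError):
    """A synthetic-motion parameter is out of range."""


@dataclass
class DrivenJoint:
    joint: str
    baseline: float      # degrees; the trough angle
    rom: float           # degrees; peak = baseline + rom
    n_reps: int
    phase: float = 0.0   # radians


@dataclass
class SyntheticMotionSpec:
    """Generator parameters; the known values are the recovery targets."""

    driven: list[DrivenJoint]
    exercise: str = "exercise"
    fps: float = 30.0
    duration: float = 10.0          # seconds
    noise_sigma: float = 0.0        # normalized-coordinate units
    dropout_prob: float = 0.0       # per-landmark per-frame burst onset
    dropout_burst: int = 3          # mean burst length, frames
    drift_amplitude: float = 0.0    # pixels
    seed: int = 0
    width: int = 1280
    height: int = 720

    def validate(self) -> None:
        if self.fps <= 0:
            raise SpecError(f"fps must be > 0, got {self.fps}")
        if self.duration * self.fps < 3:
            raise SpecError("duration*fps must be >= 3 frames")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise SpecError(f"dropout_prob must be in [0,1], got {self.dropout_prob}")
        if self.noise_sigma < 0:
            raise SpecError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.dropout_burst < 1:
            raise SpecError(f"dropout_burst must be >= 1, got {self.dropout_burst}")
        for dj in self.driven:
            if dj.joint not in DRIVEABLE:
                raise SpecError(f"unknown driven joint {dj.joint!r}")
            if dj.rom < 0:
                raise SpecError(f"{dj.joint}: rom must be >= 0, got {dj.rom}")
            if dj.n_reps < 0:
                raise SpecError(f"{dj.joint}: n_reps must be >= 0, got {dj.n_reps}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticMotionSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        driven = [DrivenJoint(**d) for d in raw.pop("driven", [])]
        spec = cls(driven=driven, **raw)
        spec.validate()
        return spec

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class SkeletonTemplate:
    """Planar skeleton: anthropometric segment lengths (pixels), rest-pose
    joint angles, and per-side rotation signs."""

    stature: float
    root: tuple[float, float]           # fraction of frame
    lengths: dict[str, float]           # pixels
    rest_angles: dict[str, float]       # degrees
    rotation_sign: dict[str, int]

    @classmethod
    def load(cls, path: str | Path | None = None) -> "SkeletonTemplate":
        if path is None:
            path = Path(__file__).parent / "data" / "skeleton.yaml"
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        s = float(raw["stature_px"])
        lengths = {k: float(v) * s for k, v in raw["proportions"].items()}
        return cls(stature=s, root=tuple(raw["root"]), lengths=lengths,
                   rest_angles={k: float(v) for k, v in raw["rest_angles"].items()},
                   rotation_sign={k: int(v) for k, v in raw["rotation_sign"].items()})


def generate_angle_trajectory(baseline: float, rom: float, n_reps: int,
                              fps: float, duration: float,
                              phase: float = 0.0) -> np.ndarray:
    """Raised-cosine repetition cycles.

    ``theta(t) = baseline + (rom/2) * (1 - cos(2*pi*n_reps*t/T + phase))``
    over ``round(duration*fps)`` frames: the trajectory starts and ends at
    the trough (``baseline``), peaks at ``baseline + rom``, and has exactly
    ``n_reps`` maxima inside (0, T).
    """
    if fps <= 0 or duration <= 0:
        raise SpecError("fps and duration must be positive")
    n_frames = round(duration * fps)
    if n_frames < 3:
        raise SpecError("need at least 3 frames")
    if rom < 0 or n_reps < 0:
        raise SpecError("rom and n_reps must be nonnegative")
    t = np.arange(n_frames) / fps
    return baseline + (rom / 2.0) * (1.0 - np.cos(2 * np.pi * n_reps * t / duration + phase))


def _rot(vec: np.ndarray, degrees: float) -> np.ndarray:
    r = math.radians(degrees)
    c, s = math.cos(r), math.sin(r)
    return np.array([c * vec[0] - s * vec[1], s * vec[0] + c * vec[1]])


def _unit(vec: np.ndarray) -> np.ndarray:
    return vec / np.hypot(*vec)


def forward_kinematics(assignments: dict[str, np.ndarray],
                       skeleton: SkeletonTemplate | None = None,
                       width: int = 1280, height: int = 720,
                       fps: float = 30.0) -> PoseSequence:
    """Render per-frame joint-angle assignments into a pose sequence.

    Each driveable joint rotates its distal segment about the vertex so
    that the measured triplet angle equals the assigned angle exactly;
    undriven joints hold the skeleton's rest pose.  Output is normalized
    by the frame size with visibility 1 everywhere.
    """
    if skeleton is None:
        skeleton = SkeletonTemplate.load()
    for name in assignments:
        if name not in DRIVEABLE:
            raise SpecError(f"cannot drive unknown joint {name!r}")
    if assignments:
        sizes = {len(np.atleast_1d(v)) for v in assignments.values()}
        if len(sizes) != 1:
            raise SpecError("all driven angle series must share one length")
        n_frames = sizes.pop()
    else:
        n_frames = round(fps)

    for side in ("left", "right"):
        if (f"{side}_hip_sagittal" in assignments
                and f"{side}_hip_frontal" in assignments):
            raise SpecError(f"{side} hip: sagittal and frontal drivers conflict")

    L = skeleton.lengths
    rest = skeleton.rest_angles
    cx, cy = skeleton.root[0] * width, skeleton.root[1] * height
    sh_y = cy - L["trunk"]

    coords = np.zeros((n_frames, N_LANDMARKS, 2))
    for f in range(n_frames):
        pts = np.zeros((N_LANDMARKS, 2))
        # trunk and head (static)
        mid_sh = np.array([cx, sh_y])
        pts[L_HIP] = [cx + L["hip_half_width"], cy]
        pts[R_HIP] = [cx - L["hip_half_width"], cy]
        pts[L_SHOULDER] = [cx + L["shoulder_half_width"], sh_y]
        pts[R_SHOULDER] = [cx - L["shoulder_half_width"], sh_y]
        nose = mid_sh - np.array([0.0, L["neck_to_nose"]])
        pts[NOSE] = nose
        hr = L["head_radius"]
        # face cluster: eyes, ears, mouth as fixed offsets around the nose
        face = {1: (0.3, -0.5), 2: (0.5, -0.5), 3: (0.7, -0.5),
                4: (-0.3, -0.5), 5: (-0.5, -0.5), 6: (-0.7, -0.5),
                7: (1.0, -0.2), 8: (-1.0, -0.2),
                9: (0.3, 0.4), 10: (-0.3, 0.4)}
        for li, (ox, oy) in face.items():
            pts[li] = nose + hr * np.array([ox, oy])

        for side in ("left", "right"):
            idx = _SIDE_IDX[side]
            s = skeleton.rotation_sign[side]
            hip = pts[idx["hip"]]
            shoulder = pts[idx["shoulder"]]

            # leg: thigh rotates off the trunk (or off the pelvis line in
            # frontal mode), shank off the thigh
            if f"{side}_hip_frontal" in assignments:
                ref = _unit(pts[idx["other_hip"]] - hip)
                th = float(np.atleast_1d(assignments[f"{side}_hip_frontal"])[f])
            else:
                ref = _unit(shoulder - hip)
                key = f"{side}_hip_sagittal"
                th = (float(np.atleast_1d(assignments[key])[f])
                      if key in assignments else rest["hip_sagittal"])
            knee = hip + L["thigh"] * _rot(ref, s * th)
            pts[idx["knee"]] = knee

            key = f"{side}_knee"
            th = (float(np.atleast_1d(assignments[key])[f])
                  if key in assignments else rest["knee"])
            ankle = knee + L["shank"] * _rot(_unit(hip - knee), s * th)
            pts[idx["ankle"]] = ankle
            shank_dir = _unit(ankle - knee)
            pts[idx["heel"]] = ankle + L["heel"] * shank_dir
            pts[idx["foot"]] = ankle + L["foot"] * _rot(shank_dir, s * 90.0)

            # arm: upper arm rotates off the trunk, forearm off the upper arm
            key = f"{side}_shoulder"
            th = (float(np.atleast_1d(assignments[key])[f])
                  if key in assignments else rest["shoulder"])
            elbow = shoulder + L["upper_arm"] * _rot(_unit(hip - shoulder), s * th)
            pts[idx["elbow"]] = elbow

            key = f"{side}_elbow"
            th = (float(np.atleast_1d(assignments[key])[f])
                  if key in assignments else rest["elbow"])
            wrist = elbow + L["forearm"] * _rot(_unit(shoulder - elbow), s * th)
            pts[idx["wrist"]] = wrist
            hand_dir = _unit(wrist - elbow)
            pts[idx["index"]] = wrist + L["hand"] * hand_dir
            pts[idx["pinky"]] = wrist + L["hand"] * _rot(hand_dir, s * 15.0)
            pts[idx["thumb"]] = wrist + 0.6 * L["hand"] * _rot(hand_dir, -s * 25.0)

        coords[f] = pts

    norm = np.empty_like(coords)
    norm[..., 0] = coords[..., 0] / width
    norm[..., 1] = coords[..., 1] / height
    visibility = np.ones((n_frames, N_LANDMARKS))
    return sequence_from_arrays(norm, visibility, width=width, height=height, fps=fps)


def corrupt(seq: PoseSequence, spec: SyntheticMotionSpec) -> PoseSequence:
    """Apply seeded jitter, global drift and visibility dropout.

    * i.i.d. Gaussian noise, sd ``noise_sigma`` (normalized units), per
      landmark coordinate;
    * a shared sinusoidal translation of all landmarks (amplitude
      ``drift_amplitude`` pixels, 0.25 Hz) — pure translation, so joint
      angles are untouched by construction;
    * visibility dropped to 0 in bursts: per-landmark Bernoulli onset with
      probability ``dropout_prob`` per frame, geometric burst length with
      mean ``dropout_burst``.

    With all corruption parameters zero this is the identity.
    """
    if spec.noise_sigma == 0 and spec.dropout_prob == 0 and spec.drift_amplitude == 0:
        return seq
    rng = np.random.default_rng(spec.seed)
    coords = seq.coords()
    vis = seq.visibility()
    n = len(coords)

    if spec.drift_amplitude > 0:
        t = np.arange(n) / seq.fps
        dx = spec.drift_amplitude * np.sin(2 * np.pi * 0.25 * t) / seq.width
        dy = spec.drift_amplitude * np.cos(2 * np.pi * 0.25 * t) / seq.height
        coords[..., 0] += dx[:, None]
        coords[..., 1] += dy[:, None]

    if spec.noise_sigma > 0:
        coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)

    if spec.dropout_prob > 0:
        onsets = rng.random((n, N_LANDMARKS)) < spec.dropout_prob
        for f, j in zip(*np.nonzero(onsets)):
            burst = rng.geometric(1.0 / spec.dropout_burst)
            vis[f: f + burst, j] = 0.0
    return sequence_from_arrays(coords, vis, width=seq.width,
                                height=seq.height, fps=seq.fps)


def simulate(spec: SyntheticMotionSpec,
             skeleton: SkeletonTemplate | None = None) -> PoseSequence:
    """Render a full synthetic recording from a motion spec."""
    spec.validate()
    assignments = {
        dj.joint: generate_angle_trajectory(dj.baseline, dj.rom, dj.n_reps,
                                            spec.fps, spec.duration, dj.phase)
        for dj in spec.driven
    }
    seq = forward_kinematics(assignments, skeleton=skeleton, width=spec.width,
                             height=spec.height, fps=spec.fps)
    return corrupt(seq, spec)


def make_pair(user_spec: SyntheticMotionSpec,
              reference_spec: SyntheticMotionSpec,
              skeleton: SkeletonTemplate | None = None
              ) -> tuple[PoseSequence, PoseSequence]:
    """Render a user/reference pair over a shared skeleton.

    Any intended discrepancy (different ROM, repetition count, speed,
    corruption) is exactly the difference between the two specs, giving
    ground truth for end-to-end scoring tests.
    """
    if skeleton is None:
        skeleton = SkeletonTemplate.load()
    return simulate(user_spec, skeleton), simulate(reference_spec, skeleton)
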