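"""Kinematic feature extraction: joint angles, ROM, angular velocity.

A joint angle is the angle at the vertex of a (proximal, vertex, distal)
landmark triplet, computed from the dot product of the two limb vectors::

    a = p_proximal - p_vertex,  b = p_distal - p_vertex
    theta = arccos(a . b / (|a| |b|))          in [0, 180] degrees

Angles are invariant to global translation, rotation and uniform scaling of
the keypoints, which is what makes angular features robust to camera
placement and detector jitter.  They must therefore be computed on pixel
(or any isotropically scaled) coordinates — anisotropic bounding-box
normalization distorts them.

An optional *signed* mode returns the counterclockwise angle from the
proximal to the distal limb vector in [0, 360), admitting reflex angles
(hyperextension beyond 180 degrees) that the arccos form folds back.

Units: degrees, seconds and degrees/second externally; radians only inside
trigonometric calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .keypoint_io import N_LANDMARKS


class DegenerateGeometryError(ValueError):
    """A limb vector has zero length; the angle is undefined."""


@dataclass(frozen=True)
class JointDefinition:
    """A named joint: three distinct landmark indices with the vertex in
    the middle, plus an anatomical plane label used only for reporting."""

    name: str
    triplet: tuple[int, int, int]
    plane: str = "sagittal"

    def __post_init__(self):
        if len(set(self.triplet)) != 3:
            raise ValueError(f"{self.name}: triplet indices must be distinct")
        if not all(0 <= i < N_LANDMARKS for i in self.triplet):
            raise ValueError(f"{self.name}: indices must be in [0, {N_LANDMARKS - 1}]")


@dataclass
class JointAngleSeries:
    """Per-frame angle (degrees) for one joint; ``valid`` marks frames where
    every triplet landmark was usable."""

    joint: JointDefinition
    angles: np.ndarray   # (n_frames,) degrees; NaN where invalid
    valid: np.ndarray    # (n_frames,) bool
    fps: float


@dataclass
class KinematicSummary:
    """ROM and extreme angles, optionally with across-repetition spread."""

    rom: float
    theta_max: float
    theta_min: float
    mean_velocity: float | None = None
    velocity_sd: float | None = None
    rom_sd: float | None = None
    n_repetitions: int | None = None
    single_repetition: bool = False


@dataclass
class VelocitySeries:
    values: np.ndarray   # degrees/second
    fps: float


@dataclass
class StandardizedSeries:
    values: np.ndarray
    mu: float
    sigma: float
    constant: bool = False


def load_joints(path: str | Path | None = None) -> dict[str, JointDefinition]:
    """Load the joint triplet table (the shipped default or a user file)."""
    if path is None:
        path = Path(__file__).parent / "data" / "joints.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        name: JointDefinition(name=name, triplet=tuple(cfg["triplet"]),
                              plane=cfg.get("plane", "sagittal"))
        for name, cfg in raw.items()
    }


def joint_angle(p_proximal, p_vertex, p_distal, signed: bool = False) -> float:
    """Angle at the vertex of a landmark triplet, in degrees.

    Default mode returns the arccos of the normalized dot product,
    in [0, 180].  ``signed=True`` returns the counterclockwise angle from
    the proximal to the distal limb vector in [0, 360).
    """
    a = np.asarray(p_proximal, dtype=float) - np.asarray(p_vertex, dtype=float)
    b = np.asarray(p_distal, dtype=float) - np.asarray(p_vertex, dtype=float)
    na, nb = np.hypot(*a), np.hypot(*b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateGeometryError("zero-length limb vector")
    if signed:
        ang = np.degrees(np.arctan2(a[0] * b[1] - a[1] * b[0], a @ b))
        return float(ang % 360.0)
    cos = np.clip((a @ b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def angle_series(seq, joint: JointDefinition, signed: bool = False) -> JointAngleSeries:
    """Per-frame joint angle over a pixel or normalized sequence.

    Frames where any triplet landmark is invalid (masked out or
    non-finite) or geometrically degenerate are marked ``valid=False`` with
    angle NaN; neighbouring frames are unaffected.
    """
    coords = seq.coords
    mask = seq.valid_mask()
    p, v, d = joint.triplet
    n = len(coords)
    angles = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        if not (mask[i, p] and mask[i, v] and mask[i, d]):
            continue
        if not np.all(np.isfinite(coords[i, [p, v, d]])):
            continue
        try:
            angles[i] = joint_angle(coords[i, p], coords[i, v], coords[i, d],
                                    signed=signed)
        except DegenerateGeometryError:
            continue
        valid[i] = True
    return JointAngleSeries(joint=joint, angles=angles, valid=valid, fps=seq.fps)


def range_of_motion(series: JointAngleSeries) -> KinematicSummary:
    """ROM = theta_max - theta_min over the valid frames."""
    if not series.valid.any():
        raise ValueError("no valid frame in angle series")
    vals = series.angles[series.valid]
    theta_max = float(vals.max())
    theta_min = float(vals.min())
    return KinematicSummary(rom=theta_max - theta_min,
                            theta_max=theta_max, theta_min=theta_min)


def angular_velocity(series: JointAngleSeries) -> VelocitySeries:
    """Angular velocity by central differences, degrees/second.

    Interior frames use ``(theta(t+1) - theta(t-1)) / (2 dt)``; the first
    and last frames fall back to one-sided differences.  The central
    stencil halves high-frequency noise relative to forward differences
    and is second-order accurate on smooth trajectories.
    """
    theta = np.asarray(series.angles, dtype=float)
    if theta.size < 3:
        raise ValueError("need at least 3 frames for velocity estimation")
    dt = 1.0 / series.fps
    v = np.empty_like(theta)
    v[1:-1] = (theta[2:] - theta[:-2]) / (2 * dt)
    v[0] = (theta[1] - theta[0]) / dt
    v[-1] = (theta[-1] - theta[-2]) / dt
    return VelocitySeries(values=v, fps=series.fps)


def standardize(series) -> StandardizedSeries:
    """Center to zero mean and scale to unit variance (population sd).

    A constant series carries no shape information to correlate: it is
    returned as all zeros with ``constant=True`` rather than raising.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to standardize")
    mu = float(x.mean())
    sigma = float(x.std())  # population sd, ddof=0
    if sigma == 0.0:
        return StandardizedSeries(values=np.zeros_like(x), mu=mu, sigma=0.0,
                                  constant=True)
    return StandardizedSeries(values=(x - mu) / sigma, mu=mu, sigma=sigma)


def summarize_repetitions(series: JointAngleSeries, reps) -> KinematicSummary:
    """Across-repetition ROM and mean |velocity|, as mean +/- sample sd.

    Only repetitions flagged ``accepted`` contribute.  With a single
    accepted repetition the spread is reported as 0 with
    ``single_repetition=True`` (sample sd is undefined at n=1).
    """
    segments = [s for s in reps.segments if s.accepted]
    if not segments:
        raise ValueError("no accepted repetition to summarize")
    vel = angular_velocity(series).values
    roms, speeds, maxs, mins = [], [], [], []
    for seg in segments:
        sl = slice(seg.start_frame, seg.end_frame + 1)
        vals = series.angles[sl][series.valid[sl]]
        roms.append(float(vals.max() - vals.min()))
        maxs.append(float(vals.max()))
        mins.append(float(vals.min()))
        vseg = vel[sl][series.valid[sl]]
        speeds.append(float(np.abs(vseg).mean()))
    n = len(segments)
    ddof = 1 if n > 1 else 0
    return KinematicSummary(
        rom=float(np.mean(roms)),
        theta_max=float(np.mean(maxs)),
        theta_min=float(np.mean(mins)),
        mean_velocity=float(np.mean(speeds)),
        velocity_sd=float(np.std(speeds, ddof=ddof)) if n > 1 else 0.0,
        rom_sd=float(np.std(roms, ddof=ddof)) if n > 1 else 0.0,
        n_repetitions=n,
        single_repetition=(n == 1),
    )


def angle_table(series_list: list[JointAngleSeries]) -> "pd.DataFrame":
    """Long-format per-frame angle/velocity table for CSV export.

    Columns: frame, time_s, joint, angle_deg, velocity_deg_s, valid.
    """
    import pandas as pd

    rows = []
    for s in series_list:
        v = angular_velocity(s).values if s.angles.size >= 3 else np.full_like(s.angles, np.nan)
        for i in range(len(s.angles)):
            rows.append({
                "frame": i,
                "time_s": i / s.fps,
                "joint": s.joint.name,
                "angle_deg": s.angles[i],
                "velocity_deg_s": v[i],
                "valid": bool(s.valid[i]),
            })
    return pd.DataFrame(rows, columns=["frame", "time_s", "joint",
                                       "angle_deg", "velocity_deg_s", "valid"])
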