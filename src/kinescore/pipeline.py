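"""End-to-end scoring pipeline: pose JSON pair -> Action Score report.

Stage order mirrors the scoring flow: validate -> pixel conversion ->
visibility filling -> joint-angle extraction (on pixel coordinates; the
fixed bounding box is computed and echoed for auditability) -> smoothing ->
repetition segmentation and stability filtering -> ordinal pairing with
peak alignment -> DTW warping -> per-repetition NCC -> aggregate
similarity and composite score -> feedback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from . import feedback as fb
from .features import (JointAngleSeries, angle_series, load_joints,
                       range_of_motion, standardize)
from .keypoint_io import PoseSequence, validate_sequence
from .preprocessing import (fill_low_visibility, max_bounding_box, smooth,
                            to_pixel)
from .repetition import (align_repetitions, count_error, filter_stable,
                         segment_repetitions)
from .scoring import action_score, dtw, ncc, similarity_score, warp_to_reference

log = logging.getLogger("kinescore")


class PipelineError(RuntimeError):
    """The input pair cannot be scored (validation or segmentation failure)."""


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters, echoed into every report."""

    visibility_threshold: float = 0.5
    max_gap: int = 5                 # frames interpolated across dropout
    buffer_frac: float = 0.05        # bounding-box buffer, fraction of frame
    smoothing_window: int = 5        # frames; odd; 1 disables
    min_prominence: float | None = None   # degrees; None = 20% of range
    min_distance_s: float = 0.25     # s between peaks
    min_valid_fraction: float = 0.8
    max_jitter: float = 20.0         # degrees/frame
    max_lag_fraction: float = 0.25
    weight_similarity: float = 1.0
    weight_repetition: float = 1.0
    tolerance: float = 5.0           # degrees, feedback threshold
    rounding: str = "integer"
    joints_file: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _validated(seq: PoseSequence, label: str) -> None:
    report = validate_sequence(seq)
    if not report.ok:
        first = report.errors()[0]
        raise PipelineError(
            f"{label} sequence failed validation: {first.code} "
            f"(frame {first.frame}, landmark {first.landmark}): {first.message}")


def extract_angles(seq: PoseSequence, joint_name: str,
                   config: PipelineConfig,
                   joints: dict | None = None) -> JointAngleSeries:
    """Validate, preprocess and extract one smoothed joint-angle series."""
    if joints is None:
        joints = load_joints(config.joints_file)
    if joint_name not in joints:
        raise PipelineError(f"unknown joint {joint_name!r}; "
                            f"known: {sorted(joints)}")
    pixel = to_pixel(seq)
    filled = fill_low_visibility(pixel, threshold=config.visibility_threshold,
                                 max_gap=config.max_gap)
    series = angle_series(filled, joints[joint_name])
    return _smooth_series(series, config.smoothing_window)


def _smooth_series(series: JointAngleSeries, window: int) -> JointAngleSeries:
    """NaN-bridge invalid frames, then moving-average the angle signal.

    The original validity mask is preserved: interpolated frames remain
    flagged invalid for the stability filter.
    """
    theta = series.angles.copy()
    valid = series.valid
    if valid.any() and not valid.all():
        idx = np.arange(theta.size)
        theta = np.interp(idx, idx[valid], theta[valid])
    if window > 1 and valid.any():
        theta = smooth(theta, window)
    return replace(series, angles=theta)


def score_pair(user: PoseSequence, reference: PoseSequence,
               joint_names: list[str],
               config: PipelineConfig | None = None) -> dict:
    """Score a user recording against a reference demonstration.

    The first entry of ``joint_names`` is the driving joint: its angle
    trajectory segments the repetitions and yields the count accuracy.
    Every listed joint is scored for similarity; the overall similarity is
    the unweighted mean across joints.  Returns a JSON-serializable report.
    """
    if config is None:
        config = PipelineConfig()
    if not joint_names:
        raise PipelineError("at least one joint must be named")
    _validated(user, "user")
    _validated(reference, "reference")
    joints = load_joints(config.joints_file)

    user_px = to_pixel(user)
    ref_px = to_pixel(reference)
    user_box = max_bounding_box(user_px, buffer=config.buffer_frac * max(user.width, user.height),
                                visibility_threshold=config.visibility_threshold)
    ref_box = max_bounding_box(ref_px, buffer=config.buffer_frac * max(reference.width, reference.height),
                               visibility_threshold=config.visibility_threshold)
    log.info("fixed boxes: user %.0fx%.0f px, reference %.0fx%.0f px",
             user_box.width, user_box.height, ref_box.width, ref_box.height)

    min_distance = max(1, round(config.min_distance_s * user.fps))
    weights = (config.weight_similarity, config.weight_repetition)

    report: dict = {
        "config": asdict(config),
        "joints": {},
        "user_frames": user.total_frames,
        "reference_frames": reference.total_frames,
    }
    joint_similarities = []
    driving_error = None

    for k, name in enumerate(joint_names):
        u_series = extract_angles(user, name, config, joints)
        r_series = extract_angles(reference, name, config, joints)
        u_reps = filter_stable(
            segment_repetitions(u_series, config.min_prominence, min_distance),
            u_series, config.min_valid_fraction, config.max_jitter)
        r_reps = filter_stable(
            segment_repetitions(r_series, config.min_prominence, min_distance),
            r_series, config.min_valid_fraction, config.max_jitter)
        log.info("%s: user %d reps, reference %d reps", name,
                 u_reps.detected_count, r_reps.detected_count)

        if u_reps.detected_count == 0 or r_reps.detected_count == 0:
            raise PipelineError(
                f"{name}: no repetitions detected on "
                f"{'user' if u_reps.detected_count == 0 else 'reference'} side")

        err = count_error(u_reps.detected_count, r_reps.detected_count)
        alignment = align_repetitions(u_reps, u_series, r_reps, r_series)

        per_rep = []
        rmaxs, lags, dists = [], [], []
        for pair in alignment.pairs:
            su = standardize(pair.user_window)
            sr = standardize(pair.reference_window)
            if su.constant or sr.constant:
                rmaxs.append(0.0)
                lags.append(0)
                dists.append(float("nan"))
                per_rep.append({"r_max": 0.0, "lag": 0, "dtw_distance": None,
                                "constant_signal": True})
                continue
            warp = dtw(su.values, sr.values)
            warped = warp_to_reference(warp, su.values, sr.values.size)
            res = ncc(warped, sr.values,
                      max_lag=max(1, int(config.max_lag_fraction * sr.values.size)))
            rmaxs.append(res.r_max)
            lags.append(res.best_lag)
            dists.append(warp.distance)
            per_rep.append({"r_max": res.r_max, "lag": res.best_lag,
                            "dtw_distance": warp.distance})

        S = similarity_score(rmaxs)
        score = action_score(S, err, weights=weights, per_rep_rmax=rmaxs,
                             per_rep_lag=lags, per_rep_dtw=dists)
        u_rom = range_of_motion(u_series)
        r_rom = range_of_motion(r_series)
        comp = fb.compare_joint(u_rom, r_rom, name, tolerance=config.tolerance,
                                mode=config.rounding)
        joint_similarities.append(S)
        if k == 0:
            driving_error = err
        report["joints"][name] = {
            "similarity": S,
            "per_repetition": per_rep,
            "user_reps_detected": u_reps.detected_count,
            "user_reps_accepted": len(u_reps.accepted_segments()),
            "reference_reps_detected": r_reps.detected_count,
            "rep_error_percent": fb.round_for_report(err.error_percent, "one_decimal"),
            "combined_score": score.combined,
            "unmatched_user": alignment.unmatched_user,
            "unmatched_reference": alignment.unmatched_reference,
            "user_rom_deg": u_rom.rom,
            "reference_rom_deg": r_rom.rom,
            "range_diff_deg": comp.range_diff,
            "max_diff_deg": comp.max_diff,
            "min_diff_deg": comp.min_diff,
            "feedback": comp.feedback_text,
        }

    overall_S = float(np.mean(joint_similarities))
    overall = action_score(overall_S, driving_error, weights=weights)
    report["overall"] = {
        "similarity": overall_S,
        "rep_error_percent": fb.round_for_report(driving_error.error_percent,
                                                 "one_decimal"),
        "combined_score": overall.combined,
        "driving_joint": joint_names[0],
    }
    return report
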