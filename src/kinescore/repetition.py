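"""Repetition segmentation, counting and user/reference pairing.

One repetition is one full movement cycle of the exercised joint's angle
trajectory: trough -> peak -> trough.  Peaks mark the midpoint of each
repetition; troughs (found by inverting the signal and re-running peak
detection) mark the starts and ends.  The sequence boundaries act as
virtual troughs so the first and last cycles of a recording are not lost.

Counting accuracy is the percentage deviation

    error % = |detected - actual| / actual * 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .features import JointAngleSeries
from .preprocessing import smooth as _smooth


@dataclass
class RepetitionSegment:
    start_frame: int
    peak_frame: int
    end_frame: int
    accepted: bool = True

    def __post_init__(self):
        if not (self.start_frame <= self.peak_frame <= self.end_frame):
            raise ValueError("segment must satisfy start <= peak <= end")


@dataclass
class RepetitionSet:
    segments: list[RepetitionSegment]
    joint_name: str = ""

    @property
    def detected_count(self) -> int:
        return len(self.segments)

    def accepted_segments(self) -> list[RepetitionSegment]:
        return [s for s in self.segments if s.accepted]


@dataclass
class CountError:
    detected: int
    actual: int
    error_percent: float


@dataclass
class AlignedPair:
    """One user/reference repetition pair with peak-aligned, edge-padded
    angle windows of common length."""

    user: RepetitionSegment
    reference: RepetitionSegment
    user_window: np.ndarray
    reference_window: np.ndarray
    peak_index: int


@dataclass
class AlignmentResult:
    pairs: list[AlignedPair]
    unmatched_user: int = 0
    unmatched_reference: int = 0


def detect_peaks(series, min_prominence: float, min_distance: int = 1) -> np.ndarray:
    """Indices of local maxima with the required prominence and spacing.

    Plateau peaks resolve to the plateau midpoint.  Monotone series yield
    no peaks; an empty result is a valid outcome.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    idx, props = find_peaks(x, prominence=min_prominence,
                            distance=max(1, int(min_distance)),
                            plateau_size=(None, None))
    # find_peaks reports left_edges/right_edges for plateaus; midpoint them.
    if len(idx) and "left_edges" in props:
        idx = ((props["left_edges"] + props["right_edges"]) // 2).astype(int)
    return idx


def segment_repetitions(series: JointAngleSeries,
                        min_prominence: float | None = None,
                        min_distance: int | None = None,
                        smooth_window: int = 1) -> RepetitionSet:
    """Segment an angle trajectory into trough-peak-trough cycles.

    Peaks are detected on the (optionally smoothed) angle series; troughs
    by running the same detector on the negated series (signal inversion).
    Defaults: ``min_prominence`` = 20% of the observed valid range (making
    counting invariant to affine rescaling of the angle signal) and
    ``min_distance`` = 0.25 s worth of frames.
    """
    theta = np.asarray(series.angles, dtype=float)
    valid = series.valid
    if not valid.any():
        return RepetitionSet(segments=[], joint_name=series.joint.name)

    # Hold-last-value fill over invalid frames so the detector sees a
    # contiguous signal; segment bounds still come from the filled signal.
    filled = theta.copy()
    good = np.flatnonzero(valid)
    filled[: good[0]] = theta[good[0]]
    for i in np.flatnonzero(~valid):
        if i > good[0]:
            prev = good[good < i][-1]
            filled[i] = filled[prev]
    if smooth_window > 1:
        filled = _smooth(filled, smooth_window)

    rng = float(filled.max() - filled.min())
    if rng == 0.0:
        return RepetitionSet(segments=[], joint_name=series.joint.name)
    if min_prominence is None:
        min_prominence = 0.2 * rng
    if min_distance is None:
        min_distance = max(1, round(0.25 * series.fps))

    peaks = detect_peaks(filled, min_prominence, min_distance)
    troughs = detect_peaks(-filled, min_prominence, min_distance)

    n = len(filled)
    segments = []
    for pk in peaks:
        before = troughs[troughs < pk]
        after = troughs[troughs > pk]
        start = int(before[-1]) if before.size else 0
        end = int(after[0]) if after.size else n - 1
        segments.append(RepetitionSegment(start_frame=start, peak_frame=int(pk),
                                          end_frame=end))
    return RepetitionSet(segments=segments, joint_name=series.joint.name)


def count_error(detected: int, actual: int) -> CountError:
    """Percentage deviation of the detected count from the actual count."""
    if actual < 1:
        raise ValueError(f"actual repetitions must be >= 1, got {actual}")
    err = abs(detected - actual) / actual * 100.0
    return CountError(detected=detected, actual=actual, error_percent=err)


def align_repetitions(user: RepetitionSet, user_series: JointAngleSeries,
                      reference: RepetitionSet,
                      reference_series: JointAngleSeries) -> AlignmentResult:
    """Pair repetitions ordinally and peak-align their angle windows.

    The i-th user repetition is paired with the i-th reference repetition,
    up to the smaller count; surplus repetitions on either side are
    reported unmatched.  Within a pair, both windows are edge-padded so
    they share a common length with the peaks at the same index.
    """
    if not user.segments:
        raise ValueError("user repetition set is empty")
    if not reference.segments:
        raise ValueError("reference repetition set is empty")

    pairs = []
    k = min(user.detected_count, reference.detected_count)
    for i in range(k):
        su, sr = user.segments[i], reference.segments[i]
        wu = np.asarray(user_series.angles[su.start_frame: su.end_frame + 1], dtype=float)
        wr = np.asarray(reference_series.angles[sr.start_frame: sr.end_frame + 1], dtype=float)
        pu = su.peak_frame - su.start_frame
        pr = sr.peak_frame - sr.start_frame
        left = max(pu, pr)
        right = max(len(wu) - 1 - pu, len(wr) - 1 - pr)
        wu = np.pad(wu, (left - pu, right - (len(wu) - 1 - pu)), mode="edge")
        wr = np.pad(wr, (left - pr, right - (len(wr) - 1 - pr)), mode="edge")
        pairs.append(AlignedPair(user=su, reference=sr, user_window=wu,
                                 reference_window=wr, peak_index=left))
    return AlignmentResult(
        pairs=pairs,
        unmatched_user=user.detected_count - k,
        unmatched_reference=reference.detected_count - k,
    )


def filter_stable(reps: RepetitionSet, series: JointAngleSeries,
                  min_valid_fraction: float = 0.8,
                  max_jitter: float = 20.0) -> RepetitionSet:
    """Flag repetitions unsuitable for biomechanical summaries.

    A repetition is *accepted* only if (a) at least ``min_valid_fraction``
    of its frames have valid angles, (b) it spans a full trough-peak-trough
    cycle (its boundary angles return below the midpoint between the
    segment's trough and peak levels), and (c) no frame-to-frame angle jump
    between valid neighbours exceeds ``max_jitter`` degrees.  Rejected
    repetitions stay in the set (they still count) with ``accepted=False``.
    """
    out = []
    theta = series.angles
    for seg in reps.segments:
        sl = slice(seg.start_frame, seg.end_frame + 1)
        v = series.valid[sl]
        accepted = v.mean() >= min_valid_fraction if v.size else False
        vals = theta[sl][v]
        if accepted and vals.size >= 3:
            lo, hi = float(vals.min()), float(vals.max())
            mid = lo + 0.5 * (hi - lo)
            first = theta[sl][v][0]
            last = theta[sl][v][-1]
            if first > mid or last > mid:
                accepted = False  # truncated boundary cycle
            dif = np.abs(np.diff(theta[sl][v]))
            if dif.size and float(dif.max()) > max_jitter:
                accepted = False
        elif accepted:
            accepted = False
        out.append(RepetitionSegment(start_frame=seg.start_frame,
                                     peak_frame=seg.peak_frame,
                                     end_frame=seg.end_frame,
                                     accepted=accepted))
    return RepetitionSet(segments=out, joint_name=reps.joint_name)


def segments_table(reps: RepetitionSet) -> "pd.DataFrame":
    """Segment table for CSV export: rep_index, start/peak/end, accepted."""
    import pandas as pd

    return pd.DataFrame(
        [{"rep_index": i, "start_frame": s.start_frame, "peak_frame": s.peak_frame,
          "end_frame": s.end_frame, "accepted": s.accepted}
         for i, s in enumerate(reps.segments)],
        columns=["rep_index", "start_frame", "peak_frame", "end_frame", "accepted"],
    )
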