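"""Keypoint preprocessing: pixel conversion, bounding boxes, normalization.

The stabilisation strategy is a *fixed maximum bounding box*: per-frame
boxes jitter with every small landmark-detection error, so a single box —
the union of all per-frame boxes — serves as a constant spatial reference
for the whole recording.  Coordinates are then re-normalized relative to
that box, removing camera framing and subject placement effects.

Joint angles downstream are computed on pixel (isotropic) coordinates, not
on the box-normalized ones: dividing x and y by different box extents is an
anisotropic scaling and distorts angles.  Box-normalized coordinates are
for trajectory-level comparison and visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .keypoint_io import N_LANDMARKS, PoseSequence


class DegenerateFrameError(ValueError):
    """No landmark in a frame passes the visibility threshold."""


class ParameterError(ValueError):
    """A preprocessing parameter is outside its documented range."""


@dataclass
class BoundingBox:
    """Axis-aligned pixel box with the safety ``buffer`` already applied."""

    min_x: float
    min_y: float
    max_x: float
    max_y: float
    buffer: float = 0.0

    @property
    def width(self) -> float:
        return self.max_x - self.min_x

    @property
    def height(self) -> float:
        return self.max_y - self.min_y

    def contains(self, other: "BoundingBox", tol: float = 1e-9) -> bool:
        return (self.min_x <= other.min_x + tol and self.min_y <= other.min_y + tol
                and self.max_x >= other.max_x - tol and self.max_y >= other.max_y - tol)


@dataclass
class PixelSequence:
    """Landmark positions in absolute pixels: X = x*width, Y = y*height."""

    coords: np.ndarray       # (n_frames, 33, 2) pixels
    visibility: np.ndarray   # (n_frames, 33)
    width: int
    height: int
    fps: float
    valid: np.ndarray | None = None  # (n_frames, 33) bool; None = all valid

    def valid_mask(self) -> np.ndarray:
        if self.valid is not None:
            return self.valid
        return np.ones(self.coords.shape[:2], dtype=bool)


@dataclass
class NormalizedSequence:
    """Landmarks re-normalized to a fixed bounding box (unit square)."""

    coords: np.ndarray
    visibility: np.ndarray
    box: BoundingBox
    fps: float
    valid: np.ndarray | None = None

    def valid_mask(self) -> np.ndarray:
        if self.valid is not None:
            return self.valid
        return np.ones(self.coords.shape[:2], dtype=bool)


def to_pixel(seq: PoseSequence) -> PixelSequence:
    """Map normalized coordinates to absolute pixel values."""
    if seq.width <= 0 or seq.height <= 0:
        raise ParameterError(f"frame size must be positive, got {seq.width}x{seq.height}")
    coords = seq.coords()
    pix = np.empty_like(coords)
    pix[..., 0] = coords[..., 0] * seq.width
    pix[..., 1] = coords[..., 1] * seq.height
    return PixelSequence(coords=pix, visibility=seq.visibility(),
                         width=seq.width, height=seq.height, fps=seq.fps)


def frame_bounding_box(frame_coords: np.ndarray, frame_visibility: np.ndarray,
                       buffer: float = 0.0, visibility_threshold: float = 0.5,
                       width: float | None = None,
                       height: float | None = None) -> BoundingBox:
    """Bounding box of one frame's landmarks passing the visibility threshold.

    The box spans the extreme horizontal and vertical landmark positions
    plus ``buffer`` on every side, clamped to the frame when its size is
    known.
    """
    if buffer < 0:
        raise ParameterError(f"buffer must be >= 0, got {buffer}")
    mask = frame_visibility >= visibility_threshold
    if not mask.any():
        raise DegenerateFrameError(
            f"no landmark passes visibility threshold {visibility_threshold}")
    pts = frame_coords[mask]
    min_x, min_y = pts.min(axis=0) - buffer
    max_x, max_y = pts.max(axis=0) + buffer
    if width is not None:
        min_x, max_x = max(min_x, 0.0), min(max_x, width)
    if height is not None:
        min_y, max_y = max(min_y, 0.0), min(max_y, height)
    return BoundingBox(min_x=float(min_x), min_y=float(min_y),
                       max_x=float(max_x), max_y=float(max_y), buffer=buffer)


def max_bounding_box(seq: PixelSequence, buffer: float | None = None,
                     visibility_threshold: float = 0.5) -> BoundingBox:
    """Fixed maximum bounding box: union of all per-frame boxes.

    ``buffer`` defaults to 5% of the larger frame dimension.  Frames with
    no passing landmark are skipped; if every frame is degenerate an error
    is raised.
    """
    if len(seq.coords) == 0:
        raise ParameterError("sequence is empty")
    if buffer is None:
        buffer = 0.05 * max(seq.width, seq.height)
    boxes = []
    for i in range(len(seq.coords)):
        try:
            boxes.append(frame_bounding_box(
                seq.coords[i], seq.visibility[i], buffer=buffer,
                visibility_threshold=visibility_threshold,
                width=seq.width, height=seq.height))
        except DegenerateFrameError:
            continue
    if not boxes:
        raise DegenerateFrameError("every frame is degenerate at this threshold")
    return BoundingBox(
        min_x=min(b.min_x for b in boxes),
        min_y=min(b.min_y for b in boxes),
        max_x=max(b.max_x for b in boxes),
        max_y=max(b.max_y for b in boxes),
        buffer=float(buffer),
    )


def normalize_to_box(seq: PixelSequence, box: BoundingBox) -> NormalizedSequence:
    """Re-normalize pixel coordinates relative to a fixed box.

    ``X_final = (X - box.min_x) / box.width`` and analogously for Y, so the
    box maps onto the unit square.
    """
    if box.width <= 0 or box.height <= 0:
        raise ParameterError(f"degenerate box: {box.width} x {box.height}")
    out = np.empty_like(seq.coords)
    out[..., 0] = (seq.coords[..., 0] - box.min_x) / box.width
    out[..., 1] = (seq.coords[..., 1] - box.min_y) / box.height
    return NormalizedSequence(coords=out, visibility=seq.visibility.copy(),
                              box=box, fps=seq.fps,
                              valid=None if seq.valid is None else seq.valid.copy())


def fill_low_visibility(seq, threshold: float = 0.5, max_gap: int = 5):
    """Interpolate landmarks whose visibility falls below ``threshold``.

    Gaps of at most ``max_gap`` consecutive low-visibility frames are
    filled per-landmark by linear interpolation between the nearest passing
    frames; longer gaps (and gaps touching a sequence boundary) leave the
    landmark marked invalid in the returned sequence's ``valid`` mask, for
    downstream exclusion.  Works on :class:`PixelSequence` and
    :class:`NormalizedSequence` alike; the input is not mutated.
    """
    coords = seq.coords.copy()
    n = len(coords)
    valid = seq.visibility >= threshold
    out_valid = valid.copy()
    for j in range(coords.shape[1]):
        good = np.flatnonzero(valid[:, j])
        if good.size == 0 or good.size == n:
            continue
        bad = np.flatnonzero(~valid[:, j])
        for i in bad:
            prev = good[good < i]
            nxt = good[good > i]
            if prev.size and nxt.size:
                lo, hi = prev[-1], nxt[0]
                if hi - lo - 1 <= max_gap:
                    w = (i - lo) / (hi - lo)
                    coords[i, j] = (1 - w) * coords[lo, j] + w * coords[hi, j]
                    out_valid[i, j] = True
    return replace(seq, coords=coords, valid=out_valid)


def smooth(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with a shrinking window at the edges.

    ``window`` must be odd and >= 1; ``window=1`` is the identity.  Works on
    1-D series or on the leading axis of an N-D array.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    series = np.asarray(series, dtype=float)
    if window == 1:
        return series.copy()
    h = window // 2
    n = series.shape[0]
    out = np.empty_like(series)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        out[i] = series[lo:hi].mean(axis=0)
    return out
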