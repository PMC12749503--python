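"""Movement similarity scoring: DTW, lagged NCC and the composite score.

Dynamic time warping absorbs differences in execution speed by allowing
the time axis to stretch or compress: the classic dynamic program with
squared pointwise cost and the symmetric step set {(1,0), (0,1), (1,1)}.
On the purely diagonal path the distance reduces to the plain Euclidean
distance between the two series.

Normalized cross-correlation measures shape similarity between two
standardized signals across time lags; its maximum over lags, R_max, lies
in [-1, 1].  The aggregate similarity S is the mean of R_max over the
analysed repetitions, and the composite Action Score blends S with the
repetition-count accuracy on a 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .repetition import CountError


@dataclass
class DTWResult:
    distance: float
    path: list[tuple[int, int]]


@dataclass
class NCCResult:
    r_max: float
    best_lag: int
    lags: np.ndarray
    curve: np.ndarray
    constant_signal: bool = False


@dataclass
class ActionScore:
    per_rep_rmax: list[float]
    similarity: float
    rep_error_percent: float
    combined: float
    weights: tuple[float, float]
    per_rep_lag: list[int] = field(default_factory=list)
    per_rep_dtw: list[float] = field(default_factory=list)


def dtw(p, d) -> DTWResult:
    """Dynamic-time-warping distance and optimal path.

    Accumulated cost uses squared pointwise differences; the returned
    distance is the square root of the cost along the optimal path, so
    ``dtw(x, x).distance == 0`` and for equal-length series the distance is
    bounded above by the Euclidean distance (the diagonal is admissible).
    Backtracking tie-break is deterministic: diagonal first, then the step
    consuming the first series.
    """
    x = np.asarray(p, dtype=float)
    y = np.asarray(d, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    n, m = x.size, y.size
    cost = (x[:, None] - y[None, :]) ** 2
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(acc[i - 1, j - 1],
                                                 acc[i - 1, j], acc[i, j - 1])
    # Backtrack from (n-1, m-1) to (0, 0).
    path = [(n - 1, m - 1)]
    i, j = n, m
    while (i, j) != (1, 1):
        choices = ((acc[i - 1, j - 1], (i - 1, j - 1)),
                   (acc[i - 1, j], (i - 1, j)),
                   (acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(choices, key=lambda c: c[0])
        path.append((i - 1, j - 1))
    path.reverse()
    return DTWResult(distance=float(np.sqrt(acc[n, m])), path=path)


def warp_to_reference(result: DTWResult, x, m: int) -> np.ndarray:
    """Project series ``x`` onto the reference timeline along a DTW path.

    Every reference index j receives the mean of the x-samples matched to
    it, yielding a length-``m`` series comparable point-by-point with the
    reference.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros(m)
    counts = np.zeros(m)
    for i, j in result.path:
        out[j] += x[i]
        counts[j] += 1
    return out / np.maximum(counts, 1)


def resample_to_common_length(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate both series onto max(len(x), len(y)) samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cannot resample an empty series")
    n = max(x.size, y.size)

    def _up(s):
        if s.size == n:
            return s.copy()
        if s.size == 1:
            return np.full(n, s[0])
        return np.interp(np.linspace(0, s.size - 1, n), np.arange(s.size), s)

    return _up(x), _up(y)


def ncc(x, y, max_lag: int | None = None) -> NCCResult:
    """Normalized cross-correlation over lags in [-max_lag, max_lag].

    Both signals are first resampled to a common length.  The correlation
    at each lag tau is the Pearson correlation of the two overlapping
    segments (means and population standard deviations taken over the
    overlap), so |R(tau)| <= 1 by Cauchy-Schwarz, ``ncc(x, x)`` peaks at
    exactly 1 at lag 0, and the result is invariant to positive affine
    transforms of either signal.  A constant signal has no shape to
    correlate: R_max is defined as 0 with ``constant_signal=True``.
    ``max_lag`` defaults to 25% of the common length.
    """
    x, y = resample_to_common_length(x, y)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples for correlation")
    if max_lag is None:
        max_lag = max(1, n // 4)
    max_lag = min(max_lag, n - 2)
    lags = np.arange(-max_lag, max_lag + 1)
    if x.std() == 0.0 or y.std() == 0.0:
        return NCCResult(r_max=0.0, best_lag=0, lags=lags,
                         curve=np.zeros_like(lags, dtype=float),
                         constant_signal=True)
    curve = np.empty(lags.size)
    for k, tau in enumerate(lags):
        if tau >= 0:
            a, b = x[: n - tau], y[tau:]
        else:
            a, b = x[-tau:], y[: n + tau]
        sa, sb = a.std(), b.std()
        if sa == 0.0 or sb == 0.0:
            curve[k] = 0.0
            continue
        curve[k] = ((a - a.mean()) * (b - b.mean())).mean() / (sa * sb)
    best = int(np.argmax(curve))
    return NCCResult(r_max=float(curve[best]), best_lag=int(lags[best]),
                     lags=lags, curve=curve)


def similarity_score(per_rep_rmax) -> float:
    """Aggregate similarity S: the mean of per-repetition R_max values."""
    vals = list(per_rep_rmax)
    if not vals:
        raise ValueError("need at least one repetition R_max")
    return float(np.mean(vals))


def action_score(similarity: float, rep_error: CountError,
                 weights: tuple[float, float] = (1.0, 1.0),
                 per_rep_rmax=None, per_rep_lag=None,
                 per_rep_dtw=None) -> ActionScore:
    """Composite Action Score on a 0-100 scale.

    ``combined = 100 * (w_sim * max(S, 0) + w_rep * max(1 - err/100, 0))
    / (w_sim + w_rep)``.  Anti-correlated similarity and over-100% count
    errors clamp to zero contribution; every component is reported
    separately so the composite stays auditable.
    """
    w_sim, w_rep = weights
    if w_sim < 0 or w_rep < 0 or (w_sim + w_rep) <= 0:
        raise ValueError(f"weights must be nonnegative with positive sum, got {weights}")
    sim_term = max(similarity, 0.0)
    rep_term = max(1.0 - rep_error.error_percent / 100.0, 0.0)
    combined = 100.0 * (w_sim * sim_term + w_rep * rep_term) / (w_sim + w_rep)
    return ActionScore(
        per_rep_rmax=list(per_rep_rmax or []),
        similarity=float(similarity),
        rep_error_percent=rep_error.error_percent,
        combined=float(combined),
        weights=(w_sim, w_rep),
        per_rep_lag=list(per_rep_lag or []),
        per_rep_dtw=list(per_rep_dtw or []),
    )
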