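"""Cross-device comparison utilities: resampling and dynamic time warping.

Independent reference devices (e.g. an electromagnetic tracker at 60 Hz
or a laser displacement sensor) sample on their own clocks; their series
are interpolated onto the camera timestamps before comparison. For fast
movements, small clock offsets produce large pointwise differences, so
matched per-point errors are computed along an optimal dynamic-time-
warping path instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["AlignedPair", "resample_to_timestamps", "dtw_match"]


@dataclass
class AlignedPair:
    """An optimal warping alignment between a reference and a test series.

    ``pairs`` is the (L, 2) monotone index path from (0, 0) to
    (n-1, m-1); ``errors`` the absolute reference-test difference at each
    matched pair.
    """

    pairs: np.ndarray
    errors: np.ndarray
    mean_error: float
    median_error: float
    total_cost: float


def resample_to_timestamps(values, source_t, target_t, *, boolean: bool = False):
    """Interpolate a channel onto new timestamps.

    Numeric channels are linearly interpolated; boolean channels take the
    nearest source sample. Targets outside the source span hold the edge
    value and emit a warning.
    """
    source_t = np.asarray(source_t, dtype=float)
    target_t = np.asarray(target_t, dtype=float)
    values = np.asarray(values)
    if np.any(np.diff(source_t) <= 0):
        raise ValueError("source timestamps must be strictly increasing")
    if target_t.size and (
        target_t.min() < source_t[0] or target_t.max() > source_t[-1]
    ):
        warnings.warn(
            "target timestamps outside source range; edge values held",
            RuntimeWarning,
            stacklevel=2,
        )
    if boolean:
        idx = np.searchsorted(source_t, target_t)
        idx = np.clip(idx, 1, len(source_t) - 1)
        left = target_t - source_t[idx - 1]
        right = source_t[idx] - target_t
        nearest = np.where(left <= right, idx - 1, idx)
        return values[nearest]
    return np.interp(target_t, source_t, values.astype(float))


def dtw_match(reference, test) -> AlignedPair:
    """Classic unconstrained dynamic time warping with |a - b| local cost.

    Symmetric unit steps (match / insert / delete), no warping window.
    Returns the optimal path, per-pair absolute errors, and their mean
    and median.
    """
    r = np.asarray(reference, dtype=float)
    s = np.asarray(test, dtype=float)
    n, m = len(r), len(s)
    if n < 2 or m < 2:
        raise ValueError("dtw requires both series to have length >= 2")
    cost = np.abs(r[:, None] - s[None, :])
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = cost[i, j] + best
    # backtrack the optimal monotone path
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            candidates.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            candidates.append((acc[i, j - 1], (i, j - 1)))
        i, j = min(candidates)[1]
        path.append((i, j))
    pairs = np.array(path[::-1], dtype=int)
    errors = np.abs(r[pairs[:, 0]] - s[pairs[:, 1]])
    return AlignedPair(
        pairs=pairs,
        errors=errors,
        mean_error=float(errors.mean()),
        median_error=float(np.median(errors)),
        total_cost=float(acc[n - 1, m - 1]),
    )
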