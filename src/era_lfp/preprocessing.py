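"""Denoising and change-point downsampling of long multi-channel signals.

Long raw recordings (hundreds of thousands of samples per phase) are reduced
to a small set of change points — knots of a continuous piecewise-linear
approximation — and then re-interpolated onto one coarse uniform grid shared
across channels. The segmenter is a deterministic penalized top-down
splitter: starting from the segment spanned by the endpoints, it repeatedly
splits the segment offering the largest reduction in residual sum of squares
at its point of maximum absolute deviation from the chord, and stops when no
split reduces the penalized cost (RSS + penalty x number of interior knots).
This plays the role that a Bayesian trend change-point decomposition plays
for real LFP data, with trend-only knots and fully reproducible output.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChangePointSet",
    "UniformSeries",
    "moving_average_smooth",
    "detect_change_points",
    "interpolate_to_uniform",
]


@dataclass
class ChangePointSet:
    """Knots of a piecewise-linear approximation of one channel.

    ``times`` (seconds) are strictly increasing and always include the first
    and last sample times of the source signal; ``values`` are the signal
    values at the knots. ``source_length`` records how many raw samples the
    knots summarize.
    """

    channel_id: str
    times: np.ndarray
    values: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size < 2 or self.times.size != self.values.size:
            raise ValueError("a ChangePointSet needs >= 2 (time, value) knots")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("knot times must be strictly increasing")

    @property
    def n_interior(self) -> int:
        return self.times.size - 2

    def interpolate(self, at_times: np.ndarray) -> np.ndarray:
        return np.interp(at_times, self.times, self.values)


@dataclass
class UniformSeries:
    """All channels re-sampled on one shared uniform grid."""

    samples: np.ndarray        # q x m'
    rate: float                # coarse rate in Hz
    t0: float                  # time of the first grid point, seconds
    cp_counts: list[int]       # per-channel interior change-point counts

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[1] < 2:
            raise ValueError("uniform series needs >= 2 grid points")
        if self.rate <= 0:
            raise ValueError("coarse rate must be positive")

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.shape[1]) / self.rate


def moving_average_smooth(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving-average filter, length preserving.

    ``window`` must be odd and positive. Interior points are the mean of the
    full window centered on them; near each boundary the window shrinks
    symmetrically to the largest centered odd window that fits, so the first
    and last samples pass through unchanged.
    """
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    y = np.atleast_2d(y)
    n = y.shape[1]
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if window == 1:
        out = y.copy()
    else:
        half = window // 2
        idx = np.arange(n)
        h = np.minimum(half, np.minimum(idx, n - 1 - idx))  # per-point half width
        csum = np.cumsum(np.pad(y, ((0, 0), (1, 0))), axis=1)
        lo, hi = idx - h, idx + h
        out = (csum[:, hi + 1] - csum[:, lo]) / (2 * h + 1)
    return out[0] if squeeze else out


def _chord_rss_fn(y: np.ndarray):
    """O(1) residual sum of squares of y[a..b] against its endpoint chord.

    Built on prefix sums of y, y^2 and i*y so that scanning every candidate
    split point of a segment costs O(segment length) in total. Accepts array
    arguments for ``a``/``b``. Tiny negative values from cancellation are
    clamped to zero.
    """
    idx = np.arange(y.size, dtype=float)
    Z1 = np.concatenate(([0.0], np.cumsum(y)))
    Z2 = np.concatenate(([0.0], np.cumsum(y * y)))
    Zi = np.concatenate(([0.0], np.cumsum(idx * y)))

    def rss(a, b):
        a = np.asarray(a, dtype=int)
        b = np.asarray(b, dtype=int)
        n = (b - a + 1).astype(float)
        span = (b - a).astype(float)
        s1 = Z1[b + 1] - Z1[a]
        s2 = Z2[b + 1] - Z2[a]
        sty = (Zi[b + 1] - Zi[a]) - a * s1  # sum of (i - a) * y_i
        alpha = y[a]
        beta = np.where(span > 0, (y[b] - alpha) / np.where(span > 0, span, 1), 0.0)
        st = span * (span + 1) / 2.0
        st2 = span * (span + 1) * (2 * span + 1) / 6.0
        out = (s2 - 2 * alpha * s1 - 2 * beta * sty + alpha * alpha * n
               + 2 * alpha * beta * st + beta * beta * st2)
        return np.maximum(out, 0.0)

    return rss


def _split_candidate(rss, a: int, b: int):
    """Best split of segment [a, b]: (gain, split_index), or None if too short.

    The split point is the interior sample whose through-the-point split
    maximizes the RSS reduction (earliest index on ties).
    """
    if b - a < 2:
        return None
    cs = np.arange(a + 1, b)
    gains = float(rss(a, b)) - rss(np.full(cs.size, a), cs) - rss(cs, np.full(cs.size, b))
    j = int(np.argmax(gains))
    return float(gains[j]), int(cs[j])


def _prune_knots(y: np.ndarray, idx: list[int], rss, penalty: float) -> np.ndarray:
    """Greedy backward elimination of interior knots.

    Repeatedly removes the interior knot whose removal increases the RSS the
    least (earliest index on ties) while that increase is at most the
    penalty. The removal order does not depend on the penalty, so results
    for different penalties are nested. Lazy-heap implementation: entries
    invalidated by a neighbor's removal are refreshed on pop.
    """
    if len(idx) <= 2:
        return np.asarray(idx)
    prev = {c: a for a, c in zip(idx[:-1], idx[1:])}
    nxt = {a: c for a, c in zip(idx[:-1], idx[1:])}
    first, last = idx[0], idx[-1]
    alive = set(idx[1:-1])

    def increase(c: int) -> float:
        a, b = prev[c], nxt[c]
        return float(rss(a, b) - rss(a, c) - rss(c, b))

    heap = [(increase(c), c) for c in alive]
    heapq.heapify(heap)
    while heap and alive:
        inc, c = heapq.heappop(heap)
        if c not in alive:
            continue
        cur = increase(c)
        if cur != inc:
            heapq.heappush(heap, (cur, c))
            continue
        if cur > penalty:
            break
        alive.discard(c)
        a, b = prev[c], nxt[c]
        nxt[a], prev[b] = b, a
        if a != first and a in alive:
            heapq.heappush(heap, (increase(a), a))
        if b != last and b in alive:
            heapq.heappush(heap, (increase(b), b))
    return np.array(sorted(alive | {first, last}))


def detect_change_points(
    series: np.ndarray,
    rate: float = 1.0,
    *,
    penalty: float,
    max_cps: int | None = None,
    t0: float = 0.0,
    channel_id: str = "ch0",
) -> ChangePointSet:
    """Penalized piecewise-linear segmentation of one channel.

    Minimizes ``RSS + penalty * n_interior_knots`` in two passes. Grow:
    segments are split greedily in order of decreasing RSS gain, each split
    placed at the interior sample whose through-the-point split reduces the
    segment RSS the most, until no split gains more than a small numerical
    floor or ``max_cps`` interior knots exist; this pass does not depend on
    the penalty. Prune: interior knots are then removed greedily, cheapest
    RSS increase first, while the cheapest removal costs at most the
    penalty. Because the grow pass and the prune order are both
    penalty-independent, a larger penalty always yields a subset of the
    knots of a smaller one (monotone compression). Knot values are the
    observed sample values, so a noise-free piecewise-linear signal whose
    knots lie on the sampling grid is recovered exactly — with exactly its
    own knots.
    """
    y = np.asarray(series, dtype=float).ravel()
    n = y.size
    if n < 2:
        raise ValueError(f"series must contain >= 2 samples, got {n}")
    if penalty <= 0:
        raise ValueError(f"penalty must be positive, got {penalty}")

    knots = [0, n - 1]
    rss = _chord_rss_fn(y)
    # floor absorbs cancellation noise in the O(1) RSS formula on exact fits
    gain_floor = 1e-10 * float(rss(0, n - 1))
    heap: list[tuple[float, int, int, int]] = []

    def push(a: int, b: int) -> None:
        cand = _split_candidate(rss, a, b)
        if cand is not None:
            gain, c = cand
            heapq.heappush(heap, (-gain, a, b, c))

    push(0, n - 1)
    n_interior = 0
    cap = n - 2 if max_cps is None else min(max_cps, n - 2)
    while heap and n_interior < cap:
        neg_gain, a, b, c = heapq.heappop(heap)
        if -neg_gain <= gain_floor:
            break
        knots.append(c)
        n_interior += 1
        push(a, c)
        push(c, b)

    idx = sorted(knots)
    idx = _prune_knots(y, idx, rss, penalty)

    return ChangePointSet(
        channel_id=channel_id,
        times=t0 + idx / rate,
        values=y[idx],
        source_length=n,
    )


def interpolate_to_uniform(
    cp_sets: list[ChangePointSet],
    target_points: int,
    rtol: float = 1e-9,
) -> UniformSeries:
    """Sample every channel's piecewise-linear fit on one shared uniform grid.

    All channels must span the same time interval (to relative tolerance
    ``rtol``); the grid has ``target_points`` points from the common start to
    the common end time inclusive.
    """
    if not cp_sets:
        raise ValueError("need at least one channel")
    if target_points < 2:
        raise ValueError("target_points must be >= 2")
    t_start = cp_sets[0].times[0]
    t_end = cp_sets[0].times[-1]
    span = t_end - t_start
    for cp in cp_sets[1:]:
        if (abs(cp.times[0] - t_start) > rtol * max(1.0, abs(span))
                or abs(cp.times[-1] - t_end) > rtol * max(1.0, abs(span))):
            raise ValueError(
                f"channel {cp.channel_id!r} spans [{cp.times[0]}, {cp.times[-1]}] "
                f"but channel {cp_sets[0].channel_id!r} spans [{t_start}, {t_end}]"
            )
    grid = np.linspace(t_start, t_end, target_points)
    samples = np.vstack([cp.interpolate(grid) for cp in cp_sets])
    rate = (target_points - 1) / span if span > 0 else 1.0
    return UniformSeries(
        samples=samples,
        rate=rate,
        t0=t_start,
        cp_counts=[cp.n_interior for cp in cp_sets],
    )
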