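"""Kinetic change-point segmentation of single-molecule time series.

Segments a noisy trace into piecewise-linear regimes (replication
kinetics) or piecewise-constant levels (photobleaching steps) by
recursive binary segmentation.  At each region the candidate breakpoint
that minimises the combined residual sum of squares (RSS) of the
two-piece fit is accepted if an F-type likelihood-ratio statistic
exceeds the critical value at the requested confidence level; the
recursion then continues on both halves.

An exhaustive single-breakpoint search (:func:`oracle_best_split`) is
provided as an independent test oracle; it scans every admissible
breakpoint with plain per-side least squares.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Segment",
    "SegmentedFit",
    "fit_piecewise_linear",
    "fit_steps",
    "first_split",
    "oracle_best_split",
]

# Minimum points per segment: 3 for lines (2 parameters), 2 for levels.
DEFAULT_MIN_SEGMENT_POINTS = 3
DEFAULT_MIN_DWELL_POINTS = 2
DEFAULT_CONFIDENCE = 0.95


@dataclass(frozen=True)
class Segment:
    """One fitted regime of a trace.

    ``i_start``/``i_end`` index the samples of the analysed trace
    (half-open interval); ``t_start``/``t_end`` are the times of the
    first and last sample in the segment.  ``klass`` is filled in by
    downstream classification ('burst' / 'pause' / 'terminal').
    """

    i_start: int
    i_end: int
    t_start: float
    t_end: float
    slope: float
    intercept: float
    n_points: int
    slope_se: float
    rss: float
    klass: str = ""

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def predict(self, t):
        return self.slope * np.asarray(t, dtype=float) + self.intercept

    def with_class(self, klass: str) -> "Segment":
        return dataclasses.replace(self, klass=klass)


@dataclass
class SegmentedFit:
    """Ordered, contiguous piecewise fit of a single trace."""

    segments: list[Segment]
    confidence: float = DEFAULT_CONFIDENCE
    model: str = "linear"  # 'linear' or 'constant'
    flags: tuple[str, ...] = ()
    t: np.ndarray | None = None
    x: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def breakpoints(self) -> list[float]:
        """Times at which a new regime starts (start of each segment but the first)."""
        return [s.t_start for s in self.segments[1:]]

    @property
    def total_rss(self) -> float:
        return float(sum(s.rss for s in self.segments))

    @property
    def levels(self) -> np.ndarray:
        """Plateau levels (meaningful for the constant/step model)."""
        return np.array([s.intercept for s in self.segments])

    @property
    def step_amplitudes(self) -> np.ndarray:
        """Level changes between consecutive plateaus (constant model)."""
        lv = self.levels
        return np.diff(lv)

    @property
    def step_times(self) -> np.ndarray:
        """Time of each level change (start of the new plateau)."""
        return np.array([s.t_start for s in self.segments[1:]])

    def predict(self, t=None) -> np.ndarray:
        """Piecewise reconstruction evaluated at the fitted sample times."""
        if t is None:
            t = self.t
        t = np.asarray(t, dtype=float)
        out = np.empty_like(t)
        for seg in self.segments:
            m = (t >= seg.t_start) & (t <= seg.t_end)
            out[m] = seg.predict(t[m])
        # anything outside the analysed span: nearest segment
        out[t < self.segments[0].t_start] = self.segments[0].predict(
            t[t < self.segments[0].t_start]
        )
        out[t > self.segments[-1].t_end] = self.segments[-1].predict(
            t[t > self.segments[-1].t_end]
        )
        return out


class _PrefixSums:
    """O(1) windowed first/second moments via prefix sums."""

    def __init__(self, t: np.ndarray, x: np.ndarray):
        z = np.zeros(1)
        self.t1 = np.concatenate([z, np.cumsum(t)])
        self.x1 = np.concatenate([z, np.cumsum(x)])
        self.tt = np.concatenate([z, np.cumsum(t * t)])
        self.xx = np.concatenate([z, np.cumsum(x * x)])
        self.tx = np.concatenate([z, np.cumsum(t * x)])
        # scale for numeric tolerance on RSS comparisons
        self.scale = float(self.xx[-1]) + 1.0

    def moments(self, i, j):
        n = j - i
        return (
            n,
            self.t1[j] - self.t1[i],
            self.x1[j] - self.x1[i],
            self.tt[j] - self.tt[i],
            self.xx[j] - self.xx[i],
            self.tx[j] - self.tx[i],
        )

    def rss(self, i, j, model: str):
        """RSS of the OLS fit (line or constant) on samples [i, j)."""
        n, st, sx, stt, sxx, stx = self.moments(i, j)
        xc = sxx - sx * sx / n
        if model == "constant":
            return np.maximum(xc, 0.0)
        tc = stt - st * st / n
        txc = stx - st * sx / n
        with np.errstate(divide="ignore", invalid="ignore"):
            expl = np.where(tc > 0, txc * txc / np.where(tc > 0, tc, 1.0), 0.0)
        return np.maximum(xc - expl, 0.0)


def _ols_segment(t, x, i, j, model: str) -> Segment:
    ts = t[i:j]
    xs = x[i:j]
    n = j - i
    if model == "constant":
        level = float(np.mean(xs))
        rss = float(np.sum((xs - level) ** 2))
        return Segment(i, j, float(ts[0]), float(ts[-1]), 0.0, level, n, 0.0, rss)
    tc = ts - ts.mean()
    stt = float(np.sum(tc * tc))
    if stt == 0.0:
        slope = 0.0
        intercept = float(xs.mean())
    else:
        slope = float(np.sum(tc * (xs - xs.mean())) / stt)
        intercept = float(xs.mean() - slope * ts.mean())
    resid = xs - (slope * ts + intercept)
    rss = float(np.sum(resid**2))
    dof = n - 2
    se = float(np.sqrt(rss / dof / stt)) if (dof > 0 and stt > 0) else np.nan
    return Segment(i, j, float(ts[0]), float(ts[-1]), slope, intercept, n, se, rss)


def _best_split(S: _PrefixSums, i: int, j: int, min_pts: int, model: str):
    """Earliest global RSS-minimising split of [i, j); None if no admissible split."""
    ks = np.arange(i + min_pts, j - min_pts + 1)
    if ks.size == 0:
        return None
    total = S.rss(i, ks, model) + S.rss(ks, j, model)
    b = int(np.argmin(total))  # argmin returns the first minimiser -> earliest tie
    return int(ks[b]), float(total[b])


def _split_accepted(S, i, j, k_rss, confidence, model, n_candidates):
    """F-test: does the two-piece fit significantly beat the one-piece fit?

    The tested breakpoint is the RSS-minimising candidate of the
    region, i.e. a scan statistic, so the critical value carries a
    Bonferroni correction over the number of admissible candidates;
    without it the family-wise false-split rate on pure noise would far
    exceed 1 - confidence.
    """
    n = j - i
    p = 1 if model == "constant" else 2  # parameters added by the extra piece
    df2 = n - 2 * p
    if df2 <= 0:
        return False
    rss0 = float(S.rss(i, j, model))
    rss1 = k_rss
    tol = 1e-10 * S.scale
    if rss0 <= tol:
        return False  # already a perfect fit
    if rss1 <= tol:
        return True  # split is (numerically) perfect, one piece is not
    F = ((rss0 - rss1) / p) / (rss1 / df2)
    alpha = (1.0 - confidence) / max(n_candidates, 1)
    crit = stats.f.isf(alpha, p, df2)
    return F > crit


def _split_margin(S, a, b, c, confidence, model, min_pts):
    """F / critical-value ratio for keeping boundary b inside region [a, c)."""
    n = c - a
    p = 1 if model == "constant" else 2
    df2 = n - 2 * p
    if df2 <= 0:
        return 0.0
    rss0 = float(S.rss(a, c, model))
    rss1 = float(S.rss(a, b, model)) + float(S.rss(b, c, model))
    tol = 1e-10 * S.scale
    if rss0 <= tol:
        return 0.0
    if rss1 <= tol:
        return np.inf
    F = ((rss0 - rss1) / p) / (rss1 / df2)
    alpha = (1.0 - confidence) / max(n - 2 * min_pts + 1, 1)
    return F / stats.f.isf(alpha, p, df2)


def _prune(S, boundaries, confidence, model, min_pts):
    """Backward elimination of boundaries that are not significant in place.

    Binary segmentation can misplace a boundary by a few samples and
    compensate with a short spurious segment; re-testing every interior
    boundary against its merged neighbourhood and removing the weakest
    until all are significant eliminates those artifacts.
    """
    boundaries = list(boundaries)
    while len(boundaries) > 2:
        margins = [
            _split_margin(
                S, boundaries[i - 1], boundaries[i], boundaries[i + 1],
                confidence, model, min_pts,
            )
            for i in range(1, len(boundaries) - 1)
        ]
        worst = int(np.argmin(margins))
        if margins[worst] > 1.0:
            break
        del boundaries[worst + 1]
    return boundaries


def _validate(t, x, min_pts):
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.ndim != 1 or x.ndim != 1 or t.shape != x.shape:
        raise ValueError("t and x must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
        raise ValueError("trace contains NaN or infinite samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    return t, x


def _segment(t, x, confidence, min_pts, model):
    t, x = _validate(t, x, min_pts)
    n = len(t)
    flags: list[str] = []
    if n < 2 * min_pts:
        flags.append("too_short")
        seg = _ols_segment(t, x, 0, n, model)
        return SegmentedFit([seg], confidence, model, tuple(flags), t, x)
    S = _PrefixSums(t, x)
    boundaries = [0, n]
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2 * min_pts:
            continue
        found = _best_split(S, i, j, min_pts, model)
        if found is None:
            continue
        k, k_rss = found
        n_cand = (j - i) - 2 * min_pts + 1
        if _split_accepted(S, i, j, k_rss, confidence, model, n_cand):
            boundaries.append(k)
            stack.append((i, k))
            stack.append((k, j))
    boundaries = _prune(S, sorted(set(boundaries)), confidence, model, min_pts)
    segs = [
        _ols_segment(t, x, a, b, model)
        for a, b in zip(boundaries[:-1], boundaries[1:])
    ]
    return SegmentedFit(segs, confidence, model, tuple(flags), t, x)


def fit_piecewise_linear(
    t,
    x,
    confidence: float = DEFAULT_CONFIDENCE,
    min_segment_points: int = DEFAULT_MIN_SEGMENT_POINTS,
) -> SegmentedFit:
    """Segment a position-vs-time trace into piecewise-linear regimes.

    Parameters
    ----------
    t, x : array-like
        Sample times (strictly increasing, s) and positions.
    confidence : float
        Confidence level of the per-split F-test (default 0.95).
    min_segment_points : int
        Minimum samples per fitted segment (default 3).

    Returns
    -------
    SegmentedFit
        Ordered contiguous segments with per-segment OLS slope,
        intercept and slope standard error.  Traces shorter than
        ``2 * min_segment_points`` yield a single segment flagged
        ``'too_short'``.
    """
    return _segment(t, x, confidence, min_segment_points, "linear")


def fit_steps(
    t,
    x,
    confidence: float = DEFAULT_CONFIDENCE,
    min_dwell_points: int = DEFAULT_MIN_DWELL_POINTS,
) -> SegmentedFit:
    """Segment an intensity trace into constant plateaus (bleaching steps).

    Same recursion as :func:`fit_piecewise_linear` but with mean-level
    models; the plateau level is stored in ``Segment.intercept`` and
    step amplitudes are available via ``SegmentedFit.step_amplitudes``.
    """
    return _segment(t, x, confidence, min_dwell_points, "constant")


def first_split(
    t,
    x,
    confidence: float = DEFAULT_CONFIDENCE,
    min_segment_points: int = DEFAULT_MIN_SEGMENT_POINTS,
    model: str = "linear",
):
    """Index of the first accepted top-level split, or None.

    Exposed so the recursive engine can be compared split-by-split
    against the exhaustive oracle.
    """
    t, x = _validate(t, x, min_segment_points)
    n = len(t)
    if n < 2 * min_segment_points:
        return None
    S = _PrefixSums(t, x)
    found = _best_split(S, 0, n, min_segment_points, model)
    if found is None:
        return None
    k, k_rss = found
    n_cand = n - 2 * min_segment_points + 1
    return k if _split_accepted(S, 0, n, k_rss, confidence, model, n_cand) else None


def oracle_best_split(t, x, model: str = "linear", min_segment_points: int | None = None):
    """Exhaustive single-breakpoint search (test oracle).

    Fits both sides of every admissible breakpoint with independent
    least squares and returns ``(k, rss)`` for the global minimiser of
    the combined RSS; ties are broken toward the earliest breakpoint.
    Intended for traces of at most ~10 000 points.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(t)
    if n > 10_000:
        raise ValueError("oracle is limited to traces of <= 10000 points")
    if min_segment_points is None:
        min_segment_points = (
            DEFAULT_MIN_DWELL_POINTS if model == "constant" else DEFAULT_MIN_SEGMENT_POINTS
        )

    def side_rss(a, b):
        ts, xs = t[a:b], x[a:b]
        if model == "constant":
            return float(np.sum((xs - xs.mean()) ** 2))
        if len(ts) < 2 or np.ptp(ts) == 0:
            return float(np.sum((xs - xs.mean()) ** 2))
        coef = np.polyfit(ts, xs, 1)
        return float(np.sum((xs - np.polyval(coef, ts)) ** 2))

    best_k, best_rss = None, np.inf
    for k in range(min_segment_points, n - min_segment_points + 1):
        r = side_rss(0, k) + side_rss(k, n)
        if best_k is None or r < best_rss - 1e-12 * (1.0 + abs(best_rss)):
            best_k, best_rss = k, r
    if best_k is None:
        raise ValueError("no admissible breakpoint")
    return best_k, best_rss
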