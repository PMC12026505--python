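"""Transverse-flow strand traces and fork-rotation fluctuation statistics.

Under transverse flow the parental, leading and lagging strands of a
replication fork are spatially separated; per-frame segmentation masks
give the length of each strand over time.  Fork rotation wraps the
lagging-strand product around the leading strand, producing large
frame-to-frame length fluctuations that are quantified as the variance
of the first-differenced (stationary) lagging-length series, with
Dickey-Fuller unit-root tests confirming stationarity after
differencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.morphology import skeletonize
from statsmodels.tsa.stattools import adfuller

from . import kinetics as _kinetics
from .changepoint import fit_piecewise_linear

__all__ = [
    "AdfResult",
    "FluctuationSummary",
    "skeleton_length",
    "import_masks",
    "calibrate_bp_per_px",
    "difference_series",
    "adf_test",
    "fluctuation_variance",
    "analyze_fluctuations",
    "transverse_kinetics",
]

STRAND_NAMES = ("parental", "leading", "lagging")


# ---------------------------------------------------------------------------
# mask import
# ---------------------------------------------------------------------------

def skeleton_length(mask: np.ndarray) -> float:
    """Geodesic length (px) of a labelled strand region.

    The region is skeletonized and the length is 1 + the sum of
    inter-pixel steps along the skeleton (1 for 4-neighbours, sqrt(2)
    for diagonal neighbours that are not already bridged by an axial
    pixel), so a straight n-pixel line has length n.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("nan")
    skel = skeletonize(mask)
    coords = set(map(tuple, np.argwhere(skel)))
    axial = 0
    diag = 0
    for (y, x) in coords:
        if (y, x + 1) in coords:
            axial += 1
        if (y + 1, x) in coords:
            axial += 1
        for dy, dx in ((1, 1), (1, -1)):
            if (y + dy, x + dx) in coords:
                # skip diagonals short-circuited by a shared axial neighbour
                if (y, x + dx) in coords or (y + dy, x) in coords:
                    continue
                diag += 1
    return float(1 + axial + np.sqrt(2.0) * diag)


def import_masks(
    label_stack: np.ndarray,
    class_map: dict[int, str],
    frame_interval_s: float = 5.0,
    bp_per_px: float | None = None,
    template_bp: int = 27_000,
    molecule_id=None,
) -> pd.DataFrame:
    """Strand lengths per frame from a label-image stack.

    ``class_map`` maps label values to strand names ('parental',
    'leading', 'lagging').  A class missing from a frame is recorded
    as missing (NaN), never zero.  When ``bp_per_px`` is None it is
    calibrated per molecule from the final leading-strand length
    (template / final leading px), assuming full replication.
    """
    label_stack = np.asarray(label_stack)
    rows = []
    for f, labels in enumerate(label_stack):
        row: dict = {"molecule_id": molecule_id, "frame": f, "t_s": f * frame_interval_s}
        for value, name in class_map.items():
            if name not in STRAND_NAMES:
                raise ValueError(f"unknown strand class {name!r}")
            row[f"{name}_px"] = skeleton_length(labels == value)
        rows.append(row)
    df = pd.DataFrame(rows)
    if bp_per_px is None:
        bp_per_px = calibrate_bp_per_px(df["leading_px"].to_numpy(), template_bp)
    for name in STRAND_NAMES:
        if f"{name}_px" in df:
            df[f"{name}_bp"] = df[f"{name}_px"] * bp_per_px
    df.attrs["bp_per_px"] = bp_per_px
    return df


def calibrate_bp_per_px(leading_px: np.ndarray, template_bp: int = 27_000) -> float:
    """Per-molecule bp/px scale from the fully replicated leading strand."""
    leading_px = np.asarray(leading_px, dtype=float)
    final = leading_px[~np.isnan(leading_px)]
    if final.size == 0 or final[-1] <= 0:
        raise ValueError("cannot calibrate: no final leading-strand length")
    return float(template_bp / final[-1])


# ---------------------------------------------------------------------------
# stationarity statistics
# ---------------------------------------------------------------------------

def difference_series(x) -> np.ndarray:
    """First differences d(t) = x(t) - x(t-1); pairs spanning a missing value dropped."""
    x = np.asarray(x, dtype=float)
    if np.sum(~np.isnan(x)) < 2:
        raise ValueError("need at least 2 non-missing points")
    d = np.diff(x)
    return d[~np.isnan(d)]


@dataclass(frozen=True)
class AdfResult:
    statistic: float
    pvalue: float
    critical_5pct: float
    stationary: bool  # unit root rejected at 5 %


def adf_test(series, lag: int = 1) -> AdfResult:
    """Augmented Dickey-Fuller unit-root test (constant-only regression).

    Regresses the first difference on a constant, the lagged level and
    ``lag`` lagged differences; the decision compares the t-ratio of
    the lagged-level coefficient against the tabulated 5 % critical
    value.
    """
    series = np.asarray(series, dtype=float)
    series = series[~np.isnan(series)]
    if len(series) < 20:
        raise ValueError("series too short for an ADF test (need >= 20 points)")
    stat, pvalue, _, _, crit = adfuller(
        series, maxlag=lag, regression="c", autolag=None
    )[:5]
    crit5 = float(crit["5%"])
    return AdfResult(float(stat), float(pvalue), crit5, bool(stat < crit5))


def fluctuation_variance(lagging_kb) -> float:
    """Sample variance (kb^2) of the first-differenced lagging-length series.

    For a smooth trace with i.i.d. measurement noise of SD sigma the
    expectation is 2 sigma^2; wrap/unwrap events from fork rotation
    inflate it.
    """
    d = difference_series(np.asarray(lagging_kb, dtype=float))
    if len(d) < 10:
        raise ValueError("differenced series too short (need >= 10 points)")
    return float(np.var(d, ddof=1))


@dataclass(frozen=True)
class FluctuationSummary:
    molecule_id: object
    adf_statistic_raw: float
    adf_statistic_diff: float
    stationary_after_diff: bool
    diff_variance_kb2: float


def analyze_fluctuations(trace: pd.DataFrame, lag: int = 1) -> FluctuationSummary:
    """Stationarity tests + first-difference variance of one lagging-length trace.

    ``trace`` needs columns ``molecule_id`` and ``lagging_bp``.
    """
    lagging_kb = trace["lagging_bp"].to_numpy(dtype=float) / 1000.0
    raw = adf_test(lagging_kb, lag)
    diffd = difference_series(lagging_kb)
    diff = adf_test(diffd, lag)
    mid = trace["molecule_id"].iloc[0] if "molecule_id" in trace else None
    return FluctuationSummary(
        molecule_id=mid,
        adf_statistic_raw=raw.statistic,
        adf_statistic_diff=diff.statistic,
        stationary_after_diff=diff.stationary,
        diff_variance_kb2=fluctuation_variance(lagging_kb),
    )


# ---------------------------------------------------------------------------
# per-strand kinetics
# ---------------------------------------------------------------------------

def transverse_kinetics(
    trace: pd.DataFrame,
    template_bp: float = 27_000,
    confidence: float = 0.95,
    pause_threshold: float = _kinetics.PAUSE_THRESHOLD_BP_S,
) -> dict[str, dict]:
    """Change-point rates for each strand's length-vs-time series.

    Pauses are classified on the slope magnitude so the shrinking
    parental strand (negative slope) is handled symmetrically; the
    signed duration-weighted rate over burst segments is reported per
    strand, along with the fitted endpoint.
    """
    t = trace["t_s"].to_numpy(dtype=float)
    out = {}
    for strand in STRAND_NAMES:
        col = f"{strand}_bp"
        if col not in trace:
            continue
        x = trace[col].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        fit = fit_piecewise_linear(t[ok], x[ok], confidence)
        fit = _kinetics.classify_segments(fit, pause_threshold, by_magnitude=True)
        fit = _kinetics._mark_terminal_plateau(fit)
        bursts = [s for s in fit.segments if s.klass == "burst"]
        if bursts:
            w = np.array([s.duration for s in bursts])
            v = np.array([s.slope for s in bursts])
            rate = float(np.sum(w * v) / np.sum(w)) if w.sum() else float(np.mean(v))
        else:
            rate = float("nan")
        last = fit.segments[-1]
        out[strand] = {
            "rate_bp_s": rate,
            "n_pauses": _kinetics.n_pause_events(fit),
            "endpoint_bp": float(last.predict(last.t_end)),
            "n_segments": fit.n_segments,
        }
    return out
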