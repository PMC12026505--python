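"""Replication kinetics from segmented traces, plus nicking survival.

Converts piecewise-linear fits of lagging-strand position traces into
the headline per-molecule quantities: duration-weighted burst rate,
merged pause events, processivity (fitted endpoint of the final
segment) and completion; aggregates them per condition; and fits the
photo-nicking survival curve y = y0 * 0.5^(x/b) where b is the
half-life.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .changepoint import SegmentedFit, fit_piecewise_linear, fit_steps

__all__ = [
    "KineticsSummary",
    "SurvivalFit",
    "PAUSE_THRESHOLD_BP_S",
    "classify_segments",
    "burst_rate",
    "n_pause_events",
    "processivity",
    "analyze_trace",
    "analyze_cohort",
    "summarize_condition",
    "detect_nick_events",
    "fit_survival",
]

# Rates below 15 bp/s (a ~6-fold reduction from the median burst rate)
# count as pausing; the boundary is strict ("lower than").
PAUSE_THRESHOLD_BP_S = 15.0
COMPLETION_TOLERANCE_BP = 1000.0


@dataclass(frozen=True)
class KineticsSummary:
    """Headline kinetics of one molecule."""

    molecule_id: object
    burst_rate: float  # bp/s, NaN when undefined
    burst_rate_unweighted: float
    n_pauses: int
    processivity: float  # bp
    completed: bool
    excluded: bool = False
    reason: str = ""


def classify_segments(
    fit: SegmentedFit,
    pause_threshold: float = PAUSE_THRESHOLD_BP_S,
    by_magnitude: bool = False,
) -> SegmentedFit:
    """Label each segment 'burst' or 'pause'.

    A segment is a pause iff its slope (or |slope| when
    ``by_magnitude`` is set, for strands that shorten) is strictly
    below ``pause_threshold``; a slope exactly at the threshold is a
    burst.
    """
    segs = []
    for s in fit.segments:
        v = abs(s.slope) if by_magnitude else s.slope
        segs.append(s.with_class("pause" if v < pause_threshold else "burst"))
    return dataclasses.replace(fit, segments=segs)


def _mark_terminal_plateau(fit: SegmentedFit) -> SegmentedFit:
    """Reclassify the trailing run of pause segments as the post-termination plateau.

    Once synthesis terminates the trace sits flat until the movie ends;
    that plateau is below the pause threshold but is not a pausing
    event.  Only a pause run that touches the end of the trace is
    terminal.
    """
    segs = list(fit.segments)
    i = len(segs) - 1
    while i >= 0 and segs[i].klass == "pause":
        segs[i] = segs[i].with_class("terminal")
        i -= 1
    return dataclasses.replace(fit, segments=segs)


def n_pause_events(fit: SegmentedFit) -> int:
    """Number of merged pause events (adjacent pause segments count once)."""
    n = 0
    prev = None
    for s in fit.segments:
        if s.klass == "pause" and prev != "pause":
            n += 1
        prev = s.klass
    return n


def burst_rate(fit: SegmentedFit, weighted: bool = True) -> float:
    """Mean slope over burst segments, duration-weighted by default.

    Raises ``ValueError`` if the fit has no burst segment (an all-pause
    molecule has no defined burst rate).
    """
    bursts = [s for s in fit.segments if s.klass == "burst"]
    if not bursts:
        raise ValueError("no burst segments; burst rate undefined")
    if not weighted:
        return float(np.mean([s.slope for s in bursts]))
    w = np.array([s.duration for s in bursts])
    v = np.array([s.slope for s in bursts])
    if w.sum() == 0:
        return float(np.mean(v))
    return float(np.sum(w * v) / np.sum(w))


def processivity(
    fit: SegmentedFit,
    template_bp: float = 27_000,
    completion_tolerance: float = COMPLETION_TOLERANCE_BP,
) -> tuple[float, bool]:
    """Fitted position at the end of the final segment, and completion.

    A molecule is completed when the endpoint reaches
    ``template_bp - completion_tolerance``.
    """
    last = fit.segments[-1]
    endpoint = float(np.clip(last.predict(last.t_end), 0.0, template_bp))
    return endpoint, bool(endpoint >= template_bp - completion_tolerance)


def analyze_trace(
    t,
    x,
    molecule_id=None,
    template_bp: float = 27_000,
    confidence: float = 0.95,
    pause_threshold: float = PAUSE_THRESHOLD_BP_S,
    completion_tolerance: float = COMPLETION_TOLERANCE_BP,
    min_segment_points: int = 3,
    exclude_active_at_end: bool = True,
) -> tuple[KineticsSummary, SegmentedFit]:
    """Segment one position trace and extract its kinetics.

    Molecules with no burst segment are excluded ('no_burst').  When
    ``exclude_active_at_end`` is set, molecules whose final segment is
    still a burst short of the template (replication ran past the end
    of the movie, so rate and processivity would be censored) are
    excluded with reason 'active_at_end'.
    """
    fit = fit_piecewise_linear(t, x, confidence, min_segment_points)
    fit = classify_segments(fit, pause_threshold)
    fit = _mark_terminal_plateau(fit)
    proc, completed = processivity(fit, template_bp, completion_tolerance)
    bursts = [s for s in fit.segments if s.klass == "burst"]
    if not bursts:
        summ = KineticsSummary(molecule_id, np.nan, np.nan, 0, proc, completed,
                               excluded=True, reason="no_burst")
        return summ, fit
    excluded, reason = False, ""
    if (
        exclude_active_at_end
        and fit.segments[-1].klass == "burst"
        and proc < template_bp - completion_tolerance
    ):
        excluded, reason = True, "active_at_end"
    summ = KineticsSummary(
        molecule_id,
        burst_rate(fit, weighted=True),
        burst_rate(fit, weighted=False),
        n_pause_events(fit),
        proc,
        completed,
        excluded=excluded,
        reason=reason,
    )
    return summ, fit


def analyze_cohort(traces: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Run :func:`analyze_trace` on every molecule of a tidy trace table.

    ``traces`` needs columns ``molecule_id, t_s, position_bp``.
    """
    out = []
    for mid, g in traces.groupby("molecule_id"):
        g = g.sort_values("t_s")
        summ, _ = analyze_trace(
            g["t_s"].to_numpy(), g["position_bp"].to_numpy(), molecule_id=mid, **kwargs
        )
        out.append(dataclasses.asdict(summ))
    return pd.DataFrame(out)


def summarize_condition(summaries: pd.DataFrame) -> dict:
    """Condition-level means +/- SEM and pause/completion fractions.

    Excluded molecules are reported in the counts but do not contribute
    to the kinetic statistics.  SEM is NaN at n = 1.
    """
    if len(summaries) == 0:
        raise ValueError("no molecules to summarize")
    ok = summaries[~summaries["excluded"]]
    if len(ok) == 0:
        raise ValueError("all molecules were excluded")
    n = len(ok)

    def sem(v):
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")

    pauses = ok["n_pauses"].to_numpy()
    return {
        "n": n,
        "n_excluded": int(summaries["excluded"].sum()),
        "burst_rate_mean": float(ok["burst_rate"].mean()),
        "burst_rate_sem": sem(ok["burst_rate"]),
        "processivity_mean_bp": float(ok["processivity"].mean()),
        "processivity_sem_bp": sem(ok["processivity"]),
        "completion_fraction": float(ok["completed"].mean()),
        "pause_fraction_0": float(np.mean(pauses == 0)),
        "pause_fraction_1": float(np.mean(pauses == 1)),
        "pause_fraction_2plus": float(np.mean(pauses >= 2)),
        "pause_fraction_any": float(np.mean(pauses >= 1)),
    }


# ---------------------------------------------------------------------------
# photo-nicking survival
# ---------------------------------------------------------------------------

def detect_nick_events(
    areas: pd.DataFrame,
    confidence: float = 0.95,
    min_dwell_points: int = 2,
    snr_factor: float = 2.0,
) -> pd.DataFrame:
    """Per-molecule nick time from area-vs-time step fitting.

    The nick is the first upward step whose amplitude exceeds
    ``snr_factor`` times the pre-step residual SD; molecules without
    such a step are right-censored at the movie end.  Returns columns
    ``molecule_id, nick_time_s, censored``.
    """
    rows = []
    for mid, g in areas.groupby("molecule_id"):
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy()
        a = g["area_px2"].to_numpy()
        fit = fit_steps(t, a, confidence, min_dwell_points)
        nick, censored = float(t[-1]), True
        for prev, nxt in zip(fit.segments[:-1], fit.segments[1:]):
            amp = nxt.intercept - prev.intercept
            pre_sd = np.sqrt(prev.rss / prev.n_points)
            if amp > snr_factor * pre_sd:
                nick, censored = float(nxt.t_start), False
                break
        rows.append({"molecule_id": mid, "nick_time_s": nick, "censored": censored})
    return pd.DataFrame(rows)


@dataclass
class SurvivalFit:
    """Exponential-decay survival fit on the percent scale.

    ``y0`` is the initial percentage and ``b`` the half-life (s) of
    y = y0 * 0.5^(x/b).
    """

    y0: float
    b: float
    x: np.ndarray
    y: np.ndarray
    cov: np.ndarray | None = None
    flags: tuple[str, ...] = ()


def survival_curve(nick_events: pd.DataFrame, t_grid=None) -> tuple[np.ndarray, np.ndarray]:
    """Percentage of unnicked molecules vs time.

    At each grid time the fraction of molecules not yet nicked
    (censored molecules count as unnicked) over the starting total.
    """
    times = nick_events["nick_time_s"].to_numpy(dtype=float)
    censored = nick_events["censored"].to_numpy(dtype=bool)
    if t_grid is None:
        t_end = float(times.max())
        t_grid = np.linspace(0.0, t_end, 50)
    t_grid = np.asarray(t_grid, dtype=float)
    event = ~censored
    y = np.array(
        [100.0 * np.mean(~(event & (times <= tt))) for tt in t_grid]
    )
    return t_grid, y


def _survival_model(x, y0, b):
    return y0 * 0.5 ** (x / b)


def fit_survival_points(x, y, b0: float | None = None) -> SurvivalFit:
    """Nonlinear least squares of y = y0 * 0.5^(x/b) on (x, y) pairs.

    ``y`` is on the percent scale.  A constant curve has no finite
    half-life: b = inf, flagged 'degenerate'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        return SurvivalFit(float(y[0]), np.inf, x, y, None, ("degenerate",))
    if b0 is None:
        b0 = float(x[len(x) // 2]) or 1.0
    popt, pcov = optimize.curve_fit(
        _survival_model, x, y, p0=(100.0, b0),
        bounds=((0.0, 1e-9), (200.0, np.inf)), maxfev=10_000,
    )
    return SurvivalFit(float(popt[0]), float(popt[1]), x, y, pcov)


def fit_survival(nick_events: pd.DataFrame, t_grid=None) -> SurvivalFit:
    """Fit y = y0 * 0.5^(x/b) to the observed survival fractions.

    Needs at least 5 molecules.  When no nick events were observed the
    half-life is unbounded: b = inf, flagged 'degenerate'.
    """
    if len(nick_events) < 5:
        raise ValueError("need at least 5 molecules for a survival fit")
    x, y = survival_curve(nick_events, t_grid)
    if not nick_events["censored"].eq(False).any():
        return SurvivalFit(float(y[0]), np.inf, x, y, None, ("degenerate",))
    events = nick_events.loc[~nick_events["censored"], "nick_time_s"]
    return fit_survival_points(x, y, b0=float(np.median(events)) or 1.0)
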