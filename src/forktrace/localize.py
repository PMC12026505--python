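"""Spot detection, subpixel localization, drift correction and DNA registration.

Coordinates are 0-based pixel indices; the subpixel centre of pixel
``i`` is ``i``.  Times are seconds from the first frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

log = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "DnaModel",
    "RegistrationError",
    "detect_peaks",
    "integrate_intensity",
    "IntegrationResult",
    "find_fiducials",
    "correct_drift",
    "link_trajectories",
    "register_to_dna",
    "track_movie",
]


@dataclass(frozen=True)
class Peak:
    """A subpixel-localized fluorescent spot in one frame."""

    x: float
    y: float
    amplitude: float
    background: float
    sigma: float
    fit_residual: float
    frame: int = -1


@dataclass(frozen=True)
class DnaModel:
    """A fitted surface-tethered DNA molecule.

    ``end1``/``end2`` are (x, y) pixel coordinates of the two ends;
    the bp scale follows from the template length.
    """

    end1: tuple[float, float]
    end2: tuple[float, float]
    template_bp: int = 27_000

    @property
    def length_px(self) -> float:
        return float(np.hypot(self.end2[0] - self.end1[0], self.end2[1] - self.end1[1]))

    @property
    def bp_per_px(self) -> float:
        return self.template_bp / self.length_px


class RegistrationError(ValueError):
    """Trajectory could not be registered onto a DNA molecule."""


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _gaussian2d(params, xg, yg):
    amp, x0, y0, sigma, bg = params
    return bg + amp * np.exp(-((xg - x0) ** 2 + (yg - y0) ** 2) / (2 * sigma**2))


def _fit_gaussian(frame: np.ndarray, cx: int, cy: int, window: int = 7) -> Peak | None:
    half = window // 2
    ny, nx = frame.shape
    x_lo, x_hi = max(0, cx - half), min(nx, cx + half + 1)
    y_lo, y_hi = max(0, cy - half), min(ny, cy + half + 1)
    patch = frame[y_lo:y_hi, x_lo:x_hi].astype(float)
    yg, xg = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    bg0 = float(patch.min())
    amp0 = max(float(patch.max() - bg0), 1e-6)
    p0 = [amp0, float(cx), float(cy), 1.3, bg0]
    lb = [0.0, x_lo - 1.0, y_lo - 1.0, 0.8, -np.inf]
    ub = [np.inf, x_hi, y_hi, 3.0, np.inf]
    try:
        res = optimize.least_squares(
            lambda p: (_gaussian2d(p, xg, yg) - patch).ravel(),
            p0,
            bounds=(lb, ub),
            method="trf",
            max_nfev=200,
        )
    except Exception as exc:  # pragma: no cover - defensive
        log.warning("Gaussian fit raised %s at (%d, %d); peak dropped", exc, cx, cy)
        return None
    if not res.success:
        log.warning("Gaussian fit did not converge at (%d, %d); peak dropped", cx, cy)
        return None
    amp, x0, y0, sigma, bg = res.x
    return Peak(
        x=float(x0),
        y=float(y0),
        amplitude=float(amp),
        background=float(bg),
        sigma=float(sigma),
        fit_residual=float(np.sqrt(np.mean(res.fun**2))),
    )


def detect_peaks(
    frame: np.ndarray,
    threshold_sd: float = 5.0,
    window: int = 7,
    merge_radius: float = 2.0,
) -> list[Peak]:
    """Detect and subpixel-localize spots in one image.

    Local maxima above ``background + threshold_sd * robust SD``
    (median / MAD estimates) are refined by a 2-D Gaussian least-squares
    fit in a ``window x window`` patch with the PSF width fitted jointly
    (bounded [0.8, 3] px).  Duplicates within ``merge_radius`` px are
    merged keeping the higher amplitude; non-converged fits are dropped
    with a logged warning.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite-valued")
    bg = float(np.median(frame))
    mad = float(np.median(np.abs(frame - bg)))
    sd = 1.4826 * mad
    thresh = bg + threshold_sd * sd
    local_max = frame == ndimage.maximum_filter(frame, size=3)
    cand = np.argwhere(local_max & (frame > thresh))
    # brightest first so merging keeps the higher-amplitude fit
    cand = cand[np.argsort(-frame[cand[:, 0], cand[:, 1]])]
    peaks: list[Peak] = []
    for cy, cx in cand:
        pk = _fit_gaussian(frame, int(cx), int(cy), window)
        if pk is None:
            continue
        if any(np.hypot(pk.x - q.x, pk.y - q.y) < merge_radius for q in peaks):
            continue
        peaks.append(pk)
    return peaks


# ---------------------------------------------------------------------------
# intensity integration
# ---------------------------------------------------------------------------

class IntegrationResult(NamedTuple):
    value: float
    clipped: bool


def integrate_intensity(
    frame: np.ndarray,
    center: tuple[float, float],
    inner_radius: float = 3.0,
    outer_radius: float = 12.0,
) -> IntegrationResult:
    """Background-subtracted integrated spot intensity.

    Sums pixels within ``inner_radius`` of ``center`` (x, y) and
    subtracts the median of the annulus ``inner < r <= outer`` times
    the inner-disk pixel count.  If the annulus is clipped by the image
    border the value is still returned with ``clipped=True``.
    """
    frame = np.asarray(frame, dtype=float)
    ny, nx = frame.shape
    x0, y0 = center
    yg, xg = np.mgrid[0:ny, 0:nx]
    r = np.hypot(xg - x0, yg - y0)
    inner = r <= inner_radius
    annulus = (r > inner_radius) & (r <= outer_radius)
    clipped = (
        x0 - outer_radius < 0
        or y0 - outer_radius < 0
        or x0 + outer_radius > nx - 1
        or y0 + outer_radius > ny - 1
    )
    if not annulus.any():
        raise ValueError("annulus contains no pixels")
    bg = float(np.median(frame[annulus]))
    value = float(frame[inner].sum() - bg * inner.sum())
    return IntegrationResult(value=value, clipped=bool(clipped))


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def find_fiducials(
    traj: pd.DataFrame,
    max_total_displacement_px: float = 1.0,
    min_presence: float = 0.95,
    n_frames: int | None = None,
) -> list:
    """Identify immobile surface-stuck spots among linked trajectories.

    A fiducial is present in at least ``min_presence`` of the movie's
    frames and moves less than ``max_total_displacement_px`` overall
    *relative to the consensus (median) motion of all full-length
    tracks* — stuck dots share the stage drift, so the residual after
    removing the common mode is what distinguishes them from mobile
    molecules.
    """
    if n_frames is None:
        n_frames = int(traj["frame"].max()) + 1
    full = {}
    for mid, g in traj.groupby("molecule_id"):
        if len(g) < min_presence * n_frames or len(g) < 2:
            continue
        g = g.sort_values("frame")
        full[mid] = (
            g["frame"].to_numpy(dtype=int),
            g["x_px"].to_numpy() - g["x_px"].iloc[0],
            g["y_px"].to_numpy() - g["y_px"].iloc[0],
        )
    if not full:
        return []
    # consensus per-frame displacement over candidate tracks
    cx = np.full((len(full), n_frames), np.nan)
    cy = np.full((len(full), n_frames), np.nan)
    for i, (f, dx, dy) in enumerate(full.values()):
        cx[i, f] = dx
        cy[i, f] = dy
    with np.errstate(all="ignore"):
        consensus_x = np.nanmedian(cx, axis=0)
        consensus_y = np.nanmedian(cy, axis=0)
    ids = []
    for mid, (f, dx, dy) in full.items():
        rx = dx - consensus_x[f]
        ry = dy - consensus_y[f]
        if np.hypot(np.ptp(rx[np.isfinite(rx)]), np.ptp(ry[np.isfinite(ry)])) < max_total_displacement_px:
            ids.append(mid)
    return ids


def correct_drift(
    traj: pd.DataFrame, fiducials: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtract per-frame median fiducial displacement from all coordinates.

    Frame 0 is the reference.  Both the corrected trajectories and the
    corrected fiducial table are returned, which makes the operation
    idempotent (correcting already-corrected data is the identity).
    Requires at least one fiducial tracked over every frame.
    """
    frames = np.arange(int(max(traj["frame"].max(), fiducials["frame"].max())) + 1)
    complete = [
        g for _, g in fiducials.groupby("molecule_id") if len(g) == len(frames)
    ]
    if not complete:
        raise ValueError(
            "no fiducial is tracked over all frames; disable drift correction "
            "or supply complete fiducial trajectories"
        )
    dx = np.zeros(len(frames))
    dy = np.zeros(len(frames))
    per_fid = []
    for g in complete:
        g = g.sort_values("frame")
        per_fid.append(
            (
                g["x_px"].to_numpy() - g["x_px"].to_numpy()[0],
                g["y_px"].to_numpy() - g["y_px"].to_numpy()[0],
            )
        )
    dx = np.median([p[0] for p in per_fid], axis=0)
    dy = np.median([p[1] for p in per_fid], axis=0)

    def apply(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        f = out["frame"].to_numpy(dtype=int)
        out["x_px"] = out["x_px"].to_numpy() - dx[f]
        out["y_px"] = out["y_px"].to_numpy() - dy[f]
        return out

    return apply(traj), apply(fiducials)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_trajectories(
    peaks_per_frame: list[list[Peak]],
    max_step: float = 3.0,
    max_gap: int = 1,
    frame_interval: float = 1.0,
) -> pd.DataFrame:
    """Greedy nearest-neighbour linking of per-frame peak lists.

    Candidate links are taken in order of increasing distance; links
    longer than ``max_step`` px (per elapsed frame) are rejected and
    gaps of up to ``max_gap`` missing frames are bridged.  Returns a
    tidy table ``molecule_id, frame, t_s, x_px, y_px, intensity_au``.
    """
    tracks: list[dict] = []  # each: {'id', 'last_frame', 'x', 'y', 'rows'}
    next_id = 0
    rows = []
    for f, peaks in enumerate(peaks_per_frame):
        open_tracks = [tr for tr in tracks if f - tr["last_frame"] <= max_gap + 1]
        pairs = []
        for ti, tr in enumerate(open_tracks):
            for pi, pk in enumerate(peaks):
                d = np.hypot(pk.x - tr["x"], pk.y - tr["y"])
                gap = f - tr["last_frame"]
                if d <= max_step * gap:
                    pairs.append((d, ti, pi))
        pairs.sort(key=lambda p: p[0])
        used_t, used_p = set(), set()
        for d, ti, pi in pairs:
            if ti in used_t or pi in used_p:
                continue
            used_t.add(ti)
            used_p.add(pi)
            tr = open_tracks[ti]
            pk = peaks[pi]
            tr.update(last_frame=f, x=pk.x, y=pk.y)
            rows.append((tr["id"], f, pk))
        for pi, pk in enumerate(peaks):
            if pi in used_p:
                continue
            tracks.append({"id": next_id, "last_frame": f, "x": pk.x, "y": pk.y})
            rows.append((next_id, f, pk))
            next_id += 1
    return pd.DataFrame(
        {
            "molecule_id": [r[0] for r in rows],
            "frame": [r[1] for r in rows],
            "t_s": [r[1] * frame_interval for r in rows],
            "x_px": [r[2].x for r in rows],
            "y_px": [r[2].y for r in rows],
            "intensity_au": [r[2].amplitude for r in rows],
        }
    ).sort_values(["molecule_id", "frame"], ignore_index=True)


# ---------------------------------------------------------------------------
# registration onto the DNA axis
# ---------------------------------------------------------------------------

def register_to_dna(
    traj: pd.DataFrame,
    dna: DnaModel,
    fork_end: str = "end1",
    max_perp_px: float = 3.0,
) -> pd.DataFrame:
    """Transform a trajectory into base-pair coordinates along a DNA.

    The signed along-axis distance from the fork end is scaled by
    ``bp_per_px`` and clamped to [0, template].  A molecule whose
    median perpendicular distance from the axis exceeds ``max_perp_px``
    is not colocalized and raises :class:`RegistrationError`.
    """
    if fork_end not in ("end1", "end2"):
        raise ValueError("fork_end must be 'end1' or 'end2'")
    origin = np.array(dna.end1 if fork_end == "end1" else dna.end2, dtype=float)
    other = np.array(dna.end2 if fork_end == "end1" else dna.end1, dtype=float)
    axis = (other - origin) / np.linalg.norm(other - origin)
    xy = traj[["x_px", "y_px"]].to_numpy(dtype=float) - origin
    along = xy @ axis
    perp = np.abs(xy @ np.array([-axis[1], axis[0]]))
    if np.median(perp) > max_perp_px:
        raise RegistrationError(
            f"trajectory not colocalized with DNA axis "
            f"(median perpendicular distance {np.median(perp):.2f} px > {max_perp_px} px)"
        )
    out = traj.copy()
    out["position_bp"] = np.clip(along * dna.bp_per_px, 0.0, dna.template_bp)
    return out


# ---------------------------------------------------------------------------
# convenience: movie -> trajectories
# ---------------------------------------------------------------------------

def track_movie(
    movie: np.ndarray,
    threshold_sd: float = 5.0,
    max_step: float = 3.0,
    max_gap: int = 1,
    frame_interval: float = 1.0,
    drift_correction: bool = True,
) -> pd.DataFrame:
    """Detect, link and (optionally) drift-correct spots in a stack."""
    peaks = [
        [Peak(**{**vars(p), "frame": f}) for p in detect_peaks(frame, threshold_sd)]
        for f, frame in enumerate(movie)
    ]
    traj = link_trajectories(peaks, max_step=max_step, max_gap=max_gap,
                             frame_interval=frame_interval)
    if drift_correction:
        fid_ids = find_fiducials(traj, n_frames=len(movie))
        if fid_ids:
            fid = traj[traj["molecule_id"].isin(fid_ids)]
            mobile = traj[~traj["molecule_id"].isin(fid_ids)]
            mobile, fid = correct_drift(mobile, fid)
            traj = pd.concat([mobile, fid], ignore_index=True).sort_values(
                ["molecule_id", "frame"], ignore_index=True
            )
    return traj
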