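"""Kymographs along a DNA axis and blob size quantification.

A kymograph collapses a movie onto one spatial axis: row t is the mean
over a perpendicular strip (default 5 px each side) at each position
along the marked DNA molecule.  The lagging-strand product size is the
number of supra-threshold ("white") pixels per row after smoothing and
per-kymograph Otsu thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Kymograph",
    "build_kymograph",
    "smooth",
    "otsu_threshold",
    "blob_size_series",
]


@dataclass
class Kymograph:
    """2-D array of intensity: rows are timepoints, columns axis positions."""

    data: np.ndarray  # (t, along-axis)
    pixel_size_nm: float = 100.0
    frame_interval_s: float = 5.0
    molecule_id: object = None


def build_kymograph(
    movie: np.ndarray,
    dna_start: tuple[float, float],
    dna_end: tuple[float, float],
    half_width: int = 5,
    pixel_size_nm: float = 100.0,
    frame_interval_s: float = 5.0,
    molecule_id=None,
) -> Kymograph:
    """Average a perpendicular strip of ``2*half_width + 1`` px per axis position.

    The axis runs from ``dna_start`` to ``dna_end`` (x, y) in 1-px
    steps; intensities are sampled by bilinear interpolation.  Strips
    reaching outside the field of view are clipped (edge values) with a
    warning.
    """
    movie = np.asarray(movie, dtype=float)
    nt, ny, nx = movie.shape
    x0, y0 = dna_start
    x1, y1 = dna_end
    length = float(np.hypot(x1 - x0, y1 - y0))
    n_axis = int(np.round(length)) + 1
    s = np.linspace(0.0, length, n_axis)
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    px, py = -uy, ux  # unit perpendicular
    offs = np.arange(-half_width, half_width + 1)
    xs = x0 + ux * s[None, :] + px * offs[:, None]  # (strip, axis)
    ys = y0 + uy * s[None, :] + py * offs[:, None]
    if xs.min() < 0 or ys.min() < 0 or xs.max() > nx - 1 or ys.max() > ny - 1:
        warnings.warn("kymograph strip clipped at the image border", stacklevel=2)
    data = np.empty((nt, n_axis))
    for f in range(nt):
        samples = ndimage.map_coordinates(
            movie[f], np.stack([ys.ravel(), xs.ravel()]), order=1, mode="nearest"
        ).reshape(xs.shape)
        data[f] = samples.mean(axis=0)
    return Kymograph(data, pixel_size_nm, frame_interval_s, molecule_id)


def smooth(kymo: Kymograph, window: int = 2) -> Kymograph:
    """Left-aligned moving average along the position axis.

    ``out[i] = mean(data[i : i + window])`` with edge replication so
    the length is preserved.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    d = kymo.data
    pad = np.concatenate([d, np.repeat(d[:, -1:], window - 1, axis=1)], axis=1)
    c = np.cumsum(pad, axis=1)
    c = np.concatenate([np.zeros((d.shape[0], 1)), c], axis=1)
    out = (c[:, window:] - c[:, :-window]) / window
    return Kymograph(out, kymo.pixel_size_nm, kymo.frame_interval_s, kymo.molecule_id)


def otsu_threshold(kymo: Kymograph | np.ndarray, nbins: int = 256) -> float:
    """Global Otsu threshold from a 256-bin histogram.

    Returns the bin-centre threshold maximizing the between-class
    variance; ties break toward the lower threshold.  Raises on a
    constant image.
    """
    data = kymo.data if isinstance(kymo, Kymograph) else np.asarray(kymo, dtype=float)
    flat = data.ravel()
    if np.ptp(flat) == 0:
        raise ValueError("cannot threshold a constant image")
    counts, edges = np.histogram(flat, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(counts)[:-1].astype(float)
    w1 = flat.size - w0
    csum = np.cumsum(counts * centers)[:-1]
    total = float(np.sum(counts * centers))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (total - csum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    k = int(np.argmax(between))  # argmax -> first (lowest) maximiser
    return float(centers[k])


def blob_size_series(
    kymo: Kymograph,
    threshold: float,
    tail_offset: int = 10,
    tail_length: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Per-frame white-pixel counts of the binarized kymograph.

    The end-of-reaction summary averages the ``tail_length`` rows
    starting ``tail_offset`` rows before the final one (the interval
    between 10 and 5 timepoints preceding the end).  Both the pixel
    count and the occupied column span are reported, each converted to
    um via the pixel size.  Reactions shorter than the tail window use
    the available rows and are flagged.
    """
    binary = kymo.data > threshold
    counts = binary.sum(axis=1)
    span = np.zeros(len(counts), dtype=int)
    for i, row in enumerate(binary):
        cols = np.flatnonzero(row)
        span[i] = (cols[-1] - cols[0] + 1) if cols.size else 0
    um_per_px = kymo.pixel_size_nm / 1000.0
    df = pd.DataFrame(
        {
            "frame": np.arange(len(counts)),
            "white_pixels": counts,
            "size_um": counts * um_per_px,
            "span_px": span,
            "span_um": span * um_per_px,
        }
    )
    n = len(counts)
    flag = n < tail_offset + 1
    lo = max(0, n - 1 - tail_offset)
    hi = max(1, n - 1 - tail_offset + tail_length)
    tail = df.iloc[lo:hi]
    summary = {
        "mean_size_um": float(tail["size_um"].mean()),
        "sd_size_um": float(tail["size_um"].std(ddof=1)) if len(tail) > 1 else float("nan"),
        "mean_span_um": float(tail["span_um"].mean()),
        "sd_span_um": float(tail["span_um"].std(ddof=1)) if len(tail) > 1 else float("nan"),
        "n_tail_rows": int(len(tail)),
        "short_reaction": bool(flag),
    }
    return df, summary
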