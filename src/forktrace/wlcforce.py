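"""Worm-like chain force estimation for replication fork arms.

The entropic elasticity of DNA relates extension z to stretching force
f through the interpolated worm-like chain expression

    f = (kB T / A) * [ z/L + 1 / (4 (1 - z/L)^2) - 1/4 ]

with persistence length A = 50 nm, temperature T = 296.15 K and
contour length L = 0.34 nm per base pair.  The force on the arch
formed by the leading + parental strands, and on the flow-stretched
lagging-strand product, is estimated per frame and summarized in
overlapping 3-kb bins of product length (1.5-kb step, products below
5 kb excluded) by the bin median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "WlcParams",
    "wlc_force",
    "wlc_extension",
    "contour_length",
    "arch_force",
    "lagging_force",
    "bin_forces",
]

BOLTZMANN_PN_NM_PER_K = 0.013806485  # kB in pN nm / K


@dataclass(frozen=True)
class WlcParams:
    """Polymer parameters of the worm-like chain model."""

    A: float = 50.0  # persistence length, nm
    T: float = 296.15  # temperature, K
    kB: float = BOLTZMANN_PN_NM_PER_K  # pN nm / K
    rise_per_bp: float = 0.34  # nm / bp

    def __post_init__(self):
        if min(self.A, self.T, self.kB, self.rise_per_bp) <= 0:
            raise ValueError("A, T, kB and rise_per_bp must be positive")

    @property
    def kBT(self) -> float:
        """Thermal energy, pN nm (4.0888 at 296.15 K)."""
        return self.kB * self.T


DEFAULT_PARAMS = WlcParams()


def wlc_force(z, L, params: WlcParams = DEFAULT_PARAMS):
    """Force (pN) stretching a WLC of contour length L (nm) to extension z (nm).

    Requires 0 <= z < L; vectorized over z and L.
    """
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(z < 0):
        raise ValueError("extension z must be non-negative")
    if np.any(z >= L):
        raise ValueError("extension z must be smaller than the contour length L")
    r = z / L
    f = params.kBT / params.A * (r + 1.0 / (4.0 * (1.0 - r) ** 2) - 0.25)
    return f if f.ndim else float(f)


def wlc_extension(f: float, L: float, params: WlcParams = DEFAULT_PARAMS) -> float:
    """Extension z (nm) producing force f (pN): numeric inverse of :func:`wlc_force`.

    Bisection (Brent) on [0, L(1 - 1e-6)], relative tolerance 1e-9.
    Needed by the movie/trace simulator; the analysis itself only uses
    the forward relation.
    """
    if f < 0:
        raise ValueError("force must be non-negative")
    if f == 0:
        return 0.0
    hi = L * (1.0 - 1e-6)
    if wlc_force(hi, L, params) < f:
        return hi
    return float(
        optimize.brentq(lambda z: wlc_force(z, L, params) - f, 0.0, hi, rtol=1e-9)
    )


def contour_length(n_bp, params: WlcParams = DEFAULT_PARAMS):
    """Contour length (nm) of n_bp base pairs of B-form DNA."""
    n_bp = np.asarray(n_bp, dtype=float)
    if np.any(n_bp < 0):
        raise ValueError("n_bp must be non-negative")
    out = n_bp * params.rise_per_bp
    return out if out.ndim else float(out)


def _force_series(contour_bp, extension_nm, params) -> tuple[np.ndarray, np.ndarray]:
    L = contour_length(np.asarray(contour_bp, dtype=float), params)
    z = np.asarray(extension_nm, dtype=float)
    ok = (z >= 0) & (z < L) & np.isfinite(z) & np.isfinite(L) & (L > 0)
    f = np.full(z.shape, np.nan)
    if ok.any():
        f[ok] = wlc_force(z[ok], L[ok], params)
    return f, ~ok


def arch_force(
    trace: pd.DataFrame, params: WlcParams = DEFAULT_PARAMS
) -> pd.DataFrame:
    """Per-frame force on the leading + parental arch.

    The contour length is set by the summed parental and leading
    base-pair content; the extension is the measured arch end-to-end
    length (``arch_extension_nm`` column).  Frames with z >= L are
    flagged and excluded from summaries (NaN force).
    """
    contour_bp = trace["parental_bp"].to_numpy() + trace["leading_bp"].to_numpy()
    f, flagged = _force_series(contour_bp, trace["arch_extension_nm"].to_numpy(), params)
    out = trace.copy()
    out["contour_bp"] = contour_bp
    out["force_pN"] = f
    out["flagged"] = flagged
    return out


def lagging_force(
    trace: pd.DataFrame, params: WlcParams = DEFAULT_PARAMS
) -> pd.DataFrame:
    """Per-frame force on the lagging-strand product.

    The expected contour follows the leading-strand base-pair content
    at the same timepoint; the extension is the measured lagging length
    (``lagging_extension_nm`` column).
    """
    contour_bp = trace["leading_bp"].to_numpy()
    f, flagged = _force_series(
        contour_bp, trace["lagging_extension_nm"].to_numpy(), params
    )
    out = trace.copy()
    out["contour_bp"] = contour_bp
    out["force_pN"] = f
    out["flagged"] = flagged
    return out


def bin_forces(
    estimates: pd.DataFrame,
    bin_width: float = 3000.0,
    step: float = 1500.0,
    min_length: float = 5000.0,
) -> tuple[pd.DataFrame, float, float]:
    """Median force in overlapping product-length bins, with a linear trend.

    Frames whose product length (``contour_bp``) is below
    ``min_length`` are excluded; bins are [k*step, k*step + bin_width)
    and empty bins are skipped.  Returns (bin table, trend slope
    pN/bp, trend intercept pN); the trend is NaN with fewer than two
    bins.
    """
    ok = estimates.dropna(subset=["force_pN"])
    ok = ok[ok["contour_bp"] >= min_length]
    if len(ok) == 0:
        return pd.DataFrame(columns=["bin_start", "bin_center", "median_force_pN", "n"]), float("nan"), float("nan")
    length = ok["contour_bp"].to_numpy(dtype=float)
    force = ok["force_pN"].to_numpy(dtype=float)
    k_max = int(np.floor(length.max() / step))
    rows = []
    for k in range(0, k_max + 1):
        lo = k * step
        hi = lo + bin_width
        m = (length >= lo) & (length < hi)
        if not m.any():
            continue
        rows.append(
            {
                "bin_start": lo,
                "bin_center": lo + bin_width / 2,
                "median_force_pN": float(np.median(force[m])),
                "n": int(m.sum()),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        slope, intercept = np.polyfit(table["bin_center"], table["median_force_pN"], 1)
    else:
        slope, intercept = float("nan"), float("nan")
    return table, float(slope), float(intercept)
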