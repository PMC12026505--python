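"""Synthetic single-molecule replication data with ground truth.

Emulates the data-generating processes of a flow-stretched DNA
replication assay so every analysis stage can be verified by parameter
recovery:

* piecewise-constant synthesis kinetics with pauses and termination
  (position-vs-time traces of the lagging-strand product),
* transverse-flow strand-length traces (parental / leading / lagging)
  with optional rotation-driven compaction ("wrap") events,
* stepwise photobleaching intensity traces and replisome intensity
  records for stoichiometry,
* diffraction-limited movies of a blob moving along a stained DNA,
* photo-nicking area traces of supercoiled molecules.

All randomness flows from a single ``numpy.random.Generator`` seeded
explicitly; identical (preset, n, seed) give bit-identical outputs.

Built-in presets mirror the two experimental conditions: molecules
tethered through a single biotin are free to swivel (``unconstrained``)
while multi-biotin attachment blocks rotation (``constrained``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KineticPreset",
    "RotationPreset",
    "PhotophysicsPreset",
    "MovieGeometry",
    "RenderSettings",
    "GroundTruth",
    "KINETIC_PRESETS",
    "ROTATION_PRESETS",
    "PHOTOPHYSICS_PRESETS",
    "simulate_kinetic_traces",
    "simulate_transverse_traces",
    "simulate_bleach_traces",
    "simulate_replisome_intensities",
    "render_movie",
    "simulate_nicking_movie",
    "reconstruct_position",
]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticPreset:
    """Generative parameters of a replication-kinetics condition.

    ``burst_rate_sd`` is the between-molecule SD; each molecule draws a
    single rate (truncated at +/- 2 SD to stay physical) that is
    constant between pauses.  ``pause_prob_once`` / ``pause_prob_twice``
    are per-molecule probabilities of exactly one / exactly two
    resolvable pauses.  Incomplete molecules terminate uniformly on
    ``incomplete_length_range`` (kb); the range endpoints are calibrated
    so the mixture mean matches the observed mean processivity.
    """

    burst_rate_mean: float  # bp/s
    burst_rate_sd: float  # bp/s, between molecules
    pause_prob_once: float
    pause_prob_twice: float
    pause_duration_mean: float  # s
    completion_prob: float
    incomplete_length_range: tuple[float, float]  # kb
    template_length: int = 27_000  # bp
    frame_interval: float = 5.0  # s
    localization_noise_bp: float = 60.0  # per-frame Gaussian SD (~0.2 px)
    duration: float = 1800.0  # movie length, s
    pause_min_duration: float = 25.0  # resolvable-pause floor, s
    pause_margin_bp: float = 3000.0  # keep pauses clear of start/termination

    def validate(self) -> None:
        pr = (self.pause_prob_once, self.pause_prob_twice, self.completion_prob)
        if not all(0.0 <= p <= 1.0 for p in pr):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.pause_prob_twice > self.pause_prob_once:
            raise ValueError("pause_prob_twice must not exceed pause_prob_once")
        lo, hi = self.incomplete_length_range
        pos = (
            self.burst_rate_mean,
            self.pause_duration_mean,
            self.template_length,
            self.frame_interval,
            self.duration,
            lo,
            hi,
        )
        if not all(v > 0 for v in pos):
            raise ValueError("rates, durations and lengths must be positive")
        if self.burst_rate_sd < 0 or self.localization_noise_bp < 0:
            raise ValueError("standard deviations must be non-negative")
        if lo > hi:
            raise ValueError("incomplete_length_range must be (low, high)")
        if not 0 <= self.pause_min_duration <= self.pause_duration_mean:
            raise ValueError("pause_min_duration must lie in [0, pause_duration_mean]")


@dataclass(frozen=True)
class RotationPreset:
    """Lagging-arm appearance under transverse flow.

    ``wrap_event_rate`` is the Poisson rate of compaction state
    toggles; while wrapped, the extended lagging length collapses by up
    to ``wrap_amplitude_kb`` toward a compact floor.  ``lagging_scale``
    accounts for ssDNA-binding-protein-compacted regions that are
    shorter than dsDNA at the applied force.
    """

    base_length_noise_kb: float  # per-frame SD of the lagging-length measurement
    wrap_event_rate: float = 0.0  # events/s
    wrap_amplitude_kb: float = 0.0  # collapse per wrap state
    unwrap_on_pause: bool = True
    lagging_scale: float = 0.8
    compact_floor_kb: float = 0.9  # ~0.3 um at 0.34 nm/bp
    strand_noise_kb: float = 0.3  # parental / leading measurement SD

    def validate(self) -> None:
        if min(
            self.base_length_noise_kb,
            self.wrap_event_rate,
            self.wrap_amplitude_kb,
            self.compact_floor_kb,
            self.strand_noise_kb,
        ) < 0:
            raise ValueError("noise levels, rates and amplitudes must be >= 0")
        if not 0 < self.lagging_scale <= 1:
            raise ValueError("lagging_scale must lie in (0, 1]")


@dataclass(frozen=True)
class PhotophysicsPreset:
    """Fluorophore photophysics and replisome labelling statistics."""

    step_intensity_mean: float = 1000.0  # a.u. per fluorophore
    step_intensity_sd: float = 100.0
    bleach_rate: float = 0.02  # 1/s per fluorophore
    background_mean: float = 200.0  # a.u.
    noise_sd: float = 60.0  # a.u., per frame
    true_count_mean: float = 3.8  # fluorophores per replisome
    true_count_sd: float = 0.87  # between molecules

    def validate(self) -> None:
        if self.step_intensity_mean <= 0:
            raise ValueError("step_intensity_mean must be positive")
        if self.true_count_mean <= 0:
            raise ValueError("true_count_mean must be positive")
        if min(self.step_intensity_sd, self.bleach_rate, self.noise_sd, self.true_count_sd) < 0:
            raise ValueError("rates and SDs must be non-negative")


# Between-molecule rate SDs follow the SEM-matching rule: SD = SEM * sqrt(n)
# at the cohort sizes of the two conditions (3*sqrt(186) ~ 41; 5*sqrt(79) ~ 44).
KINETIC_PRESETS: dict[str, KineticPreset] = {
    "unconstrained": KineticPreset(
        burst_rate_mean=99.0,
        burst_rate_sd=41.0,
        pause_prob_once=0.12,
        pause_prob_twice=0.01,
        pause_duration_mean=30.0,
        completion_prob=0.75,
        incomplete_length_range=(8.0, 27.0),
    ),
    "constrained": KineticPreset(
        burst_rate_mean=96.0,
        burst_rate_sd=44.0,
        pause_prob_once=0.18,
        pause_prob_twice=0.04,
        pause_duration_mean=30.0,
        completion_prob=0.57,
        incomplete_length_range=(11.2, 27.0),
    ),
}

# base_length_noise 0.95 kb: variance of first differences of white noise is
# 2 sigma^2 ~ 1.8 kb^2.  The constrained wrap parameters are qualitative.
ROTATION_PRESETS: dict[str, RotationPreset] = {
    "unconstrained": RotationPreset(base_length_noise_kb=0.95),
    "constrained": RotationPreset(
        base_length_noise_kb=0.95, wrap_event_rate=0.01, wrap_amplitude_kb=10.0
    ),
}

# true_count SDs follow the same SEM-matching rule (0.1*sqrt(75); 0.2*sqrt(56)).
PHOTOPHYSICS_PRESETS: dict[str, PhotophysicsPreset] = {
    "calibration": PhotophysicsPreset(true_count_mean=1.0, true_count_sd=0.0),
    "unconstrained": PhotophysicsPreset(true_count_mean=3.8, true_count_sd=0.87),
    "constrained": PhotophysicsPreset(true_count_mean=11.4, true_count_sd=1.50),
}


@dataclass
class GroundTruth:
    """Per-molecule generative truth; traces are re-derivable from it."""

    molecules: pd.DataFrame
    clean_traces: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# kinetic path construction
# ---------------------------------------------------------------------------

def _draw_rate(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated (by resampling) to mean +/- 2 SD."""
    if sd == 0:
        return mean
    while True:
        r = rng.normal(mean, sd)
        if abs(r - mean) <= 2 * sd:
            return r


def _draw_molecule(rng: np.random.Generator, p: KineticPreset) -> dict:
    rate = _draw_rate(rng, p.burst_rate_mean, p.burst_rate_sd)
    u = rng.random()
    if u < p.pause_prob_twice:
        n_pauses = 2
    elif u < p.pause_prob_twice + p.pause_prob_once:
        n_pauses = 1
    else:
        n_pauses = 0
    completed = bool(rng.random() < p.completion_prob)
    if completed:
        termination = float(p.template_length)
    else:
        lo, hi = p.incomplete_length_range
        termination = float(rng.uniform(lo, hi) * 1000.0)
    # a pause inside ~pause_margin_bp of the start or the termination point
    # is indistinguishable from initiation/termination at this frame
    # interval, so resolvable pauses are placed clear of both ends
    margin = min(p.pause_margin_bp, termination / 3.0)
    pause_pos = np.sort(rng.uniform(margin, termination - margin, n_pauses))
    spread = p.pause_duration_mean - p.pause_min_duration
    pause_dur = p.pause_min_duration + (
        rng.exponential(spread, n_pauses) if spread > 0 else np.zeros(n_pauses)
    )
    return {
        "rate_bp_s": rate,
        "n_pauses": n_pauses,
        "completed": completed,
        "termination_bp": termination,
        "pause_positions_bp": tuple(float(v) for v in pause_pos),
        "pause_durations_s": tuple(float(v) for v in pause_dur),
    }


def _path_knots(truth: dict) -> tuple[np.ndarray, np.ndarray]:
    """(time, position) knots of the noiseless piecewise-linear path."""
    rate = truth["rate_bp_s"]
    times = [0.0]
    pos = [0.0]
    cur_t, cur_x = 0.0, 0.0
    for s, d in zip(truth["pause_positions_bp"], truth["pause_durations_s"]):
        cur_t += (s - cur_x) / rate
        times.append(cur_t)
        pos.append(s)
        cur_t += d
        times.append(cur_t)
        pos.append(s)
        cur_x = s
    cur_t += (truth["termination_bp"] - cur_x) / rate
    times.append(cur_t)
    pos.append(truth["termination_bp"])
    return np.array(times), np.array(pos)


def reconstruct_position(truth_row, t) -> np.ndarray:
    """Noiseless synthesised length (bp) at times ``t`` from a truth record.

    Accepts a row of ``GroundTruth.molecules`` (Series or dict).
    """
    truth = dict(truth_row)
    kt, kx = _path_knots(truth)
    t = np.asarray(t, dtype=float)
    return np.interp(t, kt, kx, left=0.0, right=truth["termination_bp"])


def _frame_times(duration: float, frame_interval: float) -> np.ndarray:
    n_frames = int(np.floor(duration / frame_interval)) + 1
    return np.arange(n_frames) * frame_interval


def simulate_kinetic_traces(
    preset: KineticPreset, n: int, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Position-vs-time traces of the lagging-strand product.

    Returns a tidy trace table with columns
    ``molecule_id, t_s, position_bp`` (Gaussian per-frame localization
    noise, clamped to [0, template]) and the per-molecule ground truth.
    """
    preset.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    t = _frame_times(preset.duration, preset.frame_interval)
    rows, truths = [], []
    for mid in range(n):
        truth = _draw_molecule(rng, preset)
        truth["molecule_id"] = mid
        truths.append(truth)
        clean = reconstruct_position(truth, t)
        noisy = clean + rng.normal(0.0, preset.localization_noise_bp, len(t))
        noisy = np.clip(noisy, 0.0, preset.template_length)
        rows.append(
            pd.DataFrame({"molecule_id": mid, "t_s": t, "position_bp": noisy})
        )
    traces = pd.concat(rows, ignore_index=True)
    truth_df = pd.DataFrame(truths)[
        [
            "molecule_id",
            "rate_bp_s",
            "n_pauses",
            "completed",
            "termination_bp",
            "pause_positions_bp",
            "pause_durations_s",
        ]
    ]
    return traces, GroundTruth(molecules=truth_df)


# ---------------------------------------------------------------------------
# transverse-flow strand traces
# ---------------------------------------------------------------------------

def _pause_mask(truth: dict, t: np.ndarray) -> np.ndarray:
    kt, _ = _path_knots(truth)
    mask = np.zeros(len(t), dtype=bool)
    # pause intervals are the flat spans between the paired knots
    idx = 1
    for _ in range(truth["n_pauses"]):
        start, stop = kt[idx], kt[idx + 1]
        mask |= (t >= start) & (t < stop)
        idx += 2
    return mask


def simulate_transverse_traces(
    kin: KineticPreset, rot: RotationPreset, n: int, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-frame parental / leading / lagging lengths under transverse flow.

    Ground truth obeys leading + parental = template at every frame.
    The measured lagging length is ``lagging_scale * synthesised`` with
    per-frame Gaussian noise; Poisson-timed wrap events collapse it
    toward a compact floor (fork rotation) and pauses unwrap it when
    ``unwrap_on_pause`` is set.
    """
    kin.validate()
    rot.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    t = _frame_times(kin.duration, kin.frame_interval)
    rows, clean_rows, truths = [], [], []
    for mid in range(n):
        truth = _draw_molecule(rng, kin)
        truth["molecule_id"] = mid
        synth = reconstruct_position(truth, t)
        parental = kin.template_length - synth
        leading = synth.copy()
        lagging_ext = rot.lagging_scale * synth
        # wrap/unwrap state toggles at Poisson event times
        wrapped = np.zeros(len(t), dtype=bool)
        if rot.wrap_event_rate > 0:
            n_ev = rng.poisson(rot.wrap_event_rate * kin.duration)
            ev = np.sort(rng.uniform(0.0, kin.duration, n_ev))
            state = False
            pauses = _pause_mask(truth, t) if rot.unwrap_on_pause else None
            ei = 0
            for k, tk in enumerate(t):
                while ei < n_ev and ev[ei] <= tk:
                    state = not state
                    ei += 1
                if pauses is not None and pauses[k]:
                    state = False
                wrapped[k] = state
        floor = rot.compact_floor_kb * 1000.0
        collapse = np.where(
            wrapped,
            np.minimum(rot.wrap_amplitude_kb * 1000.0, np.maximum(lagging_ext - floor, 0.0)),
            0.0,
        )
        lagging_clean = lagging_ext - collapse
        noise_lag = rng.normal(0.0, rot.base_length_noise_kb * 1000.0, len(t))
        noise_par = rng.normal(0.0, rot.strand_noise_kb * 1000.0, len(t))
        noise_led = rng.normal(0.0, rot.strand_noise_kb * 1000.0, len(t))
        frame = pd.DataFrame(
            {
                "molecule_id": mid,
                "t_s": t,
                "parental_bp": np.maximum(parental + noise_par, 0.0),
                "leading_bp": np.maximum(leading + noise_led, 0.0),
                "lagging_bp": np.maximum(lagging_clean + noise_lag, 0.0),
            }
        )
        rows.append(frame)
        clean_rows.append(
            pd.DataFrame(
                {
                    "molecule_id": mid,
                    "t_s": t,
                    "parental_bp": parental,
                    "leading_bp": leading,
                    "lagging_bp": lagging_clean,
                }
            )
        )
        truths.append(truth)
    traces = pd.concat(rows, ignore_index=True)
    clean = pd.concat(clean_rows, ignore_index=True)
    truth_df = pd.DataFrame(truths)[
        [
            "molecule_id",
            "rate_bp_s",
            "n_pauses",
            "completed",
            "termination_bp",
            "pause_positions_bp",
            "pause_durations_s",
        ]
    ]
    return traces, GroundTruth(molecules=truth_df, clean_traces=clean)


# ---------------------------------------------------------------------------
# photobleaching / stoichiometry
# ---------------------------------------------------------------------------

def _draw_count(rng: np.random.Generator, phys: PhotophysicsPreset) -> int:
    if phys.true_count_sd == 0:
        return int(round(phys.true_count_mean))
    return max(0, int(round(rng.normal(phys.true_count_mean, phys.true_count_sd))))


def simulate_bleach_traces(
    phys: PhotophysicsPreset,
    n: int,
    seed: int,
    duration: float = 300.0,
    frame_interval: float = 1.0,
    count: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Stepwise photobleaching intensity traces.

    Each trace starts at ``count * step + background`` and loses one
    fluorophore at exponential times (rate ``bleach_rate``), with
    per-frame Gaussian noise.  ``count`` overrides the per-molecule
    draw (e.g. 1 for single-fluorophore calibration).
    Returns ``(traces, truth)`` with trace columns
    ``molecule_id, t_s, intensity_au``.
    """
    phys.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    t = _frame_times(duration, frame_interval)
    rows, truths = [], []
    for mid in range(n):
        c = _draw_count(rng, phys) if count is None else int(count)
        steps = rng.normal(phys.step_intensity_mean, phys.step_intensity_sd, c)
        if phys.bleach_rate > 0:
            bleach_t = rng.exponential(1.0 / phys.bleach_rate, c)
        else:
            bleach_t = np.full(c, np.inf)
        alive = (t[:, None] < bleach_t[None, :]) if c else np.zeros((len(t), 0), bool)
        clean = phys.background_mean + alive @ steps if c else np.full(
            len(t), phys.background_mean
        )
        noisy = clean + rng.normal(0.0, phys.noise_sd, len(t))
        rows.append(pd.DataFrame({"molecule_id": mid, "t_s": t, "intensity_au": noisy}))
        truths.append(
            {
                "molecule_id": mid,
                "true_count": c,
                "step_sizes_au": tuple(float(s) for s in steps),
                "bleach_times_s": tuple(float(b) for b in np.sort(bleach_t)),
            }
        )
    return pd.concat(rows, ignore_index=True), GroundTruth(pd.DataFrame(truths))


def simulate_replisome_intensities(
    phys: PhotophysicsPreset, n: int, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Background-subtracted integrated replisome intensities.

    One record per molecule: the summed brightness of its labelled
    polymerases plus integration noise, as produced by annulus
    background subtraction on a spot image.
    """
    phys.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.array([_draw_count(rng, phys) for _ in range(n)])
    intensities = np.array(
        [
            float(np.sum(rng.normal(phys.step_intensity_mean, phys.step_intensity_sd, c)))
            + rng.normal(0.0, phys.noise_sd)
            for c in counts
        ]
    )
    df = pd.DataFrame(
        {"molecule_id": np.arange(n), "intensity_au": intensities}
    )
    truth = pd.DataFrame({"molecule_id": np.arange(n), "true_count": counts})
    return df, GroundTruth(truth)


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovieGeometry:
    """Field-of-view layout for rendered movies (0-based pixel coordinates)."""

    shape: tuple[int, int] = (64, 128)  # (ny, nx)
    dna_start: tuple[float, float] = (20.0, 32.0)  # (x, y): fork end
    dna_end: tuple[float, float] = (110.0, 32.0)
    pixel_size_nm: float = 100.0
    psf_sigma_px: float = 1.3
    fiducials: tuple[tuple[float, float], ...] = ()
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px/frame

    def validate(self) -> None:
        ny, nx = self.shape
        for x, y in (self.dna_start, self.dna_end, *self.fiducials):
            if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
                raise ValueError("geometry outside the field of view")
        if self.pixel_size_nm <= 0 or self.psf_sigma_px <= 0:
            raise ValueError("pixel scale and PSF width must be positive")


@dataclass(frozen=True)
class RenderSettings:
    """Photon budget and noise of a rendered movie."""

    photons_per_bp: float = 0.05  # blob brightness grows with product size
    blob_base_photons: float = 200.0
    dna_line_photons: float = 30.0  # per axis pixel
    fiducial_photons: float = 2000.0
    background: float = 100.0
    poisson_noise: bool = True
    read_noise_sd: float = 2.0


def _add_gaussian(img: np.ndarray, x0: float, y0: float, photons: float, sigma: float):
    """Accumulate an integrated-photon 2-D Gaussian spot onto ``img``."""
    ny, nx = img.shape
    r = int(np.ceil(5 * sigma))
    xs = np.arange(max(0, int(x0) - r), min(nx, int(x0) + r + 1))
    ys = np.arange(max(0, int(y0) - r), min(ny, int(y0) + r + 1))
    if xs.size == 0 or ys.size == 0:
        return
    gx = np.exp(-((xs - x0) ** 2) / (2 * sigma**2))
    gy = np.exp(-((ys - y0) ** 2) / (2 * sigma**2))
    img[np.ix_(ys, xs)] += photons / (2 * np.pi * sigma**2) * np.outer(gy, gx)


def render_movie(
    traces: pd.DataFrame,
    geometry: MovieGeometry,
    settings: RenderSettings = RenderSettings(),
    seed: int = 0,
    template_bp: int = 27_000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render position traces onto a TIRF-style image stack.

    ``traces`` must carry ``t_s`` and ``position_bp`` for a single
    molecule (registered to the DNA axis running from ``dna_start``
    toward ``dna_end``).  Returns ``(stack, truth)`` where ``stack`` is
    a uint16 (t, y, x) array with a stained-DNA line, a diffraction-
    limited blob whose brightness grows with product size, immobile
    fiducials, optional linear stage drift, and Poisson + Gaussian
    noise; ``truth`` lists the subpixel blob and fiducial centres.
    """
    geometry.validate()
    rng = np.random.default_rng(seed)
    ny, nx = geometry.shape
    x0, y0 = geometry.dna_start
    x1, y1 = geometry.dna_end
    axis_len = float(np.hypot(x1 - x0, y1 - y0))
    ux, uy = (x1 - x0) / axis_len, (y1 - y0) / axis_len
    t_vals = np.asarray(traces["t_s"], dtype=float)
    pos_bp = np.asarray(traces["position_bp"], dtype=float)
    n_frames = len(t_vals)
    stack = np.empty((n_frames, ny, nx), dtype=np.uint16)
    truth_rows = []
    # static stained-DNA line profile
    base = np.full((ny, nx), float(settings.background))
    n_axis = int(np.ceil(axis_len)) + 1
    for s in np.linspace(0.0, axis_len, n_axis):
        _add_gaussian(
            base, x0 + ux * s, y0 + uy * s, settings.dna_line_photons, geometry.psf_sigma_px
        )
    for f in range(n_frames):
        dx = geometry.drift_per_frame[0] * f
        dy = geometry.drift_per_frame[1] * f
        img = base.copy() if (dx == 0 and dy == 0) else np.full(
            (ny, nx), float(settings.background)
        )
        if not (dx == 0 and dy == 0):
            for s in np.linspace(0.0, axis_len, n_axis):
                _add_gaussian(
                    img,
                    x0 + ux * s + dx,
                    y0 + uy * s + dy,
                    settings.dna_line_photons,
                    geometry.psf_sigma_px,
                )
        s_px = pos_bp[f] / template_bp * axis_len
        bx, by = x0 + ux * s_px + dx, y0 + uy * s_px + dy
        photons = settings.blob_base_photons + settings.photons_per_bp * pos_bp[f]
        if photons > 0:
            _add_gaussian(img, bx, by, photons, geometry.psf_sigma_px)
        for fx, fy in geometry.fiducials:
            _add_gaussian(
                img, fx + dx, fy + dy, settings.fiducial_photons, geometry.psf_sigma_px
            )
        if settings.poisson_noise:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        if settings.read_noise_sd > 0:
            img = img + rng.normal(0.0, settings.read_noise_sd, img.shape)
        stack[f] = np.clip(np.rint(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        truth_rows.append(
            {
                "frame": f,
                "t_s": t_vals[f],
                "blob_x_px": bx,
                "blob_y_px": by,
                "position_bp": pos_bp[f],
                "drift_x_px": dx,
                "drift_y_px": dy,
            }
        )
    return stack, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# photo-nicking survival
# ---------------------------------------------------------------------------

def simulate_nicking_movie(
    half_life: float,
    n_molecules: int,
    seed: int,
    duration: float = 1200.0,
    frame_interval: float = 5.0,
    area_small: float = 5.0,
    area_large: float = 20.0,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Area-vs-time traces of supercoiled molecules under illumination.

    Each molecule stays compact (plectonemic, small area) until an
    exponential nick time with rate ln2 / half_life, after which its
    apparent area steps up as the plectonemes relax.  ``half_life`` may
    be ``numpy.inf`` (no nicking).  Truth records the drawn nick time
    even when it falls beyond the movie.
    """
    if not half_life > 0:
        raise ValueError("half_life must be positive")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    t = _frame_times(duration, frame_interval)
    rows, truths = [], []
    for mid in range(n_molecules):
        if np.isinf(half_life):
            nick = np.inf
        else:
            nick = float(rng.exponential(half_life / np.log(2.0)))
        area = np.where(t < nick, area_small, area_large) + (
            rng.normal(0.0, noise_sd, len(t)) if noise_sd > 0 else 0.0
        )
        rows.append(pd.DataFrame({"molecule_id": mid, "t_s": t, "area_px2": area}))
        truths.append({"molecule_id": mid, "nick_time_s": nick})
    return pd.concat(rows, ignore_index=True), GroundTruth(pd.DataFrame(truths))
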