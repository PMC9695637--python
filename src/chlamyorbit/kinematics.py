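"""Per-cell revolution kinematics: radius R, angular velocity ω, beat frequency.

A monoflagellate cell whose single flagellum keeps beating drives its centre
along a circle; the measurable kinematics of that orbit are the revolution
radius ``R``, the angular velocity ``ω`` and the rotation direction, with
the flagellar beat visible as a small oscillation of the orbital radius.

The estimators:

* the orbit circle is fitted algebraically (Kåsa least squares, closed
  form) and refined by geometric least squares (minimising radial
  residuals), which removes the small-arc bias of the algebraic fit;
* ``ω`` comes from a linear regression of the unwrapped polar angle about
  the fitted centre against time — this uses every sample and needs no
  frequency initialisation; its sign gives the rotation direction
  (``ccw`` = increasing ``atan2(y-cy, x-cx)``);
* the beat frequency is the dominant periodogram peak of the radial
  residual ``|p(t) - c| - R``, searched above twice the revolution
  frequency so the orbit fundamental (and fit-error leakage at it) cannot
  be mistaken for the beat.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares
from scipy.signal import periodogram

from .tracks import Track

__all__ = [
    "CellKinematics",
    "PopulationSummary",
    "EstimationError",
    "fit_circle",
    "estimate_revolution",
    "estimate_beat_frequency",
    "classify_motion",
    "summarize_population",
    "count_motile",
    "analyze_tracks",
]

MIN_TRACK_SAMPLES = 8

# motion-classification defaults (reported alongside results by the pipeline)
NET_DISP_THRESH_UM = 2.0      # smoothed path length below this => immotile
CIRCULARITY_THRESH = 0.35     # fit_residual / R below this => revolving
SMOOTH_WINDOW_S = 0.02        # boxcar scale for the noise-robust path length
# Beat-peak acceptance: peak power must exceed this multiple of the median
# band power. For white noise the band maximum is ~ln(m)/ln(2) ≈ 8-12 times
# the median over the few hundred bins of a half-second record, so 30 keeps
# the false-alarm rate negligible while a real beat peak (amplitude a few
# times the localisation noise, coherent over the record) sits orders of
# magnitude above the median.
BEAT_PROMINENCE = 30.0


class EstimationError(ValueError):
    """Raised when a track does not support the requested estimate."""

    def __init__(self, track_id: int, message: str):
        super().__init__(f"track {track_id}: {message}")
        self.track_id = track_id


@dataclasses.dataclass
class CellKinematics:
    """Per-cell orbit estimates. ``omega`` is the magnitude; see ``direction``."""

    track_id: int
    R: float                      # μm
    omega: float                  # rad/s, >= 0
    direction: str                # "ccw" or "cw"
    center: tuple[float, float]   # μm
    fit_residual: float           # μm, RMS radial deviation
    beat_freq: float | None = None  # Hz, None if no significant peak

    @property
    def omega_signed(self) -> float:
        return self.omega if self.direction == "ccw" else -self.omega


@dataclasses.dataclass
class PopulationSummary:
    """Arithmetic-mean kinematics over the analysed cells."""

    n_cells: int
    mean_R: float        # μm
    mean_omega: float    # rad/s
    cells: list[CellKinematics]


def fit_circle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Fit a circle to points: Kåsa algebraic start, geometric refinement.

    Returns ``(cx, cy, R)``. Raises ``ValueError`` on collinear input
    (the algebraic system is rank deficient).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("points are collinear; no circle fit")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    if r2 <= 0:
        raise ValueError("degenerate algebraic circle fit")
    r0 = float(np.sqrt(r2))

    def radial_residual(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    fit = least_squares(radial_residual, x0=[cx, cy, r0], method="lm")
    cx, cy, r = fit.x
    if r <= 0:
        raise ValueError("geometric refinement collapsed to non-positive radius")
    return float(cx), float(cy), float(r)


def estimate_revolution(track: Track,
                        min_revolutions: float = 1.0) -> CellKinematics:
    """Estimate orbit centre, R, ω and direction from one track.

    Requires at least ``MIN_TRACK_SAMPLES`` samples spanning at least
    ``min_revolutions`` full turns about the fitted centre.
    """
    if track.n_samples < MIN_TRACK_SAMPLES:
        raise EstimationError(track.track_id,
                              f"needs >= {MIN_TRACK_SAMPLES} samples, has "
                              f"{track.n_samples}")
    try:
        cx, cy, R = fit_circle(track.x, track.y)
    except ValueError as err:
        raise EstimationError(track.track_id, str(err)) from err

    phase = np.unwrap(np.arctan2(track.y - cy, track.x - cx))
    span = abs(phase[-1] - phase[0])
    if span < min_revolutions * 2 * np.pi:
        raise EstimationError(
            track.track_id,
            f"spans {span / (2 * np.pi):.2f} revolutions "
            f"(< {min_revolutions:g} required)")
    slope, _ = np.polyfit(track.t, phase, 1)
    radial = np.hypot(track.x - cx, track.y - cy)
    residual = float(np.sqrt(np.mean((radial - R) ** 2)))
    return CellKinematics(
        track_id=track.track_id,
        R=R,
        omega=abs(float(slope)),
        direction="ccw" if slope > 0 else "cw",
        center=(cx, cy),
        fit_residual=residual,
    )


def estimate_beat_frequency(track: Track, kin: CellKinematics,
                            prominence: float = BEAT_PROMINENCE,
                            min_freq_factor: float = 2.0) -> float | None:
    """Flagellar beat frequency from the radial residual's periodogram.

    The residual ``|p(t) - center| - R`` oscillates at the beat frequency.
    The search band starts at ``min_freq_factor`` times the revolution
    frequency ``ω/2π`` so the orbit fundamental is excluded. Returns None
    when the dominant peak is not at least ``prominence`` times the median
    band power (no detectable beat), raises on an undersampled track.
    """
    dt = np.diff(track.t)
    fs = 1.0 / float(np.mean(dt))
    residual = np.hypot(track.x - kin.center[0],
                        track.y - kin.center[1]) - kin.R
    if np.sqrt(np.mean(residual ** 2)) < 1e-9:
        return None
    f_rev = kin.omega / (2 * np.pi)
    f_min = min_freq_factor * f_rev
    if fs / 2 <= f_min:
        raise EstimationError(
            track.track_id,
            f"undersampled: Nyquist limit {fs / 2:.1f} Hz is below the "
            f"{f_min:.1f} Hz search floor")
    freqs, power = periodogram(residual, fs=fs, detrend="constant")
    band = freqs > f_min
    fb, pb = freqs[band], power[band]
    peak = int(np.argmax(pb))
    med = float(np.median(pb))
    if med > 0 and pb[peak] < prominence * med:
        return None
    if pb[peak] <= 0:
        return None
    return float(fb[peak])


def _smoothed_path_length(track: Track, window_s: float) -> float:
    """Path length (μm) of the boxcar-smoothed, decimated trajectory.

    Raw path length integrates centroid noise (~σ√2 per frame), so it is
    computed at a coarser time scale: positions are averaged over
    ``window_s`` and sampled every ``window_s``, which suppresses noise
    while genuine swimming or orbiting (≥ ~15 μm/s) still accumulates.
    """
    dt = float(np.mean(np.diff(track.t))) if track.n_samples > 1 else 0.0
    if dt <= 0:
        return 0.0
    w = max(1, int(round(window_s / dt)))
    xs = uniform_filter1d(track.x, w, mode="nearest")
    ys = uniform_filter1d(track.y, w, mode="nearest")
    idx = np.arange(0, track.n_samples, w)
    if idx[-1] != track.n_samples - 1:
        idx = np.append(idx, track.n_samples - 1)
    return float(np.sum(np.hypot(np.diff(xs[idx]), np.diff(ys[idx]))))


def classify_motion(track: Track,
                    net_disp_thresh: float = NET_DISP_THRESH_UM,
                    circularity_thresh: float = CIRCULARITY_THRESH,
                    smooth_window_s: float = SMOOTH_WINDOW_S) -> str:
    """Classify a track as ``immotile``, ``revolving`` or ``translating``.

    Immotile: smoothed path length over the track below ``net_disp_thresh``
    (degenerate/short tracks included). Revolving: the orbit fit converges
    over at least one revolution with relative RMS radial residual below
    ``circularity_thresh``. Anything else translates.
    """
    if track.n_samples < MIN_TRACK_SAMPLES:
        return "immotile"
    if _smoothed_path_length(track, smooth_window_s) < net_disp_thresh:
        return "immotile"
    try:
        kin = estimate_revolution(track)
    except EstimationError:
        return "translating"
    if kin.fit_residual / kin.R < circularity_thresh:
        return "revolving"
    return "translating"


def summarize_population(kins: Sequence[CellKinematics]) -> PopulationSummary:
    """Arithmetic means of R and ω over the per-cell estimates."""
    if len(kins) == 0:
        raise ValueError("cannot summarize an empty population")
    return PopulationSummary(
        n_cells=len(kins),
        mean_R=float(np.mean([k.R for k in kins])),
        mean_omega=float(np.mean([k.omega for k in kins])),
        cells=list(kins),
    )


def count_motile(tracks: Iterable[Track], window: float | None = None,
                 **classify_kwargs) -> int:
    """Number of tracks not classified immotile (clipped to ``window`` s)."""
    n = 0
    for tr in tracks:
        if window is not None:
            try:
                tr = tr.clip(tr.t[0], tr.t[0] + window)
            except ValueError:
                continue
        if classify_motion(tr, **classify_kwargs) != "immotile":
            n += 1
    return n


def analyze_tracks(tracks: Sequence[Track],
                   net_disp_thresh: float = NET_DISP_THRESH_UM,
                   circularity_thresh: float = CIRCULARITY_THRESH,
                   beat_prominence: float = BEAT_PROMINENCE,
                   ) -> tuple[list[CellKinematics], dict[int, str]]:
    """Classify every track and estimate kinematics for the revolving ones.

    Returns the per-cell kinematics (beat frequency attempted for each) and
    a ``{track_id: class}`` map covering all input tracks.
    """
    kins: list[CellKinematics] = []
    classes: dict[int, str] = {}
    for tr in tracks:
        cls = classify_motion(tr, net_disp_thresh=net_disp_thresh,
                              circularity_thresh=circularity_thresh)
        classes[tr.track_id] = cls
        if cls != "revolving":
            continue
        kin = estimate_revolution(tr)
        try:
            kin.beat_freq = estimate_beat_frequency(tr, kin,
                                                    prominence=beat_prominence)
        except EstimationError:
            kin.beat_freq = None
        kins.append(kin)
    return kins, classes
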