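"""Synthetic trajectories and microscopy-like image stacks.

The generators emulate the three motion classes seen in microwell recordings
of *Chlamydomonas reinhardtii*:

* **orbiting monoflagellates** — the cell centre travels on a circle of
  radius ``R`` (~0.7–1.9 μm) at angular velocity ``omega`` (~9–35 rad/s),
  with the flagellar beat (~49 Hz) superimposed as a small radial
  oscillation of the orbit radius;
* **translating biflagellates** — straight swimming at ~100–200 μm/s;
* **immotile cells** — stationary up to centroid-localisation noise.

Localisation noise is modelled as i.i.d. isotropic Gaussian displacement of
each centroid sample, the standard model for centroid estimation error.
:func:`render_stack` draws the cells as blurred disks into an image stack so
the segmentation/tracking stages can be exercised end-to-end against a
ground-truth table.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .tracks import Track

__all__ = [
    "OrbitParams",
    "TranslatorParams",
    "RenderParams",
    "generate_orbit_track",
    "generate_translator_track",
    "render_stack",
    "write_stack",
    "read_stack",
]


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


def _check_nonnegative(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclasses.dataclass(frozen=True)
class OrbitParams:
    """Parameters of an orbiting (revolving) monoflagellate trajectory.

    The trajectory is ``center + (R + beat_amp·sin(2π·beat_freq·t)) ·
    (cos(ωt + phase0), sin(ωt + phase0)) + noise``. ``omega`` is signed:
    positive means the polar angle about the centre increases with time.
    Defaults are the population-mean kinematics of the revolving cells
    (R = 1.16 μm, ω = 22.75 rad/s) with a 49 Hz beat, sampled at 1 kHz.
    """

    center: tuple[float, float] = (0.0, 0.0)  # μm
    R: float = 1.16                            # μm
    omega: float = 22.75                       # rad/s, signed
    phase0: float = 0.0                        # rad
    beat_freq: float = 49.0                    # Hz
    beat_amp: float = 0.0                      # μm
    noise_sigma: float = 0.0                   # μm
    duration: float = 1.0                      # s
    frame_interval: float = 1e-3               # s

    def __post_init__(self) -> None:
        _check_positive("R", self.R)
        _check_positive("duration", self.duration)
        _check_positive("frame_interval", self.frame_interval)
        _check_nonnegative("beat_amp", self.beat_amp)
        _check_nonnegative("noise_sigma", self.noise_sigma)
        if self.beat_amp > 0 and not abs(self.beat_freq) < 0.5 / self.frame_interval:
            raise ValueError(
                "beat_freq exceeds the Nyquist limit "
                f"{0.5 / self.frame_interval:g} Hz for frame_interval "
                f"{self.frame_interval:g} s"
            )


@dataclasses.dataclass(frozen=True)
class TranslatorParams:
    """Parameters of a straight-swimming (biflagellate) trajectory."""

    start: tuple[float, float] = (0.0, 0.0)  # μm
    speed: float = 150.0                      # μm/s
    heading: float = 0.0                      # rad
    noise_sigma: float = 0.0                  # μm
    duration: float = 1.0                     # s
    frame_interval: float = 1e-3              # s

    def __post_init__(self) -> None:
        _check_nonnegative("speed", self.speed)
        _check_nonnegative("noise_sigma", self.noise_sigma)
        _check_positive("duration", self.duration)
        _check_positive("frame_interval", self.frame_interval)


@dataclasses.dataclass(frozen=True)
class RenderParams:
    """Rendering geometry for synthetic phase-contrast-like frames.

    ``image_size`` is (height, width) in pixels. Cells are drawn as disks of
    ``cell_radius`` (μm); with ``antialias`` the rim pixels carry fractional
    coverage so the rendered centroid tracks the true position to well below
    a pixel, without it the disk has a hard edge (pixel centre inside the
    circle). ``blur_sigma`` applies an optional Gaussian point-spread blur.
    """

    image_size: tuple[int, int] = (256, 256)  # (H, W) px
    pixel_size: float = 0.065                  # μm/px
    cell_radius: float = 5.0                   # μm
    foreground: float = 200.0                  # grayscale level of cells
    background: float = 40.0                   # grayscale level
    blur_sigma: float = 0.0                    # px
    antialias: bool = True

    def __post_init__(self) -> None:
        _check_positive("pixel_size", self.pixel_size)
        _check_positive("cell_radius", self.cell_radius)
        _check_nonnegative("blur_sigma", self.blur_sigma)
        if len(self.image_size) != 2 or min(self.image_size) < 4:
            raise ValueError(f"image_size must be (H, W) >= 4 px, got {self.image_size!r}")


def _time_base(duration: float, frame_interval: float) -> np.ndarray:
    n = math.floor(duration / frame_interval) + 1
    return np.arange(n) * frame_interval


def generate_orbit_track(params: OrbitParams, seed: int,
                         track_id: int = 0) -> Track:
    """Generate one orbiting-cell track; deterministic for a fixed seed."""
    t = _time_base(params.duration, params.frame_interval)
    radius = params.R + params.beat_amp * np.sin(2 * np.pi * params.beat_freq * t)
    angle = params.omega * t + params.phase0
    x = params.center[0] + radius * np.cos(angle)
    y = params.center[1] + radius * np.sin(angle)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, params.noise_sigma, size=(t.size, 2))
        x = x + noise[:, 0]
        y = y + noise[:, 1]
    return Track(track_id, np.arange(t.size), t, x, y)


def generate_translator_track(params: TranslatorParams, seed: int,
                              track_id: int = 0) -> Track:
    """Generate one straight-swimming track; deterministic for a fixed seed."""
    t = _time_base(params.duration, params.frame_interval)
    x = params.start[0] + params.speed * np.cos(params.heading) * t
    y = params.start[1] + params.speed * np.sin(params.heading) * t
    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, params.noise_sigma, size=(t.size, 2))
        x = x + noise[:, 0]
        y = y + noise[:, 1]
    return Track(track_id, np.arange(t.size), t, x, y)


def _draw_disk(coverage: np.ndarray, cx: float, cy: float, r_px: float,
               antialias: bool) -> None:
    h, w = coverage.shape
    x0 = max(0, int(math.floor(cx - r_px - 1)))
    x1 = min(w, int(math.ceil(cx + r_px + 2)))
    y0 = max(0, int(math.floor(cy - r_px - 1)))
    y1 = min(h, int(math.ceil(cy + r_px + 2)))
    yy, xx = np.ogrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    if antialias:
        cov = np.clip(r_px + 0.5 - d, 0.0, 1.0)
    else:
        cov = (d <= r_px).astype(float)
    np.maximum(coverage[y0:y1, x0:x1], cov, out=coverage[y0:y1, x0:x1])


def render_stack(tracks: Sequence[Track],
                 params: RenderParams) -> tuple[np.ndarray, pd.DataFrame]:
    """Render tracks into a uint8 image stack plus a ground-truth table.

    Returns
    -------
    stack : (n_frames, H, W) uint8 array
        One frame per time point from 0 to the largest frame index present.
    truth : DataFrame
        Columns ``cell, frame, x_px, y_px, overlapping``; continuous pixel
        coordinates of the true centroid (0-based, x right, y down, the
        centre of pixel (0, 0) is coordinate (0, 0)). ``overlapping`` flags
        frames on which another cell centre is closer than one cell
        diameter.

    Raises
    ------
    ValueError
        If any cell disk would extend beyond the frame.
    """
    h, w = params.image_size
    r_px = params.cell_radius / params.pixel_size
    n_frames = 1 + max((int(tr.frame.max()) for tr in tracks), default=0)

    # positions per frame: {frame: [(cell, x_px, y_px)]}
    per_frame: dict[int, list[tuple[int, float, float]]] = {}
    for tr in tracks:
        xp = tr.x / params.pixel_size
        yp = tr.y / params.pixel_size
        if (xp.min() < r_px or xp.max() > w - 1 - r_px
                or yp.min() < r_px or yp.max() > h - 1 - r_px):
            raise ValueError(
                f"track {tr.track_id}: cell disk leaves the "
                f"{h}x{w} px frame (radius {r_px:.1f} px)"
            )
        for f, x, y in zip(tr.frame, xp, yp):
            per_frame.setdefault(int(f), []).append((tr.track_id, x, y))

    if params.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

    stack = np.empty((n_frames, h, w), dtype=np.uint8)
    rows: list[tuple[int, int, float, float, bool]] = []
    for f in range(n_frames):
        coverage = np.zeros((h, w), dtype=float)
        cells = per_frame.get(f, [])
        for cell, x, y in cells:
            _draw_disk(coverage, x, y, r_px, params.antialias)
        img = params.background + (params.foreground - params.background) * coverage
        if params.blur_sigma > 0:
            img = gaussian_filter(img, params.blur_sigma)
        stack[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        pos = np.array([(x, y) for _, x, y in cells]) if cells else np.empty((0, 2))
        for i, (cell, x, y) in enumerate(cells):
            if len(cells) > 1:
                d = np.hypot(pos[:, 0] - x, pos[:, 1] - y)
                d[i] = np.inf
                overlapping = bool(d.min() < 2 * r_px)
            else:
                overlapping = False
            rows.append((cell, f, x, y, overlapping))
    truth = pd.DataFrame(rows, columns=["cell", "frame", "x_px", "y_px",
                                        "overlapping"])
    return stack, truth


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a stack as multi-page TIFF (.tif/.tiff) or a PNG sequence.

    A path without a TIFF suffix is treated as a directory that receives
    zero-padded ``frame_00000.png`` files.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, stack, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(stack):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a stack written by :func:`write_stack` (TIFF or PNG directory)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise FileNotFoundError(f"no frame_*.png files in {path}")
        return np.stack([iio.imread(f) for f in files])
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr
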