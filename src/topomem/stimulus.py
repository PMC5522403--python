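"""Sweeping-bar contrast apertures on a visual-field grid.

Retinotopic mapping stimuli are bars of fixed width that sweep across the
visual field in cardinal and diagonal directions.  For receptive-field
modelling only the binary footprint of the bar matters, so a mapping run is
represented as an :class:`ApertureMovie`: one binary mask per fMRI volume
(TR) on a square grid of visual-field positions in degrees of visual angle
(x positive rightward, y positive upward, origin at fixation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FieldGrid",
    "BarSweep",
    "ApertureMovie",
    "DIRECTIONS",
    "make_grid",
    "render_sweep",
    "blank_movie",
    "concat_movies",
    "default_mapping_movie",
    "save_movie",
    "load_movie",
    "export_frames_png",
]

#: travel direction unit vectors for the eight standard sweep directions
DIRECTIONS: dict[str, tuple[float, float]] = {
    "left-right": (1.0, 0.0),
    "right-left": (-1.0, 0.0),
    "bottom-top": (0.0, 1.0),
    "top-bottom": (0.0, -1.0),
    "bl-tr": (math.sqrt(0.5), math.sqrt(0.5)),
    "tr-bl": (-math.sqrt(0.5), -math.sqrt(0.5)),
    "br-tl": (-math.sqrt(0.5), math.sqrt(0.5)),
    "tl-br": (math.sqrt(0.5), -math.sqrt(0.5)),
}


@dataclass(frozen=True)
class FieldGrid:
    """Square sampling grid of the modeled visual field.

    Pixel centers span ``(-extent_deg, +extent_deg)`` symmetrically on both
    axes with spacing ``2 * extent_deg / n_pix``.
    """

    extent_deg: float
    n_pix: int

    def __post_init__(self) -> None:
        if self.extent_deg <= 0:
            raise ValueError(f"extent_deg must be positive, got {self.extent_deg}")
        if self.n_pix < 16:
            raise ValueError(f"n_pix must be at least 16, got {self.n_pix}")

    @property
    def pixel_spacing(self) -> float:
        return 2.0 * self.extent_deg / self.n_pix

    @property
    def pixel_area(self) -> float:
        return self.pixel_spacing ** 2

    @property
    def coords(self) -> np.ndarray:
        """1-D pixel-center coordinates (degrees), identical for both axes."""
        d = self.pixel_spacing
        return -self.extent_deg + (np.arange(self.n_pix) + 0.5) * d

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) pixel-center coordinates; row index increases with y."""
        c = self.coords
        return np.meshgrid(c, c)


@dataclass(frozen=True)
class BarSweep:
    """One pass of a bar of fixed width across the field.

    The bar is a strip of width ``width_deg`` perpendicular to the travel
    direction; its center takes ``n_steps`` equally spaced positions
    spanning the grid's projection onto the travel axis, each held for
    ``step_duration_s`` seconds.
    """

    width_deg: float
    direction: str
    n_steps: int = 16
    step_duration_s: float = 2.0

    def __post_init__(self) -> None:
        if self.width_deg <= 0:
            raise ValueError(f"width_deg must be positive, got {self.width_deg}")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"unknown direction {self.direction!r}; valid: {sorted(DIRECTIONS)}"
            )
        if self.n_steps < 2:
            raise ValueError(f"n_steps must be >= 2, got {self.n_steps}")
        if self.step_duration_s <= 0:
            raise ValueError("step_duration_s must be positive")


@dataclass
class ApertureMovie:
    """Time-ordered binary stimulus masks, one frame per TR."""

    grid: FieldGrid
    frames: np.ndarray  # (T, n_pix, n_pix) in {0, 1}
    tr_s: float
    width_deg: float | None = None  # bar width label, if homogeneous

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.uint8)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, n, n) array with T >= 1")
        if self.frames.shape[1:] != (self.grid.n_pix, self.grid.n_pix):
            raise ValueError("frame shape does not match grid")
        if not np.isin(self.frames, (0, 1)).all():
            raise ValueError("frames must be binary")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


def make_grid(extent_deg: float, n_pix: int) -> FieldGrid:
    """Build a square visual-field grid (see :class:`FieldGrid`)."""
    return FieldGrid(float(extent_deg), int(n_pix))


def _projection_span(grid: FieldGrid, direction: str) -> float:
    ux, uy = DIRECTIONS[direction]
    # half-extent of the grid projected onto the travel axis
    return grid.extent_deg * (abs(ux) + abs(uy))


def render_sweep(sweep: BarSweep, grid: FieldGrid, tr_s: float) -> ApertureMovie:
    """Render one bar sweep into a binary aperture movie at TR resolution.

    A pixel is active when its center lies inside the bar strip; the strip
    interval is open at the trailing edge and closed at the leading edge
    (deterministic tie-break in the travel direction).  The bar position for
    each frame is the one active at the frame's temporal midpoint.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    ux, uy = DIRECTIONS[sweep.direction]
    span = _projection_span(grid, sweep.direction)
    centers = np.linspace(-span, span, sweep.n_steps)

    xx, yy = grid.meshgrid()
    proj = xx * ux + yy * uy  # signed position along travel axis

    total_s = sweep.n_steps * sweep.step_duration_s
    n_frames = max(1, math.ceil(total_s / tr_s - 1e-9))
    half_w = sweep.width_deg / 2.0
    frames = np.zeros((n_frames, grid.n_pix, grid.n_pix), dtype=np.uint8)
    for t in range(n_frames):
        t_mid = (t + 0.5) * tr_s
        step = min(int(t_mid // sweep.step_duration_s), sweep.n_steps - 1)
        d = proj - centers[step]
        frames[t] = (d > -half_w) & (d <= half_w)
    if not frames.any():
        raise ValueError("sweep never intersects the grid")
    return ApertureMovie(grid=grid, frames=frames, tr_s=tr_s, width_deg=sweep.width_deg)


def blank_movie(grid: FieldGrid, n_frames: int, tr_s: float) -> ApertureMovie:
    """All-zero frames (blank/rest periods between sweeps)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames = np.zeros((n_frames, grid.n_pix, grid.n_pix), dtype=np.uint8)
    return ApertureMovie(grid=grid, frames=frames, tr_s=tr_s)


def concat_movies(movies: list[ApertureMovie]) -> ApertureMovie:
    """Concatenate movies in time. All parts must share grid and TR."""
    if not movies:
        raise ValueError("need at least one movie")
    first = movies[0]
    for m in movies[1:]:
        if m.grid != first.grid:
            raise ValueError("grid mismatch between movies")
        if m.tr_s != first.tr_s:
            raise ValueError("tr_s mismatch between movies")
    widths = {m.width_deg for m in movies}
    width = widths.pop() if len(widths) == 1 else None
    frames = np.concatenate([m.frames for m in movies], axis=0)
    return ApertureMovie(grid=first.grid, frames=frames, tr_s=first.tr_s, width_deg=width)


def default_mapping_movie(
    grid: FieldGrid,
    width_deg: float = 2.0,
    tr_s: float = 2.0,
    n_steps: int = 16,
    blank_frames: int = 4,
    directions: tuple[str, ...] = tuple(DIRECTIONS),
    step_duration_s: float | None = None,
) -> ApertureMovie:
    """Standard mapping run: one sweep per direction, blanks in between."""
    if step_duration_s is None:
        step_duration_s = tr_s
    parts: list[ApertureMovie] = []
    for i, direction in enumerate(directions):
        sweep = BarSweep(width_deg, direction, n_steps=n_steps,
                         step_duration_s=step_duration_s)
        parts.append(render_sweep(sweep, grid, tr_s))
        if blank_frames > 0 and i < len(directions) - 1:
            parts.append(blank_movie(grid, blank_frames, tr_s))
    movie = concat_movies(parts)
    movie.width_deg = width_deg
    return movie


def save_movie(movie: ApertureMovie, path: str) -> None:
    """Write an aperture movie as a compressed NPZ with JSON metadata."""
    meta = {
        "extent_deg": movie.grid.extent_deg,
        "n_pix": movie.grid.n_pix,
        "tr_s": movie.tr_s,
        "width_deg": movie.width_deg,
    }
    np.savez_compressed(path, frames=movie.frames,
                        meta=np.array(json.dumps(meta)))


def load_movie(path: str) -> ApertureMovie:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        frames = npz["frames"]
    grid = make_grid(meta["extent_deg"], meta["n_pix"])
    return ApertureMovie(grid=grid, frames=frames, tr_s=meta["tr_s"],
                         width_deg=meta.get("width_deg"))


def export_frames_png(movie: ApertureMovie, out_dir: str, prefix: str = "frame") -> list[str]:
    """Dump individual frames as PNG images for visual inspection."""
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, frame in enumerate(movie.frames):
        p = os.path.join(out_dir, f"{prefix}_{i:04d}.png")
        plt.imsave(p, frame, cmap="gray", origin="lower", vmin=0, vmax=1)
        paths.append(p)
    return paths
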