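"""Moving-bar aperture stimulus on a visual-field pixel grid.

The stimulus is a binary "design movie": a bar of configurable width sweeps
across a circular aperture in a number of directions, optionally followed by
blank frames after each pass.  Each frame lives on a square pixel grid in
degrees of visual angle, centred on fixation (x rightward, y upward).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "VisualFieldGrid",
    "StimulusDesign",
    "make_grid",
    "make_bar_sequence",
    "save_design",
    "load_design",
]

BLANK_LABEL = -1


@dataclass(frozen=True, eq=False)
class VisualFieldGrid:
    """Square, fixation-centred pixel grid in degrees of visual angle.

    Attributes
    ----------
    x, y : ndarray
        Pixel coordinates along each axis, spanning ``[-extent, +extent]``
        with uniform spacing.  ``x`` indexes columns, ``y`` rows.
    extent : float
        Maximum eccentricity (half-width of the field) in degrees.
    """

    x: np.ndarray
    y: np.ndarray
    extent: float

    def __post_init__(self) -> None:
        xx, yy = np.meshgrid(self.x, self.y)
        object.__setattr__(self, "_xx", xx.ravel())
        object.__setattr__(self, "_yy", yy.ravel())

    @property
    def n_pixels(self) -> int:
        """Pixels per axis."""
        return self.x.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y.size, self.x.size)

    @property
    def pixel_x(self) -> np.ndarray:
        """Flattened per-pixel x coordinate (row-major)."""
        return self._xx  # type: ignore[attr-defined]

    @property
    def pixel_y(self) -> np.ndarray:
        return self._yy  # type: ignore[attr-defined]

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    def aperture_mask(self) -> np.ndarray:
        """Boolean flat mask of pixels inside the circular aperture."""
        return self.pixel_x**2 + self.pixel_y**2 <= self.extent**2


def make_grid(extent_deg: float, n_pixels: int) -> VisualFieldGrid:
    """Build a uniform square grid spanning ``[-extent, +extent]`` per axis."""
    if extent_deg <= 0:
        raise ValueError(f"extent_deg must be positive, got {extent_deg}")
    if n_pixels < 2:
        raise ValueError(f"n_pixels must be at least 2, got {n_pixels}")
    coords = np.linspace(-extent_deg, extent_deg, int(n_pixels))
    return VisualFieldGrid(x=coords, y=coords.copy(), extent=float(extent_deg))


@dataclass(eq=False)
class StimulusDesign:
    """Binary aperture movie plus frame timing and per-frame pass labels.

    ``pass_labels[t]`` is the index of the bar direction shown at frame ``t``,
    or ``BLANK_LABEL`` (-1) for blank frames.
    """

    grid: VisualFieldGrid
    frames: np.ndarray  # (T, n, n) boolean
    frame_duration: float = 1.0
    pass_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    directions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=bool)
        if self.frames.ndim != 3 or self.frames.shape[1:] != self.grid.shape:
            raise ValueError("frames must be (T, n, n) matching the grid")
        if self.n_frames < 1:
            raise ValueError("a design needs at least one frame")
        if self.pass_labels is None:
            self.pass_labels = np.full(self.n_frames, BLANK_LABEL, dtype=int)
        self.pass_labels = np.asarray(self.pass_labels, dtype=int)
        if self.pass_labels.shape != (self.n_frames,):
            raise ValueError("pass_labels must have one entry per frame")
        self._frame_matrix: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_matrix(self) -> np.ndarray:
        """Frames flattened to (T, n_pixels) float64, cached."""
        if self._frame_matrix is None:
            self._frame_matrix = self.frames.reshape(self.n_frames, -1).astype(float)
        return self._frame_matrix


def make_bar_sequence(
    grid: VisualFieldGrid,
    bar_width_deg: float = 2.0,
    steps_per_pass: int = 16,
    directions: Sequence[float] | None = None,
    blank_frames: int = 4,
    frame_duration: float = 1.0,
    circular_aperture: bool = True,
) -> StimulusDesign:
    """Generate a multi-direction bar-sweep design.

    One pass per entry of ``directions`` (motion direction, degrees; default
    eight directions at 45-degree increments).  Within a pass the bar -- a band
    orthogonal to the motion direction -- translates across the aperture in
    ``steps_per_pass`` equal steps, followed by ``blank_frames`` all-zero
    frames.  Pixels outside the circular aperture are always off unless
    ``circular_aperture`` is disabled.
    """
    if bar_width_deg <= 0:
        raise ValueError("bar_width_deg must be positive")
    if bar_width_deg > 2 * grid.extent:
        raise ValueError("bar_width_deg may not exceed the field diameter")
    if steps_per_pass < 1:
        raise ValueError("steps_per_pass must be at least 1")
    if blank_frames < 0:
        raise ValueError("blank_frames must be non-negative")
    if directions is None:
        directions = tuple(45.0 * i for i in range(8))
    directions = tuple(float(d) for d in directions)
    if len(directions) == 0:
        raise ValueError("directions must be non-empty")

    px, py = grid.pixel_x, grid.pixel_y
    aperture = grid.aperture_mask() if circular_aperture else np.ones(px.size, bool)
    half_span = grid.extent - bar_width_deg / 2.0
    if steps_per_pass == 1:
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-half_span, half_span, steps_per_pass)

    frames: list[np.ndarray] = []
    labels: list[int] = []
    blank = np.zeros(grid.shape, dtype=bool)
    for i, theta in enumerate(directions):
        rad = np.deg2rad(theta)
        proj = px * np.cos(rad) + py * np.sin(rad)
        for off in offsets:
            # tiny tolerance keeps boundary pixels consistent across the
            # float rounding of opposite-direction projections
            frame = (np.abs(proj - off) <= bar_width_deg / 2.0 + 1e-9) & aperture
            frames.append(frame.reshape(grid.shape))
            labels.append(i)
        for _ in range(blank_frames):
            frames.append(blank)
            labels.append(BLANK_LABEL)

    return StimulusDesign(
        grid=grid,
        frames=np.stack(frames),
        frame_duration=float(frame_duration),
        pass_labels=np.array(labels, dtype=int),
        directions=directions,
    )


def save_design(design: StimulusDesign, path: str | Path) -> Path:
    """Save a design as ``.npz`` with a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(
        path,
        frames=design.frames.astype(np.uint8),
        x=design.grid.x,
        y=design.grid.y,
        pass_labels=design.pass_labels,
    )
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "extent": design.grid.extent,
                "frame_duration": design.frame_duration,
                "directions": list(design.directions),
                "n_frames": design.n_frames,
            },
            indent=2,
        )
    )
    return path


def load_design(path: str | Path) -> StimulusDesign:
    path = Path(path)
    with np.load(path) as data:
        frames = data["frames"].astype(bool)
        x, y = data["x"], data["y"]
        labels = data["pass_labels"]
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = VisualFieldGrid(x=x, y=y, extent=float(meta["extent"]))
    return StimulusDesign(
        grid=grid,
        frames=frames,
        frame_duration=float(meta["frame_duration"]),
        pass_labels=labels,
        directions=tuple(meta.get("directions", ())),
    )
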