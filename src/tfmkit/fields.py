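"""Core containers: image frames, image sequences, and regular-grid vector fields.

Coordinate convention (shared by every module): the origin sits at the
center of the top-left pixel, x runs rightward along array columns,
y runs downward along array rows, and all physical lengths are in
micrometres.  Vector fields live on square-spaced regular grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = ["ImageFrame", "ImageSequence", "VectorField2D"]


@dataclass(frozen=True)
class ImageFrame:
    """A single 2D intensity image with physical pixel size.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities (arbitrary units).
    pixel_size
        Physical size of one pixel in micrometres per pixel.
    timestamp
        Acquisition time in minutes relative to the start of the recording.
    """

    pixels: np.ndarray
    pixel_size: float
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if np.any(px < 0):
            raise ValueError("pixels must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageSequence:
    """Time-ordered frames sharing one pixel size (a bead-channel movie)."""

    frames: list[ImageFrame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("ImageSequence requires at least one frame")
        sizes = {f.pixel_size for f in self.frames}
        if len(sizes) != 1:
            raise ValueError("all frames must share one pixel_size")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError("all frames must share one shape")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> ImageFrame:
        return self.frames[i]

    def __iter__(self) -> Iterator[ImageFrame]:
        return iter(self.frames)

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])


@dataclass
class VectorField2D:
    """A 2D vector field sampled on a square-spaced regular grid.

    Used for substrate displacements (components in micrometres) and for
    traction stresses (components in pascals).  ``u_x[i, j]`` is the
    x-component at grid node (row i, column j); the node's physical
    position is ``origin + spacing * (j, i)``.

    ``valid_mask`` flags nodes whose value is trustworthy; invalid nodes
    are never silently interpolated — gap filling is an explicit,
    logged operation (see :func:`tfmkit.piv.validate_and_fill`).
    """

    u_x: np.ndarray
    u_y: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        if self.u_x.shape != self.u_y.shape or self.u_x.ndim != 2:
            raise ValueError("u_x and u_y must be 2D arrays of equal shape")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.u_x.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.u_x.shape:
                raise ValueError("valid_mask shape must match u_x/u_y")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.u_x.shape

    @property
    def fov_area(self) -> float:
        """Area covered by the grid nodes (node count x spacing^2), um^2."""
        return self.u_x.size * self.spacing**2

    def node_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of every node, each as a 2D array."""
        ny, nx = self.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return np.meshgrid(x, y)

    # -- values -----------------------------------------------------------
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u_x, self.u_y)

    def norm(self) -> float:
        """Euclidean norm over all components (root of sum of squares)."""
        return float(np.sqrt(np.sum(self.u_x**2 + self.u_y**2)))

    def rms(self) -> float:
        """Root-mean-square vector magnitude over the grid."""
        return float(np.sqrt(np.mean(self.u_x**2 + self.u_y**2)))

    def mean_subtracted(self) -> "VectorField2D":
        """Return a copy with the spatial mean of each component removed."""
        return replace(
            self,
            u_x=self.u_x - self.u_x.mean(),
            u_y=self.u_y - self.u_y.mean(),
            valid_mask=self.valid_mask.copy(),
        )

    def crop(self, row0: int, row1: int, col0: int, col1: int) -> "VectorField2D":
        return VectorField2D(
            u_x=self.u_x[row0:row1, col0:col1].copy(),
            u_y=self.u_y[row0:row1, col0:col1].copy(),
            spacing=self.spacing,
            origin=(
                self.origin[0] + col0 * self.spacing,
                self.origin[1] + row0 * self.spacing,
            ),
            valid_mask=self.valid_mask[row0:row1, col0:col1].copy(),
        )

    # -- arithmetic (linear-space structure used by the property tests) ----
    def _check_compatible(self, other: "VectorField2D") -> None:
        if self.shape != other.shape:
            raise ValueError(f"grid shape mismatch: {self.shape} vs {other.shape}")
        if not np.isclose(self.spacing, other.spacing):
            raise ValueError("grid spacing mismatch")

    def __add__(self, other: "VectorField2D") -> "VectorField2D":
        self._check_compatible(other)
        return replace(
            self,
            u_x=self.u_x + other.u_x,
            u_y=self.u_y + other.u_y,
            valid_mask=self.valid_mask & other.valid_mask,
        )

    def __sub__(self, other: "VectorField2D") -> "VectorField2D":
        self._check_compatible(other)
        return replace(
            self,
            u_x=self.u_x - other.u_x,
            u_y=self.u_y - other.u_y,
            valid_mask=self.valid_mask & other.valid_mask,
        )

    def __mul__(self, scalar: float) -> "VectorField2D":
        return replace(
            self,
            u_x=self.u_x * scalar,
            u_y=self.u_y * scalar,
            valid_mask=self.valid_mask.copy(),
        )

    __rmul__ = __mul__

    def __neg__(self) -> "VectorField2D":
        return self * -1.0
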