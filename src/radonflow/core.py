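"""Core domain types and the elementary angle/velocity conversions.

A line-scan (kymograph) acquisition repeatedly scans one line along a
vessel; stacking successive lines as rows gives a space-time image whose
rows are time (line index) and columns are space (position along the
vessel).  A red blood cell moving at velocity ``v`` traces a diagonal
streak whose angle ``theta``, measured from the time (vertical) axis,
satisfies ``theta = arctan(v * dt / dx)``.  Inverting gives

    v = (dx / dt) * tan(theta)

with ``dx`` in um/pixel and ``dt`` in ms/line, so ``v`` comes out in
um/ms, numerically equal to mm/s.

Conventions shared by every module:

* ``theta`` is in degrees in ``[-90, 90)``; 0 means vertical streaks
  (stagnant flow), magnitudes approaching 90 mean horizontal streaks
  (unmeasurably fast flow).
* positive ``theta`` (and velocity) means displacement toward increasing
  column index per scanned line; the physical direction along the vessel
  is up to the user.
* row/column indexing is 0-based; windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpaceTimeImage",
    "AngleEstimate",
    "VelocitySample",
    "velocity_from_angle",
    "angle_from_velocity",
    "validate_image",
    "wrap_angle",
]


def wrap_angle(theta: float) -> float:
    """Reduce an angle in degrees modulo 180 into ``[-90, 90)``.

    The Radon projection-variance profile is 180-degree periodic, so this
    reduction is lossless for every consumer in the package.
    """
    return float((theta + 90.0) % 180.0 - 90.0)


@dataclass(frozen=True)
class SpaceTimeImage:
    """A line-scan raster with its acquisition metadata.

    Parameters
    ----------
    pixels : ndarray of shape (h, w)
        Luminance values; rows are successive line scans (time), columns
        are positions along the scanned line (space).
    dx : float
        Spatial resolution, um/pixel.
    dt : float
        Line period, ms/line.
    """

    pixels: np.ndarray
    dx: float
    dt: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float))

    @property
    def n_lines(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_columns(self) -> int:
        return self.pixels.shape[1]

    def crop_rows(self, start: int, end: int) -> "SpaceTimeImage":
        """Return the window of rows ``[start, end)`` with metadata kept."""
        return SpaceTimeImage(self.pixels[start:end], self.dx, self.dt)


@dataclass(frozen=True)
class AngleEstimate:
    """A streak-angle estimate with its peak projection variance."""

    theta: float
    peak_variance: float
    valid: bool = True

    def __post_init__(self) -> None:
        if not -90.0 <= self.theta < 90.0:
            raise ValueError(f"theta must lie in [-90, 90), got {self.theta}")
        if self.peak_variance < 0:
            raise ValueError("peak_variance must be non-negative")


@dataclass(frozen=True)
class VelocitySample:
    """One velocity measurement from a window of a long sequence."""

    velocity: float
    theta: float
    segment_start_row: int
    segment_end_row: int
    valid: bool = True
    peak_variance: float = 0.0
    n_transforms: int = 0
    achieved_delta: float = float("nan")


def velocity_from_angle(theta: float, dx: float, dt: float) -> float:
    """Convert a streak angle to a signed blood velocity in mm/s.

    ``v = (dx/dt) * tan(theta)`` with ``theta`` in degrees measured from
    the time axis, ``dx`` in um/pixel and ``dt`` in ms/line.

    Raises
    ------
    ValueError
        If ``|theta| >= 90`` (tangent singularity: horizontal streaks
        are unmeasurably fast) or ``dx``/``dt`` are not positive.
    """
    if not -90.0 < theta < 90.0:
        raise ValueError(
            f"theta must lie strictly inside (-90, 90) degrees, got {theta}"
        )
    if dx <= 0 or dt <= 0:
        raise ValueError("dx and dt must be positive")
    return (dx / dt) * math.tan(math.radians(theta))


def angle_from_velocity(v: float, dx: float, dt: float) -> float:
    """Streak angle in degrees produced by velocity ``v`` mm/s.

    Inverse of :func:`velocity_from_angle`: ``theta = arctan(v*dt/dx)``.
    """
    if dx <= 0 or dt <= 0:
        raise ValueError("dx and dt must be positive")
    return math.degrees(math.atan(v * dt / dx))


def validate_image(image: SpaceTimeImage) -> SpaceTimeImage:
    """Check the :class:`SpaceTimeImage` invariants, returning the image.

    Raises
    ------
    ValueError
        Naming the violated invariant: fewer than 3 rows or columns,
        non-positive ``dx``/``dt``, or non-finite luminance values.
    """
    px = image.pixels
    if px.ndim != 2:
        raise ValueError(f"pixels must be 2-D, got {px.ndim}-D")
    if px.shape[0] < 3:
        raise ValueError(f"too few rows: need >= 3 lines, got {px.shape[0]}")
    if px.shape[1] < 3:
        raise ValueError(f"too few columns: need >= 3, got {px.shape[1]}")
    if image.dx <= 0:
        raise ValueError(f"dx must be positive, got {image.dx}")
    if image.dt <= 0:
        raise ValueError(f"dt must be positive, got {image.dt}")
    if not np.isfinite(px).all():
        raise ValueError("pixels contain non-finite values")
    return image
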