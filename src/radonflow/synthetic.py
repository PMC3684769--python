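"""Synthetic space-time images with known ground truth.

The generator emulates two-photon line-scan recordings of a vessel with
fluorescently labeled plasma: red blood cells appear as dark diagonal
bands on a bright background.  Bands run along lines at a configurable
angle from the time axis, with a trapezoidal cross-section whose edges
are anti-aliased over one pixel (two-photon streak edges span no more
than a pixel or two).  Optional additive Gaussian noise, time-invariant
vertical bands (scan path leaving the vessel) and slowly time-varying
horizontal bands (heartbeat/brain-motion luminance artifacts) cover the
artifact taxonomy seen in vivo.

All randomness flows through a seeded generator, so identical
specifications produce bit-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import SpaceTimeImage

__all__ = [
    "SyntheticSpec",
    "generate_streak_image",
    "add_static_band",
    "add_motion_artifact",
    "generate_sequence",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth description of a synthetic streak image.

    ``streak_spacing`` is the perpendicular separation between band
    centers in pixels and must exceed ``streak_width``.  ``contrast`` is
    the luminance drop from background to band center; set
    ``inverted=True`` for bright streaks on a dark background.
    """

    theta_true: float
    width: int = 100
    height: int = 100
    streak_width: float = 3.0
    streak_spacing: float = 12.0
    contrast: float = 50.0
    background_level: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0
    dx: float = 0.5
    dt: float = 1.0
    inverted: bool = False

    def validate(self) -> "SyntheticSpec":
        if not -90 <= self.theta_true < 90:
            raise ValueError("theta_true must lie in [-90, 90)")
        if self.streak_width < 1:
            raise ValueError("streak_width must be >= 1 pixel")
        if self.streak_spacing <= self.streak_width:
            raise ValueError("streak_spacing must exceed streak_width")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.width < 3 or self.height < 3:
            raise ValueError("image must be at least 3x3")
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")
        return self


def _band_profile(spec: SyntheticSpec, u: np.ndarray) -> np.ndarray:
    """Trapezoidal band occupancy in [0, 1] from perpendicular coordinate."""
    s = spec.streak_spacing
    d = np.abs(((u + s / 2.0) % s) - s / 2.0)  # distance to nearest band center
    return np.clip(spec.streak_width / 2.0 + 0.5 - d, 0.0, 1.0)


def _streak_pixels(spec: SyntheticSpec, phase_offset: float, t0: float) -> np.ndarray:
    t, x = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
    th = math.radians(spec.theta_true)
    # perpendicular (normal) coordinate of pixel (t, x) w.r.t. streak direction
    u = -(t + t0) * math.sin(th) + x * math.cos(th) - phase_offset
    prof = _band_profile(spec, u)
    sign = 1.0 if spec.inverted else -1.0
    return spec.background_level + sign * spec.contrast * prof


def generate_streak_image(
    spec: SyntheticSpec, phase_offset: float = 0.0
) -> SpaceTimeImage:
    """Render a streak image for the given specification.

    ``phase_offset`` shifts the band pattern along the streak normal (in
    pixels), realizing streaks at different spatial positions without
    changing the angle.  Noise is drawn from ``default_rng(spec.seed)``.

    Raises
    ------
    ValueError
        If the geometry admits no streak (spacing larger than the image
        diagonal).
    """
    spec.validate()
    diag = math.hypot(spec.width, spec.height)
    if spec.streak_spacing > diag:
        raise ValueError(
            "streak_spacing exceeds the image diagonal: no streak fits"
        )
    px = _streak_pixels(spec, phase_offset, t0=0.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        px = px + rng.normal(0.0, spec.noise_sd, px.shape)
    return SpaceTimeImage(px, spec.dx, spec.dt)


def add_static_band(
    image: SpaceTimeImage, column_range: tuple[int, int], level: float
) -> SpaceTimeImage:
    """Overwrite the columns ``[start, stop)`` with a time-invariant level.

    Emulates a scan path that leaves the vessel: a vertical band whose
    luminance never changes with time.
    """
    start, stop = column_range
    if not 0 <= start <= stop <= image.n_columns:
        raise ValueError(
            f"column range [{start}, {stop}) outside image width {image.n_columns}"
        )
    px = image.pixels.copy()
    px[:, start:stop] = level
    return SpaceTimeImage(px, image.dx, image.dt)


def add_motion_artifact(
    image: SpaceTimeImage,
    period_lines: int,
    amplitude_level: float,
    duty: float = 0.3,
    seed: int = 0,
) -> SpaceTimeImage:
    """Add slowly varying horizontal darkening bands (heartbeat motion).

    Whole rows are darkened by smooth raised-cosine pulses recurring
    roughly every ``period_lines`` lines (period and depth jittered by
    ~10% per cycle from the seeded generator), each pulse spanning
    ``duty`` of the period.  At typical line rates a few hundred lines
    per period corresponds to the 3-8 Hz band of cardiac/respiratory
    brain motion.  The smoothness matters: these artifacts vary slowly
    relative to the line period, unlike the sharp streak edges.
    """
    if period_lines < 2:
        raise ValueError("period_lines must be >= 2")
    if not 0 < duty < 1:
        raise ValueError("duty must lie in (0, 1)")
    if amplitude_level < 0:
        raise ValueError("amplitude_level must be non-negative")
    n = image.n_lines
    envelope = np.zeros(n)
    if amplitude_level > 0:
        rng = np.random.default_rng(seed)
        pulse_len = max(2, int(round(duty * period_lines)))
        center = rng.uniform(0.3, 0.7) * period_lines
        while center < n + pulse_len:
            depth = amplitude_level * rng.uniform(0.9, 1.1)
            rows = np.arange(n)
            arg = (rows - center) / pulse_len  # pulse support |arg| < 1/2
            mask = np.abs(arg) < 0.5
            envelope[mask] += depth * 0.5 * (1 + np.cos(2 * np.pi * arg[mask]))
            center += period_lines * rng.uniform(0.9, 1.1)
    px = image.pixels - envelope[:, None]
    return SpaceTimeImage(px, image.dx, image.dt)


def generate_sequence(
    specs: list[tuple[SyntheticSpec, int]]
) -> SpaceTimeImage:
    """Row-wise concatenation of constant-angle epochs.

    Each entry is ``(spec, n_lines)``; all specs must share ``width``,
    ``dx`` and ``dt``.  The streak phase is continued across epoch
    boundaries (band positions at the first line of an epoch match the
    last line of the previous one at the left image edge), so a step
    change in angle produces kinked but unbroken streaks, as a genuine
    velocity step would.
    """
    if not specs:
        raise ValueError("epoch list must be non-empty")
    first = specs[0][0]
    for spec, n_lines in specs:
        spec.validate()
        if n_lines < 1:
            raise ValueError("epoch length must be >= 1 line")
        if (spec.width, spec.dx, spec.dt) != (first.width, first.dx, first.dt):
            raise ValueError("all epochs must share width, dx and dt")

    blocks = []
    phase = 0.0
    noise_parts = []
    for k, (spec, n_lines) in enumerate(specs):
        epoch = replace(spec, height=n_lines, noise_sd=0.0)
        px = _streak_pixels(epoch, phase_offset=phase, t0=0.0)
        blocks.append(px)
        # continue the band pattern at x=0: the first line of the next epoch
        # must match the line that would have followed this one
        th = math.radians(spec.theta_true)
        phase += n_lines * math.sin(th)
        if spec.noise_sd > 0:
            rng = np.random.default_rng(spec.seed + k)
            noise_parts.append(rng.normal(0.0, spec.noise_sd, px.shape))
        else:
            noise_parts.append(np.zeros_like(px))
    px = np.vstack(blocks) + np.vstack(noise_parts)
    return SpaceTimeImage(px, first.dx, first.dt)
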