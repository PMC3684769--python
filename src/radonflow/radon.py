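"""Discrete Radon projections and the projection-variance angle profile.

The Radon transform of an image at angle ``theta`` integrates the image
along parallel rays at that angle.  When the rays are aligned with the
streaks, each ray stays either inside a dark band or inside the bright
plasma between bands, so the projection is maximally structured; the
streak angle is the angle maximizing the variance of the projection over
offsets.

Discretization: each pixel's center is rotated about the image center
and its value dispatched, with linear splitting, into the two nearest
unit-spaced offset bins.  This is the adjoint ("pixel-driven") form of
the rotate-and-sum projection; the linear split makes total mass exact
at every angle.  The bin coordinate is calibrated so that a streak at
angle ``+theta`` (package convention: degrees from the time axis,
positive toward increasing column index) yields its variance peak at
``+theta``.  Ray lengths through the image are tracked by projecting a
ones mask the same way; variances are computed on the residual after
removing the ray-length-proportional component, restricted to bins
whose ray length exceeds half the maximum, because raw sums over rays
of unequal length would contribute purely geometric variance (nonzero
even for a constant image) and near-empty corner rays would distort the
profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AngleEstimate, wrap_angle
from .filtering import FilteredImage

__all__ = [
    "VarianceProfile",
    "radon_projection",
    "projection_variance",
    "variance_profile",
    "best_angle",
]


def _pixels(image) -> np.ndarray:
    return image.pixels if hasattr(image, "pixels") else np.asarray(image, float)


def _bin_offsets(shape: tuple[int, int], theta: float):
    """Fractional bin coordinate of every pixel at projection angle theta.

    ``u = (x - cx) cos(theta) - (t - cy) sin(theta)``: pixels lying on a
    streak at angle ``theta`` share the same ``u``.  Integer centers
    ``(h//2, w//2)`` keep ``u`` exactly integral at ``theta = 0`` so the
    zero-angle projection reduces to plain column sums.
    """
    h, w = shape
    th = math.radians(theta)
    t, x = np.mgrid[0:h, 0:w].astype(float)
    return (x - w // 2) * math.cos(th) - (t - h // 2) * math.sin(th)


def _accumulate(values: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Dispatch values into unit bins with linear splitting (mass exact)."""
    lo = np.floor(u).astype(int)
    frac = u - lo
    rad = max(-lo.min(), lo.max() + 1)
    n = 2 * rad + 1
    idx = (lo + rad).ravel()
    v = values.ravel()
    f = frac.ravel()
    out = np.bincount(idx, weights=v * (1.0 - f), minlength=n)
    out += np.bincount(idx + 1, weights=v * f, minlength=n)[: len(out)]
    return out


def radon_projection(image: FilteredImage | np.ndarray, theta: float) -> np.ndarray:
    """1-D line-integral projection of the image at angle ``theta``.

    ``theta`` is in degrees in ``[-90, 90)`` measured from the time
    (vertical) axis.  Bins are unit-spaced offsets about the image
    center; the center bin sits at index ``len(out) // 2``.  The sum of
    all bins equals the sum of all pixels exactly.  All bins are
    returned; support trimming happens only when a variance is computed.
    """
    theta = wrap_angle(theta)
    px = _pixels(image)
    return _accumulate(px, _bin_offsets(px.shape, theta))


def projection_variance(image: FilteredImage | np.ndarray, theta: float) -> float:
    """Variance over offsets of the projection at ``theta``.

    The variance is taken over the residual of the projection after
    removing its ray-length-proportional component (the image's mean
    intensity times each bin's ray length): rays of unequal length at
    oblique angles would otherwise contribute purely geometric variance,
    nonzero even for a constant image.  For zero-mean (filtered) images
    the correction vanishes and this is the plain projection variance.
    Only bins whose ray length exceeds half the maximal ray length are
    kept; the residual is mean-centered before squaring (a no-op for the
    variance, kept for hygiene).
    """
    theta = wrap_angle(theta)
    px = _pixels(image)
    u = _bin_offsets(px.shape, theta)
    proj = _accumulate(px, u)
    lengths = _accumulate(np.ones_like(px), u)
    support = lengths > 0.5 * lengths.max()
    kept_p = proj[support]
    kept_l = lengths[support]
    rate = kept_p.sum() / kept_l.sum()
    resid = kept_p - rate * kept_l
    resid = resid - resid.mean()
    return float(np.mean(resid**2))


@dataclass(frozen=True)
class VarianceProfile:
    """Projection variance sampled over an ordered set of angles."""

    angles: np.ndarray
    variances: np.ndarray
    best_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", np.asarray(self.angles, float))
        object.__setattr__(self, "variances", np.asarray(self.variances, float))
        if self.angles.shape != self.variances.shape:
            raise ValueError("angles and variances must have equal length")

    @property
    def best_theta(self) -> float:
        return float(self.angles[self.best_index])

    @property
    def best_variance(self) -> float:
        return float(self.variances[self.best_index])


def variance_profile(
    image: FilteredImage | np.ndarray, angles: Sequence[float]
) -> VarianceProfile:
    """Projection variance at each requested angle, with the argmax marked.

    Angles are reduced modulo 180 into ``[-90, 90)``.  Ties in the
    maximum are broken in favor of the smallest ``|theta|``, then the
    earlier list position.
    """
    angles = np.asarray([wrap_angle(a) for a in np.atleast_1d(angles)], float)
    if angles.size == 0:
        raise ValueError("angle list must be non-empty")
    px = _pixels(image)
    variances = np.array([projection_variance(px, a) for a in angles])
    vmax = variances.max()
    tied = np.flatnonzero(variances == vmax)
    # stable sort on |theta| keeps earlier positions first among equals
    best = int(tied[np.argsort(np.abs(angles[tied]), kind="stable")[0]])
    return VarianceProfile(angles, variances, best)


def best_angle(
    image: FilteredImage | np.ndarray, angles: Sequence[float]
) -> AngleEstimate:
    """Variance-maximizing angle over the given angle set."""
    prof = variance_profile(image, angles)
    return AngleEstimate(prof.best_theta, prof.best_variance)
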