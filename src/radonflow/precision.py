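"""Measurement-design calculus for line-scan velocimetry.

Three groups of closed forms:

* **Acquisition re-scaling.**  Speeding line acquisition by a factor
  ``k`` (via spatial resolution, dwell time or line length) maps a
  streak angle ``theta`` to ``arctan(tan(theta)/k)``; conversely the
  factor needed to move ``theta`` to ``theta_new`` is
  ``tan(theta)/tan(theta_new)``.  Fractional velocity changes are best
  resolved near 45 degrees, so ``k = tan(theta)`` is the canonical
  target.

* **Pixel-resolution limits.**  Offsetting a single streak's endpoint by
  one pixel in its longer dimension bounds the finest angle change one
  streak can show (``delta_s1``); with ``n_s`` streaks in the image the
  theoretically finest detectable change is ``delta_n = delta_s1/n_s``.
  Streak extents follow from the image geometry:
  ``ws = min(w, ceil(h tan(theta0)))``, ``hs = min(h, ceil(w cot(theta0)))``.

* **Velocity-change sensitivity.**  A step from angle ``theta0`` to
  ``theta1`` corresponds to a fractional velocity change
  ``dv/v = tan(theta1)/tan(theta0) - 1``; inverting gives the angle
  step needed to resolve a target ``dv/v``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "PrecisionReport",
    "speed_factor",
    "rescaled_angle",
    "k_from_resolutions",
    "streak_extents",
    "single_streak_precision",
    "max_streak_count",
    "finest_detectable_angle",
    "dv_from_angle_change",
    "angle_change_for_dv",
    "precision_report",
]

#: default minimum inter-streak distance along the vessel, um
DEFAULT_DS_UM = 4.0


def _tand(a: float) -> float:
    return math.tan(math.radians(a))


def speed_factor(theta: float, theta_new: float) -> float:
    """Acquisition speed-up factor mapping angle ``theta`` to ``theta_new``.

    ``k = tan(theta) / tan(theta_new)``; both angles in (0, 90) degrees.
    """
    for name, a in (("theta", theta), ("theta_new", theta_new)):
        if not 0 < a < 90:
            raise ValueError(f"{name} must lie in (0, 90) degrees, got {a}")
    return _tand(theta) / _tand(theta_new)


def rescaled_angle(theta: float, k: float) -> float:
    """Streak angle after speeding the acquisition by factor ``k``.

    ``arctan(tan(theta)/k)`` in degrees; inverse of :func:`speed_factor`.
    """
    if not -90 < theta < 90:
        raise ValueError(f"theta must lie in (-90, 90) degrees, got {theta}")
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    return math.degrees(math.atan(_tand(theta) / k))


def k_from_resolutions(dx: float, dx_new: float, dt: float, dt_new: float) -> float:
    """Speed factor implied by a change of acquisition resolutions.

    ``k = (dx_new/dx) * (dt/dt_new)`` for ``dx`` in um/pixel and ``dt``
    in ms/line.
    """
    if min(dx, dx_new, dt, dt_new) <= 0:
        raise ValueError("all resolutions must be positive")
    return (dx_new / dx) * (dt / dt_new)


def streak_extents(theta0: float, w: int, h: int) -> tuple[int, int]:
    """Pixel extents (ws, hs) of one streak in a ``w`` x ``h`` image.

    ``ws = min(w, ceil(h tan(|theta0|)))``, ``hs = min(h, ceil(w cot(|theta0|)))``.
    The degenerate angles return the documented conventions: 0 degrees
    (vertical streak) gives ``(1, h)``; 90 gives ``(w, 1)``.
    """
    if w < 1 or h < 1:
        raise ValueError("w and h must be >= 1")
    a = abs(theta0)
    if not 0 <= a <= 90:
        raise ValueError(f"|theta0| must lie in [0, 90], got {a}")
    if a == 0:
        return 1, h
    if a == 90:
        return w, 1
    t = _tand(a)
    ws = min(w, math.ceil(h * t))
    hs = min(h, math.ceil(w / t))
    return max(ws, 1), max(hs, 1)


def single_streak_precision(ws: int, hs: int) -> float:
    """Finest angle change detectable from a single streak, degrees.

    Obtained by offsetting the streak endpoint one pixel in its longer
    dimension: ``arctan(ws/(hs-1)) - arctan(ws/hs)`` when ``ws <= hs``,
    ``arctan(ws/hs) - arctan((ws-1)/hs)`` otherwise.
    """
    if ws < 1 or hs < 1:
        raise ValueError("streak extents must be >= 1 pixel")
    if ws <= hs:
        if hs < 2:
            raise ValueError("hs must be >= 2 when ws <= hs")
        d = math.atan2(ws, hs - 1) - math.atan2(ws, hs)
    else:
        if ws < 2:
            raise ValueError("ws must be >= 2 when ws > hs")
        d = math.atan2(ws, hs) - math.atan2(ws - 1, hs)
    return math.degrees(d)


def max_streak_count(
    w: int,
    h: int,
    dx: float,
    dt: float,
    ws: int,
    hs: int,
    ds: float = DEFAULT_DS_UM,
    dt_streak: float | None = None,
) -> int:
    """Maximum number of streaks that fit in the image.

    If streaks span the full height (``hs == h``) the count is packed
    along space: ``floor(w*dx / ds)`` with ``ds`` the minimum
    inter-streak distance in um.  If they span the full width
    (``ws == w``) they are packed along time:
    ``floor(h*dt_s / dt_streak)`` with ``dt_streak`` the minimum
    inter-streak time in seconds (``dt`` is ms/line), equivalently
    ``floor(h*dx*ws / (ds*hs))`` when only ``ds`` is known.  When both
    extents are full (diagonal-spanning streaks) the spatial branch is
    used.  The count is floored at 1 with a warning when the raw floor
    is 0.
    """
    if ds <= 0:
        raise ValueError("ds must be positive")
    if hs == h:
        raw = math.floor(w * dx / ds)
    elif ws == w:
        if dt_streak is not None:
            if dt_streak <= 0:
                raise ValueError("dt_streak must be positive")
            raw = math.floor(h * dt / 1000.0 / dt_streak)
        else:
            raw = math.floor(h * dx * ws / (ds * hs))
    else:
        raise ValueError(
            f"inconsistent streak extents: ws={ws}, hs={hs} span neither "
            f"the full width ({w}) nor the full height ({h})"
        )
    if raw < 1:
        warnings.warn(
            "image too small to hold one streak at the given spacing; "
            "streak count floored at 1",
            stacklevel=2,
        )
        return 1
    return raw


def finest_detectable_angle(delta_s1: float, ns: int) -> float:
    """Theoretically finest detectable angle change: ``delta_s1 / ns``."""
    if delta_s1 <= 0:
        raise ValueError("delta_s1 must be positive")
    if ns < 1:
        raise ValueError("ns must be >= 1")
    return delta_s1 / ns


def dv_from_angle_change(theta0: float, theta1: float) -> float:
    """Signed fractional velocity change for an angle step theta0 -> theta1.

    ``dv/v = tan(theta1)/tan(theta0) - 1``; ``theta0`` must be nonzero
    (zero baseline velocity has no fractional change).
    """
    for name, a in (("theta0", theta0), ("theta1", theta1)):
        if not -90 < a < 90:
            raise ValueError(f"{name} must lie in (-90, 90) degrees, got {a}")
    if theta0 == 0:
        raise ValueError("theta0 must be nonzero (zero baseline velocity)")
    return _tand(theta1) / _tand(theta0) - 1.0


def angle_change_for_dv(theta0: float, dv: float) -> float:
    """Angle step (degrees) corresponding to a fractional velocity change.

    ``delta = |arctan((dv + 1) tan(theta0)) - theta0|`` for
    ``theta0`` in (0, 90) and ``dv > -1``.
    """
    if not 0 < theta0 < 90:
        raise ValueError(f"theta0 must lie in (0, 90) degrees, got {theta0}")
    if dv <= -1:
        raise ValueError(f"dv must exceed -1, got {dv}")
    theta1 = math.degrees(math.atan((dv + 1.0) * _tand(theta0)))
    return abs(theta1 - theta0)


@dataclass(frozen=True)
class PrecisionReport:
    """Pixel-resolution limits on angle detection for one geometry."""

    theta0: float
    w: int
    h: int
    ws: int
    hs: int
    delta_s1: float
    ns: int
    delta_n: float
    ds: float
    dt_streak: float | None = None


def precision_report(
    theta0: float,
    w: int,
    h: int,
    dx: float,
    dt: float,
    ds: float = DEFAULT_DS_UM,
    dt_streak: float | None = None,
) -> PrecisionReport:
    """Assemble the full pixel-resolution precision report.

    Composes :func:`streak_extents`, :func:`single_streak_precision`,
    :func:`max_streak_count` and :func:`finest_detectable_angle` for a
    measured angle ``theta0`` (degrees; the sign is ignored) and the
    image geometry.
    """
    a = abs(theta0)
    ws, hs = streak_extents(a, w, h)
    delta_s1 = single_streak_precision(ws, hs)
    ns = max_streak_count(w, h, dx, dt, ws, hs, ds=ds, dt_streak=dt_streak)
    delta_n = finest_detectable_angle(delta_s1, ns)
    return PrecisionReport(
        theta0=theta0,
        w=w,
        h=h,
        ws=ws,
        hs=hs,
        delta_s1=delta_s1,
        ns=ns,
        delta_n=delta_n,
        ds=ds,
        dt_streak=dt_streak,
    )
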