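"""Model/Results front end for line-scan velocimetry.

:class:`LinescanVelocimetry` is built from a space-time image plus its
acquisition metadata; ``fit`` runs the filter + iterative Radon search
on the whole image and returns a :class:`VelocimetryResults` carrying
the angle/velocity estimate, its angular resolution, the
pixel-resolution precision limits of the geometry, and the full search
trace.  ``fit_trace`` runs the windowed pipeline over a long recording
and returns :class:`VelocityTraceResults`, which knows how to flag
boundary outliers, smooth, tabulate and plot itself.

    >>> model = LinescanVelocimetry(pixels, dx=0.5, dt=1.0)
    >>> res = model.fit(target_delta=0.1)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import pipeline as _pipeline
from .core import SpaceTimeImage, validate_image, velocity_from_angle
from .filtering import FILTERS, apply_filter
from .precision import (
    PrecisionReport,
    dv_from_angle_change,
    precision_report,
)
from .search import IterativeSearchResult, iterative_radon

__all__ = ["LinescanVelocimetry", "VelocimetryResults", "VelocityTraceResults"]


class LinescanVelocimetry:
    """Streak-angle velocimetry model for one space-time image.

    Parameters
    ----------
    image : SpaceTimeImage or 2-D array
        Line-scan raster, rows = time, columns = space.
    dx, dt : float
        Spatial resolution (um/pixel) and line period (ms/line);
        required when ``image`` is a bare array.
    filter : str
        Pre-processing filter: ``"sobel"`` (default), ``"vdemean"``,
        ``"whole_image_demean"`` or ``"none"``.
    """

    def __init__(
        self,
        image: SpaceTimeImage | np.ndarray,
        dx: float | None = None,
        dt: float | None = None,
        filter: str = "sobel",
    ) -> None:
        if isinstance(image, SpaceTimeImage):
            self.image = image
        else:
            if dx is None or dt is None:
                raise ValueError("dx and dt are required with a bare pixel array")
            self.image = SpaceTimeImage(np.asarray(image, float), dx, dt)
        validate_image(self.image)
        if filter not in FILTERS:
            raise ValueError(f"unknown filter {filter!r}")
        self.filter = filter

    @classmethod
    def from_file(
        cls, path, dx: float, dt: float, filter: str = "sobel"
    ) -> "LinescanVelocimetry":
        """Build the model from a TIFF or text-matrix file."""
        from .io import read_linescan

        return cls(read_linescan(path, dx, dt), filter=filter)

    def fit(
        self,
        target_delta: float | None = None,
        n_iterations: int | None = None,
    ) -> "VelocimetryResults":
        """Estimate the streak angle of the whole image.

        Give either ``target_delta`` (angle resolution in degrees,
        default 0.1) or ``n_iterations``.
        """
        if target_delta is None and n_iterations is None:
            target_delta = 0.1
        filtered = apply_filter(self.image, self.filter)
        search = iterative_radon(
            filtered, target_delta=target_delta, n_iterations=n_iterations
        )
        return VelocimetryResults(self, search)

    def fit_trace(
        self,
        window: int = 100,
        step: int = 25,
        target_delta: float | None = None,
        target_dv: float | None = None,
        outlier_margin: float = 0.5,
    ) -> "VelocityTraceResults":
        """Windowed velocity trace over a long recording.

        Defaults to ``target_delta=0.1`` degrees if no precision target
        is given; samples within ``outlier_margin`` degrees of the
        +-90 degree boundary are flagged invalid.
        """
        if target_delta is None and target_dv is None:
            target_delta = 0.1
        trace = _pipeline.estimate_trace(
            self.image,
            window=window,
            step=step,
            target_delta=target_delta,
            target_dv=target_dv,
            filter=self.filter,
        )
        trace = _pipeline.flag_outliers(trace, outlier_margin)
        return VelocityTraceResults(self, trace)


@dataclass
class VelocimetryResults:
    """Fitted streak angle and velocity for one image."""

    model: LinescanVelocimetry
    search: IterativeSearchResult

    @property
    def theta(self) -> float:
        """Estimated streak angle, degrees from the time axis."""
        return self.search.theta

    @property
    def velocity(self) -> float:
        """Estimated blood velocity, mm/s (NaN if the fit is invalid)."""
        if not self.valid:
            return float("nan")
        return velocity_from_angle(self.theta, self.model.image.dx, self.model.image.dt)

    @property
    def valid(self) -> bool:
        return self.search.valid

    @property
    def achieved_delta(self) -> float:
        """Angular resolution of the search, degrees."""
        return self.search.achieved_delta

    @property
    def n_transforms(self) -> int:
        return self.search.n_transforms

    def dv_sensitivity(self) -> float:
        """Fractional velocity change resolvable at the fitted angle.

        ``tan(|theta| + delta)/tan(|theta|) - 1`` for the achieved
        angular resolution; NaN at a vertical (zero-velocity) angle.
        """
        a = abs(self.theta)
        if not 0 < a < 90 or a + self.achieved_delta >= 90:
            return float("nan")
        return dv_from_angle_change(a, a + self.achieved_delta)

    def precision_limits(self, ds: float = 4.0) -> PrecisionReport:
        """Pixel-resolution limits of this geometry at the fitted angle."""
        img = self.model.image
        return precision_report(
            max(abs(self.theta), 1e-6), img.n_columns, img.n_lines, img.dx, img.dt, ds=ds
        )

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        img = self.model.image
        rows = [
            ("image (h x w)", f"{img.n_lines} x {img.n_columns} px"),
            ("dx", f"{img.dx:g} um/pixel"),
            ("dt", f"{img.dt:g} ms/line"),
            ("filter", self.model.filter),
            ("streak angle", f"{self.theta:.4f} deg"),
            ("velocity", f"{self.velocity:.4f} mm/s"),
            ("angle resolution", f"{self.achieved_delta:.4g} deg"),
            ("dv/v sensitivity", f"{self.dv_sensitivity():.4g}"),
            ("iterations", f"{self.search.n_iterations}"),
            ("Radon transforms", f"{self.n_transforms}"),
            ("peak variance", f"{self.search.peak_variance:.6g}"),
            ("valid", str(self.valid)),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Line-scan velocimetry fit", "=" * 42]
        lines += [f"{k.ljust(width)} : {v}" for k, v in rows]
        return "\n".join(lines)

    def plot_search(self, ax=None):
        """Variance-vs-angle scatter of every evaluated candidate."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for rec in self.search.trace:
            ax.scatter(rec.angles, rec.variances, s=18, label=f"iter {rec.iteration}")
        ax.axvline(self.theta, color="k", lw=0.8, ls="--")
        ax.set_xlabel("angle (deg)")
        ax.set_ylabel("projection variance")
        ax.legend(fontsize="x-small", ncol=2)
        return ax


@dataclass
class VelocityTraceResults:
    """Windowed velocity trace with quality flags."""

    model: LinescanVelocimetry
    trace: _pipeline.VelocityTrace

    @property
    def n_valid(self) -> int:
        return self.trace.n_valid

    @property
    def n_invalid(self) -> int:
        return self.trace.n_invalid

    def smooth(self, span: float) -> "VelocityTraceResults":
        """Moving-average smoothed copy (span in seconds)."""
        return VelocityTraceResults(self.model, _pipeline.smooth_trace(self.trace, span))

    def to_frame(self):
        """Trace as a pandas DataFrame, one row per window."""
        import pandas as pd

        t = self.trace
        return pd.DataFrame(
            {
                "start_line": [s.segment_start_row for s in t.samples],
                "end_line": [s.segment_end_row for s in t.samples],
                "t_center_ms": t.times_ms(),
                "angle_deg": t.angles(),
                "velocity_mm_s": t.velocities(),
                "peak_variance": [s.peak_variance for s in t.samples],
                "n_transforms": [s.n_transforms for s in t.samples],
                "achieved_delta_deg": [s.achieved_delta for s in t.samples],
                "valid": [s.valid for s in t.samples],
            }
        )

    def save(self, path) -> None:
        """Write the trace CSV (see :func:`radonflow.io.write_trace`)."""
        from .io import write_trace

        write_trace(self.trace, path)

    def summary(self) -> str:
        t = self.trace
        v = np.array([s.velocity for s in t.samples if s.valid])
        lines = [
            "Line-scan velocity trace",
            "=" * 42,
            f"windows          : {len(t.samples)} "
            f"(window {t.window_lines} lines, step {t.step_lines})",
            f"valid / flagged  : {t.n_valid} / {t.n_invalid}",
        ]
        if v.size:
            lines += [
                f"mean velocity    : {v.mean():.4f} mm/s",
                f"velocity sd      : {v.std(ddof=1) if v.size > 1 else 0.0:.4f} mm/s",
                f"velocity range   : [{v.min():.4f}, {v.max():.4f}] mm/s",
            ]
        return "\n".join(lines)

    def plot(self, ax=None, show_invalid: bool = True):
        """Velocity vs time; flagged windows marked with open circles."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t_s = self.trace.times_ms() / 1000.0
        v = self.trace.velocities()
        valid = np.array([s.valid for s in self.trace.samples])
        ax.plot(t_s[valid], v[valid], "k.-", ms=4, lw=0.8, label="valid")
        if show_invalid and (~valid).any():
            ax.plot(
                t_s[~valid],
                np.zeros((~valid).sum()),
                "o",
                mfc="none",
                mec="r",
                label="flagged",
            )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("velocity (mm/s)")
        ax.legend(fontsize="x-small")
        return ax
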