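"""Reading line-scan images and writing velocity traces.

Supported inputs: single- or multi-page grayscale TIFF (pages are
concatenated row-wise in page order, the natural layout for line-scan
acquisitions saved in chunks) and whitespace-delimited numeric text
matrices.  Pixel values are converted to float without rescaling: the
variance-argmax angle detector is invariant to affine luminance maps,
so native ranges are kept.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile

from .core import SpaceTimeImage, VelocitySample, validate_image
from .pipeline import VelocityTrace

__all__ = ["read_linescan", "write_linescan", "write_trace", "read_trace", "TRACE_HEADER"]

TRACE_HEADER = (
    "segment_index,start_line,end_line,t_center_ms,angle_deg,velocity_mm_s,"
    "peak_variance,n_transforms,achieved_delta_deg,valid"
)

_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_linescan(path: str | Path, dx: float, dt: float) -> SpaceTimeImage:
    """Load a space-time image from TIFF or a numeric text matrix.

    Rows are time (line index), columns are space.  Multi-page TIFFs are
    concatenated row-wise in page order.  Color images and ragged text
    matrices are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        with tifffile.TiffFile(str(path)) as tif:
            grayscale = {
                tifffile.PHOTOMETRIC.MINISBLACK,
                tifffile.PHOTOMETRIC.MINISWHITE,
            }
            if any(p.photometric not in grayscale for p in tif.pages):
                raise ValueError(
                    f"{path}: color TIFF not supported; provide grayscale line scans"
                )
            arrays = [p.asarray() for p in tif.pages]
        if any(a.ndim != 2 for a in arrays):
            raise ValueError(f"{path}: each TIFF page must be a 2-D grayscale raster")
        pixels = arrays[0] if len(arrays) == 1 else np.concatenate(arrays, axis=0)
    else:
        try:
            pixels = np.loadtxt(str(path), dtype=float, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: not a rectangular numeric matrix ({exc})")
    return validate_image(SpaceTimeImage(np.asarray(pixels, float), dx, dt))


def write_linescan(image: SpaceTimeImage, path: str | Path) -> None:
    """Write a space-time image as a single-page float32 grayscale TIFF."""
    tifffile.imwrite(str(Path(path)), image.pixels.astype(np.float32))


def write_trace(trace: VelocityTrace, path: str | Path) -> None:
    """Write a velocity trace as CSV, one row per window.

    Columns: ``segment_index,start_line,end_line,t_center_ms,angle_deg,
    velocity_mm_s,peak_variance,n_transforms,achieved_delta_deg,valid``;
    floats carry 8 significant digits, ``valid`` is true/false.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRACE_HEADER.split(","))
        for i, s in enumerate(trace.samples):
            t_center = (s.segment_start_row + trace.window_lines / 2.0) * trace.dt
            writer.writerow(
                [
                    i,
                    s.segment_start_row,
                    s.segment_end_row,
                    f"{t_center:.8g}",
                    f"{s.theta:.8g}",
                    f"{s.velocity:.8g}",
                    f"{s.peak_variance:.8g}",
                    s.n_transforms,
                    f"{s.achieved_delta:.8g}",
                    "true" if s.valid else "false",
                ]
            )


def read_trace(path: str | Path, dx: float, dt: float) -> VelocityTrace:
    """Read back a trace CSV written by :func:`write_trace`."""
    samples = []
    window = step = None
    prev_start = None
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != TRACE_HEADER.split(","):
            raise ValueError(f"{path}: unexpected trace CSV header")
        for row in reader:
            start = int(row["start_line"])
            end = int(row["end_line"])
            window = end - start
            if prev_start is not None:
                step = start - prev_start
            prev_start = start
            samples.append(
                VelocitySample(
                    velocity=float(row["velocity_mm_s"]),
                    theta=float(row["angle_deg"]),
                    segment_start_row=start,
                    segment_end_row=end,
                    valid=row["valid"] == "true",
                    peak_variance=float(row["peak_variance"]),
                    n_transforms=int(row["n_transforms"]),
                    achieved_delta=float(row["achieved_delta_deg"]),
                )
            )
    return VelocityTrace(
        samples=tuple(samples),
        window_lines=window or 0,
        step_lines=step or (window or 1),
        dx=dx,
        dt=dt,
    )
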