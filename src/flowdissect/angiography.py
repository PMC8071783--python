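"""Speckle-decorrelation angiography from repeated complex B-scans.

A composite frame is built from N repeated B-scans at one lateral location:
the reflectance image is the pixelwise mean of the signal magnitudes, while
the angiogram is the average absolute difference of consecutive repeat
magnitudes, (1/(N-1)) * sum_i | |S_(i+1)| - |S_i| |.  Static tissue cancels
in the differences; flowing blood decorrelates the speckle between repeats
and lights up.  The angiogram is a relative flow contrast, not an absolute
velocity measure.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "BScanSeries", "AngiogramFrame", "ReflectanceFrame",
    "compute_reflectance", "compute_angiogram", "axial_motion_correct",
    "crop_roi",
]


@dataclasses.dataclass
class BScanSeries:
    """Repeated complex B-scans at one lateral location and time point.

    ``data`` has axes (repeat, depth, lateral); ``pixel_size_um`` is
    (depth, lateral) microns per pixel.
    """

    data: np.ndarray
    pixel_size_um: tuple[float, float] = (4.0, 4.0)
    frame_index: int = 0
    lateral_location_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("BScanSeries.data must be (repeat, depth, lateral)")
        if not np.all(np.isfinite(self.data.view(float))):
            raise ValueError("BScanSeries contains non-finite values")
        if any(s <= 0 for s in self.pixel_size_um):
            raise ValueError("pixel sizes must be > 0")

    @property
    def n_repeats(self) -> int:
        return self.data.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclasses.dataclass
class AngiogramFrame:
    """Nonnegative flow-contrast image with physical pixel scale."""

    values: np.ndarray
    pixel_size_um: tuple[float, float] = (4.0, 4.0)
    frame_index: int = 0
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("frame values must be 2-D (depth, lateral)")
        if np.any(self.values < 0):
            raise ValueError("angiogram values must be >= 0")

    @property
    def depth_um(self) -> float:
        return self.values.shape[0] * self.pixel_size_um[0]


@dataclasses.dataclass
class ReflectanceFrame:
    values: np.ndarray
    pixel_size_um: tuple[float, float] = (4.0, 4.0)
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("frame values must be 2-D (depth, lateral)")


def compute_reflectance(series: BScanSeries) -> ReflectanceFrame:
    """Pixelwise mean magnitude over all repeats."""
    if series.n_repeats < 1:
        raise ValueError("empty series")
    return ReflectanceFrame(values=np.abs(series.data).mean(axis=0),
                            pixel_size_um=series.pixel_size_um,
                            frame_index=series.frame_index)


def compute_angiogram(series: BScanSeries, pairs: str = "adjacent",
                      motion_corrected: bool = False) -> AngiogramFrame:
    """Average absolute magnitude difference between repeated B-scans.

    ``pairs="adjacent"`` (default) averages |ΔM| over the N-1 consecutive
    repeat pairs; ``pairs="all"`` averages over all N(N-1)/2 pairs, provided
    for sensitivity analysis.
    """
    if series.n_repeats < 2:
        raise ValueError("angiogram needs >= 2 repeats")
    mag = np.abs(series.data)
    if pairs == "adjacent":
        values = np.abs(np.diff(mag, axis=0)).mean(axis=0)
    elif pairs == "all":
        acc = np.zeros(mag.shape[1:])
        n = 0
        for i, j in itertools.combinations(range(series.n_repeats), 2):
            acc += np.abs(mag[j] - mag[i])
            n += 1
        values = acc / n
    else:
        raise ValueError(f"pairs must be 'adjacent' or 'all', got {pairs!r}")
    return AngiogramFrame(
        values=values, pixel_size_um=series.pixel_size_um,
        frame_index=series.frame_index,
        provenance={"n_repeats": series.n_repeats, "pairs": pairs,
                    "motion_corrected": motion_corrected, "roi_um": None})


def _parabolic_refine(corr: np.ndarray, i: int) -> float:
    """Subpixel offset of a correlation peak by quadratic interpolation."""
    if i == 0 or i == corr.size - 1:
        return 0.0
    y0, y1, y2 = corr[i - 1], corr[i], corr[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return 0.0
    return float(0.5 * (y0 - y2) / denom)


def axial_motion_correct(series: BScanSeries, max_shift_px: float = 10.0
                         ) -> tuple[BScanSeries, np.ndarray]:
    """Align each repeat axially to the first repeat by cross-correlation.

    Each repeat's axial (depth) shift is estimated from the cross-correlation
    of its laterally averaged depth profile against the first repeat's, with
    quadratic interpolation of the correlation peak for subpixel precision,
    and applied by linear interpolation (real and imaginary parts).  Returns
    the corrected series and the applied shifts (one per repeat; shift 0 for
    the reference).  Shifts are clipped to ``±max_shift_px``.
    """
    if series.n_repeats < 2:
        raise ValueError("motion correction needs >= 2 repeats")
    mag = np.abs(series.data)
    profiles = mag.mean(axis=2)            # (repeat, depth)
    ref = profiles[0] - profiles[0].mean()
    if np.all(profiles[0] == 0):
        warnings.warn("reference repeat is all zero; no correction applied")
        return series, np.zeros(series.n_repeats)

    max_lag = int(np.ceil(max_shift_px))
    lags = np.arange(-max_lag, max_lag + 1)
    shifts = np.zeros(series.n_repeats)
    out = np.array(series.data, copy=True)
    for r in range(1, series.n_repeats):
        p = profiles[r] - profiles[r].mean()
        if np.all(profiles[r] == 0):
            warnings.warn(f"repeat {r} is all zero; zero shift assumed")
            continue
        corr = np.array([np.dot(np.roll(p, -lag), ref) for lag in lags])
        i = int(np.argmax(corr))
        lag = lags[i] + _parabolic_refine(corr, i)
        shift = float(np.clip(-lag, -max_shift_px, max_shift_px))
        shifts[r] = shift
        if shift != 0.0:
            out[r] = (ndimage.shift(series.data[r].real, (shift, 0.0), order=1,
                                    mode="nearest")
                      + 1j * ndimage.shift(series.data[r].imag, (shift, 0.0),
                                           order=1, mode="nearest"))
    corrected = BScanSeries(data=out, pixel_size_um=series.pixel_size_um,
                            frame_index=series.frame_index,
                            lateral_location_index=series.lateral_location_index)
    return corrected, shifts


def crop_roi(frame, depth_interval_um: tuple[float, float]):
    """Crop a frame to a half-open depth interval [top, bottom) in microns.

    The interval must lie within the frame; rows are selected as
    [round(top/dz), round(bottom/dz)).
    """
    top, bottom = depth_interval_um
    dz = frame.pixel_size_um[0]
    n_rows = frame.values.shape[0]
    if top < 0 or bottom <= top:
        raise ValueError("need 0 <= top < bottom")
    if bottom > n_rows * dz + 1e-9:
        raise ValueError(
            f"depth interval [{top}, {bottom}) um exceeds frame depth "
            f"{n_rows * dz} um")
    r0, r1 = int(round(top / dz)), int(round(bottom / dz))
    cropped = dataclasses.replace(frame, values=frame.values[r0:r1])
    if isinstance(cropped, AngiogramFrame):
        cropped.provenance = dict(frame.provenance, roi_um=(top, bottom))
    return cropped
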