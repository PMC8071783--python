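"""Diameter-binned vessel segmentation of angiogram frames.

Multilevel Otsu thresholding (3 classes, 256-bin histogram) splits an
angiogram into background, low-contrast and high-contrast pixels.  Connected
components of the high-contrast pixels are binned by equivalent-circle
diameter d = 2*sqrt(area/pi) into medium (10-20 um) and large (>20 um)
vessel cross-sections.  Pixels above the lower ("non-zero flow") threshold
that do not overlap the resolved vessel populations are attributed to
vessels below the resolution limit (< 10 um); a configurable guard ring
(default 2 px, the reach of a resolved vessel's partial-volume halo) around
the resolved masks keeps their edges out of the small mask.  Masks are typically built once from the time-averaged baseline
angiogram and applied to every frame of a trial.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .angiography import AngiogramFrame

__all__ = [
    "ComponentRecord", "VesselMaskSet", "otsu_multithreshold",
    "segment_vessels", "apply_masks",
]

CLASSES = ("small", "medium", "large")


def otsu_multithreshold(frame, n_classes: int = 3, nbins: int = 256) -> np.ndarray:
    """Otsu thresholds maximizing between-class variance over the histogram.

    Returns ``n_classes - 1`` thresholds.  Raises ``ValueError`` on frames
    with fewer distinct values than classes (no thresholds exist).
    """
    values = frame.values if isinstance(frame, AngiogramFrame) else np.asarray(frame)
    if np.unique(values).size < n_classes:
        raise ValueError("frame needs at least n_classes distinct values")
    return filters.threshold_multiotsu(values, classes=n_classes, nbins=nbins)


@dataclasses.dataclass(frozen=True)
class ComponentRecord:
    label: int
    vessel_class: str
    equivalent_diameter_um: float
    pixel_count: int
    centroid_px: tuple[float, float]


@dataclasses.dataclass
class VesselMaskSet:
    """Binary masks for the three diameter classes plus component records."""

    masks: dict[str, np.ndarray]
    components: list[ComponentRecord]
    thresholds: np.ndarray
    pixel_size_um: tuple[float, float]
    source: str = ""

    def __post_init__(self) -> None:
        for a in CLASSES:
            if a not in self.masks:
                raise ValueError(f"missing mask for class {a!r}")
        shape = self.masks["small"].shape
        for cls in CLASSES:
            if self.masks[cls].shape != shape:
                raise ValueError("class masks must share geometry")
        for i, a in enumerate(CLASSES):
            for b in CLASSES[i + 1:]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"masks {a!r} and {b!r} overlap")

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks["small"].shape

    def pixel_counts(self) -> dict[str, int]:
        return {cls: int(self.masks[cls].sum()) for cls in CLASSES}

    def to_table(self):
        """Component table as a pandas DataFrame."""
        import pandas as pd
        return pd.DataFrame([
            {"label": c.label, "class": c.vessel_class,
             "diameter_um": c.equivalent_diameter_um, "area_px": c.pixel_count,
             "centroid_z": c.centroid_px[0], "centroid_x": c.centroid_px[1]}
            for c in self.components])


def _equivalent_diameter_um(area_px: int, pixel_size_um) -> float:
    px_area = pixel_size_um[0] * pixel_size_um[1]
    return 2.0 * np.sqrt(area_px * px_area / np.pi)


def segment_vessels(frame: AngiogramFrame,
                    diameter_bins_um: tuple[float, float] = (10.0, 20.0),
                    min_flow_quantile: Optional[float] = None,
                    exclusion_dilation_px: int = 2,
                    source: str = "") -> VesselMaskSet:
    """Segment an angiogram frame into diameter-binned vessel masks.

    ``frame`` should be the time-averaged (or single) angiogram over the
    ROI.  The small-class "non-zero flow" gate defaults to the lower Otsu
    threshold; pass ``min_flow_quantile`` to gate at a frame-value quantile
    instead.  Returns empty masks with a warning when nothing exceeds the
    thresholds (or the frame is constant).
    """
    values = frame.values
    if values.size == 0:
        raise ValueError("empty frame")
    empty = {cls: np.zeros(values.shape, dtype=bool) for cls in CLASSES}
    if np.ptp(values) == 0:
        warnings.warn("constant frame: no vessels segmented")
        return VesselMaskSet(masks=empty, components=[],
                             thresholds=np.array([]),
                             pixel_size_um=frame.pixel_size_um, source=source)

    thresholds = otsu_multithreshold(frame, n_classes=3)
    t_low, t_high = float(thresholds[0]), float(thresholds[-1])
    gate = (float(np.quantile(values, min_flow_quantile))
            if min_flow_quantile is not None else t_low)

    cores = values > t_high
    if not cores.any():
        warnings.warn("no suprathreshold pixels: empty mask set")
        return VesselMaskSet(masks=empty, components=[], thresholds=thresholds,
                             pixel_size_um=frame.pixel_size_um, source=source)

    labels = measure.label(cores, connectivity=2)  # 8-connected
    lo, hi = diameter_bins_um
    medium = np.zeros(values.shape, dtype=bool)
    large = np.zeros(values.shape, dtype=bool)
    components: list[ComponentRecord] = []
    for region in measure.regionprops(labels):
        d_um = _equivalent_diameter_um(region.area, frame.pixel_size_um)
        if d_um < lo:
            continue  # bright but unresolved: falls through to the small mask
        cls = "medium" if d_um <= hi else "large"
        target = medium if cls == "medium" else large
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        target[rr, cc] = True
        components.append(ComponentRecord(
            label=region.label, vessel_class=cls, equivalent_diameter_um=d_um,
            pixel_count=int(region.area),
            centroid_px=(float(region.centroid[0]), float(region.centroid[1]))))

    resolved = medium | large
    if exclusion_dilation_px > 0:
        structure = np.ones((3, 3), dtype=bool)
        excluded = ndimage.binary_dilation(resolved, structure=structure,
                                           iterations=exclusion_dilation_px)
    else:
        excluded = resolved
    small = (values > gate) & ~excluded

    label_offset = labels.max()
    for region in measure.regionprops(measure.label(small, connectivity=2)):
        components.append(ComponentRecord(
            label=label_offset + region.label, vessel_class="small",
            equivalent_diameter_um=_equivalent_diameter_um(
                region.area, frame.pixel_size_um),
            pixel_count=int(region.area),
            centroid_px=(float(region.centroid[0]), float(region.centroid[1]))))

    return VesselMaskSet(masks={"small": small, "medium": medium, "large": large},
                         components=components, thresholds=thresholds,
                         pixel_size_um=frame.pixel_size_um, source=source)


def apply_masks(frames: Sequence, masks: VesselMaskSet) -> dict[str, np.ndarray]:
    """Per-class, per-frame sums of angiogram values inside each class mask."""
    out = {cls: [] for cls in CLASSES}
    for frame in frames:
        values = frame.values if isinstance(frame, AngiogramFrame) else np.asarray(frame)
        if values.shape != masks.shape:
            raise ValueError(f"frame shape {values.shape} does not match mask "
                             f"shape {masks.shape}")
        for cls in CLASSES:
            out[cls].append(float(values[masks.masks[cls]].sum()))
    return {cls: np.asarray(v) for cls, v in out.items()}
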