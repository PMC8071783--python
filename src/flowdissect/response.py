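"""Baseline-normalized relative-flow waveforms and their averaging.

A flow waveform is a dimensionless time series normalized so that its mean
over the pre-stimulus baseline window equals 1; values are then read as
relative blood flow.  Waveforms from repeated stimulus presentations on the
same time grid are averaged pointwise, and waveforms from different
modalities (e.g. the 4.4-Hz diffuse channel vs the 0.46-s composite-frame
grid) are compared after linear resampling onto a common grid.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "WaveformSource", "FlowWaveform", "normalize_to_baseline",
    "average_presentations", "extract_class_response", "resample_to_grid",
]


@dataclasses.dataclass(frozen=True)
class WaveformSource:
    modality: str = "OCT-A"            # "OCT-A" or "DCS"
    vessel_class: Optional[str] = None
    stimulus_current_ma: Optional[float] = None
    animal_id: Optional[str] = None
    presentation: Optional[int] = None

    def key(self) -> tuple:
        """Identity ignoring the presentation index (averaging compatibility)."""
        return (self.modality, self.vessel_class, self.stimulus_current_ma,
                self.animal_id)


@dataclasses.dataclass
class FlowWaveform:
    times: np.ndarray                     # seconds, strictly increasing
    values: np.ndarray                    # relative flow, baseline ~ 1
    baseline_window: tuple[float, float]  # [t0, t1) seconds
    stim_window: tuple[float, float]      # [onset, onset + duration] seconds
    n_averaged: int = 1
    source: WaveformSource = dataclasses.field(default_factory=WaveformSource)
    sem: Optional[np.ndarray] = None      # standard error per time point

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")

    def baseline_mask(self) -> np.ndarray:
        t0, t1 = self.baseline_window
        return (self.times >= t0) & (self.times < t1)

    def baseline_mean(self) -> float:
        sel = self.baseline_mask()
        if sel.sum() < 2:
            raise ValueError("need >= 2 samples inside the baseline window")
        return float(self.values[sel].mean())


def normalize_to_baseline(raw: FlowWaveform) -> FlowWaveform:
    """Divide a raw signal by its baseline-window mean (idempotent).

    Raises ``ValueError`` if fewer than two samples fall in the window or
    the baseline mean is not positive (the signal cannot be read as flow).
    """
    mean = raw.baseline_mean()
    if mean <= 0:
        raise ValueError("baseline mean must be > 0 to normalize to relative flow")
    return dataclasses.replace(
        raw, values=raw.values / mean,
        sem=None if raw.sem is None else np.asarray(raw.sem) / mean)


def average_presentations(waveforms: Sequence[FlowWaveform]) -> FlowWaveform:
    """Pointwise mean over stimulus presentations sharing a time grid.

    All inputs must share the time grid, windows and source identity (apart
    from the presentation index).  ``n_averaged`` accumulates, and the
    standard error of the mean is retained per time point.
    """
    if not waveforms:
        raise ValueError("no waveforms to average")
    ref = waveforms[0]
    for w in waveforms[1:]:
        if w.times.shape != ref.times.shape or not np.allclose(w.times, ref.times):
            raise ValueError("waveforms are on different time grids")
        if w.source.key() != ref.source.key():
            raise ValueError("waveforms come from different sources")
    stack = np.stack([w.values for w in waveforms])
    n = len(waveforms)
    sem = (stack.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else None
    source = dataclasses.replace(ref.source, presentation=None)
    return FlowWaveform(times=ref.times.copy(), values=stack.mean(axis=0),
                        baseline_window=ref.baseline_window,
                        stim_window=ref.stim_window,
                        n_averaged=sum(w.n_averaged for w in waveforms),
                        source=source, sem=sem)


def extract_class_response(frames, masks, protocol,
                           source: Optional[WaveformSource] = None
                           ) -> dict[str, FlowWaveform]:
    """Masked sums per frame, baseline-normalized per vessel class.

    ``frames`` is the trial's sequence of angiogram frames (one per
    composite frame), ``masks`` a :class:`~flowdissect.segmentation.VesselMaskSet`
    built over the same geometry.  Timestamps are the protocol's frame
    centers; normalization is per class over the protocol baseline window.
    """
    from .segmentation import apply_masks  # local import avoids a cycle

    raw_sums = apply_masks(frames, masks)
    times = protocol.frame_times
    out = {}
    for cls, sums in raw_sums.items():
        if sums.size != times.size:
            raise ValueError("frame count does not match the protocol")
        src = dataclasses.replace(source or WaveformSource(), vessel_class=cls,
                                  modality="OCT-A")
        raw = FlowWaveform(times=times, values=sums,
                           baseline_window=protocol.baseline_window,
                           stim_window=protocol.stim_window, source=src)
        out[cls] = normalize_to_baseline(raw)
    return out


def resample_to_grid(waveform: FlowWaveform, target_times: np.ndarray
                     ) -> FlowWaveform:
    """Linear interpolation onto ``target_times`` (no extrapolation)."""
    target = np.asarray(target_times, dtype=float)
    if target.min() < waveform.times[0] - 1e-12 or (
            target.max() > waveform.times[-1] + 1e-12):
        raise ValueError("target grid extends beyond the waveform span")
    values = np.interp(target, waveform.times, waveform.values)
    return dataclasses.replace(waveform, times=target, values=values, sem=None)
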