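"""Acquisition protocol: stimulus and frame timing shared by every pipeline stage.

The default protocol describes a 30-s somatosensory stimulation acquisition:
a train of 12 current pulses at 3 Hz (4 s total) starting 5 s in, imaged as
65 composite B-scan frames (one per 0.46 s, 32 repeated B-scans each) with a
concurrent diffuse-correlation flow channel sampled at 4.4 Hz.  The first
nine frames (~4 s) precede the stimulus and serve as the normalization
baseline.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = ["AcquisitionProtocol", "ProtocolError", "make_protocol"]


class ProtocolError(ValueError):
    """Raised when a protocol configuration violates a timing invariant."""


@dataclasses.dataclass(frozen=True)
class AcquisitionProtocol:
    total_duration: float = 30.0          # s
    stim_onset: float = 5.0               # s after acquisition start
    stim_pulses: int = 12                 # pulses per train
    stim_rate: float = 3.0                # Hz
    stim_duration: float = 4.0            # s (pulse-train span)
    composite_frame_period: float = 0.46  # s per composite B-scan frame
    n_frames: int = 65
    n_baseline_frames: int = 9
    n_repeats_per_frame: int = 32         # repeated B-scans per composite frame
    dcs_rate: float = 4.4                 # Hz
    n_stim_presentations: int = 10

    def __post_init__(self) -> None:
        counts = {
            "stim_pulses": self.stim_pulses,
            "n_frames": self.n_frames,
            "n_baseline_frames": self.n_baseline_frames,
            "n_repeats_per_frame": self.n_repeats_per_frame,
            "n_stim_presentations": self.n_stim_presentations,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ProtocolError(f"{name} must be a positive integer, got {value!r}")
        for name in ("total_duration", "stim_onset", "stim_duration",
                     "composite_frame_period", "stim_rate", "dcs_rate"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be > 0")
        if self.n_frames * self.composite_frame_period < (
                self.total_duration - self.composite_frame_period):
            raise ProtocolError(
                "n_frames x composite_frame_period must cover the acquisition "
                "(>= total_duration - one frame period)")
        if self.stim_onset + self.stim_duration >= self.total_duration:
            raise ProtocolError("stimulus must end before the acquisition does")
        if self.n_baseline_frames * self.composite_frame_period > self.stim_onset:
            raise ProtocolError("baseline frames must all precede the stimulus onset")

    # -- timing helpers -------------------------------------------------

    @property
    def frame_times(self) -> np.ndarray:
        """Composite-frame timestamps (frame centers), seconds."""
        idx = np.arange(self.n_frames)
        return (idx + 0.5) * self.composite_frame_period

    @property
    def baseline_window(self) -> tuple[float, float]:
        """Half-open [0, t) window covering the baseline frames, seconds."""
        return (0.0, self.n_baseline_frames * self.composite_frame_period)

    @property
    def stim_window(self) -> tuple[float, float]:
        return (self.stim_onset, self.stim_onset + self.stim_duration)

    @property
    def stim_frames(self) -> np.ndarray:
        """0-based indices of frames starting within the stimulus window.

        A frame i (starting at i*period) counts as a stimulus frame when
        onset <= i*period < onset + duration; at defaults this yields frames
        11..19, conventionally reported 1-based as "frames ~11 to 20".
        """
        starts = np.arange(self.n_frames) * self.composite_frame_period
        on, off = self.stim_window
        return np.nonzero((starts >= on) & (starts < off))[0]

    @property
    def n_dcs_samples(self) -> int:
        return math.floor(self.total_duration * self.dcs_rate)

    @property
    def dcs_times(self) -> np.ndarray:
        """Diffuse-flow channel timestamps, seconds."""
        return np.arange(self.n_dcs_samples) / self.dcs_rate


def make_protocol(**overrides: float) -> AcquisitionProtocol:
    """Build an :class:`AcquisitionProtocol`, applying overrides to defaults.

    Raises :class:`ProtocolError` on unknown field names or invariant
    violations.
    """
    known = {f.name for f in dataclasses.fields(AcquisitionProtocol)}
    unknown = set(overrides) - known
    if unknown:
        raise ProtocolError(f"unknown protocol field(s): {sorted(unknown)}")
    return AcquisitionProtocol(**overrides)
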