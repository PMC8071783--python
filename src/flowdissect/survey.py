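"""Coarse en-face survey of evoked flow used to locate the activation centroid.

A survey volume samples one lateral axis densely (250 A-scans over 1 mm) and
the perpendicular axis coarsely (10 B-scan locations over 1 mm), with
repeated stimulus presentations per location.  The reduction to a survey
video runs four steps per location, in order:

1. average the angiogram frames over the presentations;
2. accumulate (sum) pixel values in 10 (width) x 100 (depth) blocks,
   reducing each B-scan to a 25-sample vector;
3. normalize each of the 65 vectors per element to the average of the first
   nine (pre-stimulus baseline) vectors;
4. expand the 10 coarse locations to 25 by interpolation (linear by
   default; nearest-neighbor available).

The result is a 65-frame, 25 x 25 relative-flow video at defaults.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .angiography import AngiogramFrame
from .protocol import AcquisitionProtocol

__all__ = ["SurveyVideo", "block_reduce_bscan", "build_survey", "peak_location"]


@dataclasses.dataclass
class SurveyVideo:
    """Relative-flow survey frames (n_frames x coarse x dense)."""

    frames: np.ndarray
    frame_period: float
    grid: dict = dataclasses.field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _as_array(frame) -> np.ndarray:
    return frame.values if isinstance(frame, AngiogramFrame) else np.asarray(frame)


def block_reduce_bscan(image: np.ndarray, block_width: int = 10,
                       block_depth: int = 100) -> np.ndarray:
    """Sum a (depth x lateral) B-scan image into a lateral block vector.

    Accumulates all pixel values in ``block_width x block_depth`` regions:
    the first ``block_depth`` depth rows are summed whole, and the lateral
    axis is summed in consecutive ``block_width`` bins.  Total signal is
    conserved: the vector sums to the sum of the reduced region.
    """
    if image.shape[0] < block_depth:
        raise ValueError(f"need >= {block_depth} depth pixels, got {image.shape[0]}")
    if image.shape[1] % block_width != 0:
        raise ValueError(f"lateral size {image.shape[1]} is not a multiple of "
                         f"block width {block_width}")
    region = image[:block_depth]
    n_blocks = image.shape[1] // block_width
    return region.reshape(block_depth, n_blocks, block_width).sum(axis=(0, 2))


def build_survey(location_stacks: Sequence[Sequence[Sequence]],
                 protocol: AcquisitionProtocol,
                 block_width: int = 10, block_depth: int = 100,
                 n_ascans: int = 250, n_coarse_out: int = 25,
                 interpolation: str = "linear") -> SurveyVideo:
    """Build the en-face response survey video from per-location trial stacks.

    ``location_stacks[loc][presentation][frame]`` is an angiogram frame
    (:class:`AngiogramFrame` or array) of shape (depth, ``n_ascans``).
    """
    n_locations = len(location_stacks)
    if n_locations < 2:
        raise ValueError("need >= 2 B-scan locations to build a survey")
    n_frames = protocol.n_frames
    n_dense = n_ascans // block_width

    reduced = np.empty((n_locations, n_frames, n_dense))
    for li, presentations in enumerate(location_stacks):
        if len(presentations) < 1:
            raise ValueError(f"location {li} has no presentations")
        for pres in presentations:
            if len(pres) != n_frames:
                raise ValueError(
                    f"location {li}: expected {n_frames} frames per "
                    f"presentation, got {len(pres)}")
        for fi in range(n_frames):
            frame = np.mean([_as_array(pres[fi]) for pres in presentations],
                            axis=0)
            if frame.shape[1] != n_ascans:
                raise ValueError(
                    f"location {li} frame {fi}: expected {n_ascans} A-scans, "
                    f"got {frame.shape[1]}")
            reduced[li, fi] = block_reduce_bscan(frame, block_width, block_depth)

    baseline = reduced[:, :protocol.n_baseline_frames].mean(axis=1)
    if np.any(baseline <= 0):
        raise ValueError("baseline block values must be positive to normalize")
    normalized = reduced / baseline[:, None, :]

    coarse_in = np.arange(n_locations, dtype=float)
    coarse_out = np.linspace(0.0, n_locations - 1.0, n_coarse_out)
    if interpolation == "linear":
        frames = np.empty((n_frames, n_coarse_out, n_dense))
        for fi in range(n_frames):
            for di in range(n_dense):
                frames[fi, :, di] = np.interp(coarse_out, coarse_in,
                                              normalized[:, fi, di])
    elif interpolation == "nearest":
        idx = np.rint(coarse_out).astype(int)
        frames = normalized[idx].transpose(1, 0, 2)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")

    return SurveyVideo(
        frames=frames, frame_period=protocol.composite_frame_period,
        grid={"n_dense_locations_out": n_dense, "n_coarse_in": n_locations,
              "n_coarse_out": n_coarse_out,
              "block_px": (block_width, block_depth),
              "interpolation": interpolation})


def peak_location(survey: SurveyVideo) -> tuple[int, int, int]:
    """(frame, coarse, dense) index of the survey's maximum relative flow."""
    return tuple(int(i) for i in
                 np.unravel_index(np.argmax(survey.frames), survey.frames.shape))
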