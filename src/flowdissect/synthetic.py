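"""Synthetic acquisition generator with known ground truth.

Emulates the raw unit the angiography pipeline consumes: stacks of repeated
complex B-scans over a field of static speckle parenchyma with embedded
vessel cross-sections (filled disks), plus a diffuse-flow (DCS-like) channel
sharing the same ground-truth response.

Forward contrast model
----------------------
Each pixel's complex signal per repeat is

    S_r = (1 - cov) * P  +  sum_v cov_v * d_v * flow_v * w_(v,r)  +  sigma_n * n_r

where ``P`` is a static complex speckle field (drawn once per scene),
``cov_v`` is the vessel's subpixel coverage fraction of the pixel, ``d_v``
its baseline decorrelation amplitude, ``w_(v,r)`` unit circular complex
Gaussian speckle redrawn independently for every repeat (blood is fully
decorrelated between repeats), and ``n_r`` circular complex detector noise.
The expected average absolute magnitude difference between consecutive
repeats then grows like sqrt((cov*d*flow)^2 + sigma_n^2 [+ static terms]),
i.e. it is monotone in flow and, away from the noise floor, locally
proportional to it — so the baseline-normalized angiogram readout is a
faithful relative flow measure.

Flow is modulated in time by a ground-truth double-gamma response per
vessel: flow(t) = 1 + response.curve(t - stim_onset).
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from .angiography import BScanSeries
from .hrf import GroundTruthResponse
from .protocol import AcquisitionProtocol
from .response import FlowWaveform, WaveformSource

__all__ = [
    "VesselSpec", "SceneConfig", "diameter_class", "DIAMETER_BINS_UM",
    "simulate_bscan_series", "simulate_trial", "iter_trial_series",
    "trial_flow_truth", "simulate_dcs_waveform",
]

DIAMETER_BINS_UM = (10.0, 20.0)
_SUPERSAMPLE = 4  # subpixel grid per axis for disk coverage fractions


def diameter_class(diameter_um: float,
                   bins: tuple[float, float] = DIAMETER_BINS_UM) -> str:
    """Bin a vessel diameter into small (<10), medium ([10, 20]), large (>20) um."""
    lo, hi = bins
    if diameter_um < lo:
        return "small"
    if diameter_um <= hi:
        return "medium"
    return "large"


@dataclasses.dataclass(frozen=True)
class VesselSpec:
    """One vessel cross-section: a filled disk in the B-scan plane."""

    center_um: tuple[float, float]        # (depth, lateral) of the disk center
    diameter_um: float
    baseline_decorrelation: float         # dynamic speckle amplitude at flow = 1
    response: GroundTruthResponse
    class_truth: Optional[str] = None

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("vessel diameter must be > 0")
        if not 0.0 <= self.baseline_decorrelation <= 1.0:
            raise ValueError("baseline_decorrelation must be in [0, 1]")
        expected = diameter_class(self.diameter_um)
        if self.class_truth is None:
            object.__setattr__(self, "class_truth", expected)
        elif self.class_truth != expected:
            raise ValueError(
                f"class_truth {self.class_truth!r} inconsistent with diameter "
                f"{self.diameter_um} um (binning gives {expected!r})")


class SceneConfig:
    """Imaging field geometry, vessels and noise levels for the generator.

    Parameters
    ----------
    shape_px : (depth_px, lateral_px) field size in pixels.
    pixel_size_um : microns per pixel, (depth, lateral); default 4 um both.
    vessels : vessel cross-sections; disks must fit inside the field and not
        overlap one another.
    parenchyma_noise_sd : amplitude of the static tissue speckle field.
    detector_noise_sd : per-repeat circular complex detector noise amplitude.
    rng_seed : seeds the static speckle field (fixed scene realization).
    """

    def __init__(self, shape_px: tuple[int, int] = (100, 250),
                 pixel_size_um: tuple[float, float] = (4.0, 4.0),
                 vessels: Sequence[VesselSpec] = (),
                 parenchyma_noise_sd: float = 0.3,
                 detector_noise_sd: float = 0.05,
                 rng_seed: int = 0) -> None:
        if parenchyma_noise_sd < 0 or detector_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        self.shape_px = (int(shape_px[0]), int(shape_px[1]))
        self.pixel_size_um = (float(pixel_size_um[0]), float(pixel_size_um[1]))
        self.vessels = list(vessels)
        self.parenchyma_noise_sd = float(parenchyma_noise_sd)
        self.detector_noise_sd = float(detector_noise_sd)
        self.rng_seed = int(rng_seed)
        self._validate_geometry()
        self._coverage: Optional[list] = None
        self._static_field: Optional[np.ndarray] = None

    def _validate_geometry(self) -> None:
        dz, dx = self.pixel_size_um
        depth_um = self.shape_px[0] * dz
        lateral_um = self.shape_px[1] * dx
        for v in self.vessels:
            r = v.diameter_um / 2.0
            cz, cx = v.center_um
            if not (r <= cz <= depth_um - r and r <= cx <= lateral_um - r):
                raise ValueError(f"vessel at {v.center_um} um does not fit the "
                                 f"{depth_um} x {lateral_um} um field")
        for i, a in enumerate(self.vessels):
            for b in self.vessels[i + 1:]:
                dist = np.hypot(a.center_um[0] - b.center_um[0],
                                a.center_um[1] - b.center_um[1])
                if dist < (a.diameter_um + b.diameter_um) / 2.0:
                    raise ValueError("vessel cross-sections overlap")

    # -- cached geometry / static speckle -------------------------------

    def coverage(self) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-vessel (depth_idx, lateral_idx, coverage_fraction) arrays."""
        if self._coverage is None:
            self._coverage = [self._disk_coverage(v) for v in self.vessels]
        return self._coverage

    def _disk_coverage(self, v: VesselSpec):
        dz, dx = self.pixel_size_um
        r = v.diameter_um / 2.0
        cz, cx = v.center_um
        i0 = max(int((cz - r) / dz) - 1, 0)
        i1 = min(int((cz + r) / dz) + 2, self.shape_px[0])
        j0 = max(int((cx - r) / dx) - 1, 0)
        j1 = min(int((cx + r) / dx) + 2, self.shape_px[1])
        s = _SUPERSAMPLE
        off = (np.arange(s) + 0.5) / s
        ii, jj, cov = [], [], []
        for i in range(i0, i1):
            zs = (i + off) * dz
            for j in range(j0, j1):
                xs = (j + off) * dx
                d2 = (zs[:, None] - cz) ** 2 + (xs[None, :] - cx) ** 2
                frac = float(np.mean(d2 <= r * r))
                if frac > 0:
                    ii.append(i)
                    jj.append(j)
                    cov.append(frac)
        return (np.asarray(ii, dtype=int), np.asarray(jj, dtype=int),
                np.asarray(cov, dtype=float))

    def coverage_flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """All vessel pixels concatenated: (depth_idx, lateral_idx, coverage, vessel_idx)."""
        if not self.vessels:
            z = np.zeros(0, dtype=int)
            return z, z, np.zeros(0), z
        cov = self.coverage()
        ii = np.concatenate([c[0] for c in cov])
        jj = np.concatenate([c[1] for c in cov])
        frac = np.concatenate([c[2] for c in cov])
        vid = np.concatenate([np.full(c[0].size, k, dtype=int)
                              for k, c in enumerate(cov)])
        return ii, jj, frac, vid

    def static_field(self) -> np.ndarray:
        """Static complex parenchyma speckle, attenuated under vessel disks."""
        if self._static_field is None:
            rng = np.random.default_rng(np.random.SeedSequence(self.rng_seed))
            g = rng.standard_normal((2,) + self.shape_px, dtype=np.float32)
            field = ((self.parenchyma_noise_sd / np.sqrt(2.0))
                     * (g[0] + 1j * g[1])).astype(np.complex64)
            for ii, jj, cov in self.coverage():
                field[ii, jj] *= (1.0 - cov)
            self._static_field = field
        return self._static_field

    def vessel_indices_by_class(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {"small": [], "medium": [], "large": []}
        for k, v in enumerate(self.vessels):
            out[v.class_truth].append(k)
        return out


def _resolve_flow_levels(scene: SceneConfig, flow_levels) -> np.ndarray:
    n = len(scene.vessels)
    if isinstance(flow_levels, Mapping):
        unknown = set(flow_levels) - set(range(n))
        if unknown:
            raise KeyError(f"unknown vessel key(s): {sorted(unknown)}")
        flows = np.ones(n)
        for k, f in flow_levels.items():
            flows[k] = f
    else:
        flows = np.asarray(flow_levels, dtype=float)
        if flows.shape != (n,):
            raise ValueError(f"flow_levels must have one entry per vessel ({n})")
    if np.any(flows < 0):
        raise ValueError("flow levels must be >= 0")
    return flows


def simulate_bscan_series(scene: SceneConfig, flow_levels, repeats: int,
                          rng: np.random.Generator, frame_index: int = 0,
                          lateral_location_index: int = 0) -> BScanSeries:
    """Simulate one stack of repeated complex B-scans at given vessel flows.

    ``flow_levels`` is either a mapping {vessel index: flow} (unlisted
    vessels default to baseline flow 1) or an array with one entry per
    vessel.  Flow 0 freezes a vessel (its pixels carry only static signal
    and detector noise).
    """
    if repeats < 2:
        raise ValueError("need >= 2 repeats")
    flows = _resolve_flow_levels(scene, flow_levels)
    d, l = scene.shape_px

    base = scene.static_field()
    g = rng.standard_normal((2, repeats, d, l), dtype=np.float32)
    data = base[None, :, :] + np.complex64(
        scene.detector_noise_sd / np.sqrt(2.0)) * (g[0] + 1j * g[1])
    ii, jj, cov, vid = scene.coverage_flat()
    if ii.size:
        decors = np.array([v.baseline_decorrelation for v in scene.vessels])
        amp = ((decors[vid] * flows[vid] * cov) / np.sqrt(2.0)).astype(np.float32)
        w = rng.standard_normal((2, repeats, ii.size), dtype=np.float32)
        data[:, ii, jj] += amp[None, :] * (w[0] + 1j * w[1])
    return BScanSeries(data=data, pixel_size_um=scene.pixel_size_um,
                       frame_index=frame_index,
                       lateral_location_index=lateral_location_index)


def trial_flow_truth(protocol: AcquisitionProtocol, scene: SceneConfig
                     ) -> dict[int, np.ndarray]:
    """Ground-truth relative flow per vessel at each composite frame center."""
    t = protocol.frame_times - protocol.stim_onset
    return {k: 1.0 + v.response.curve(t) for k, v in enumerate(scene.vessels)}


def iter_trial_series(protocol: AcquisitionProtocol, scene: SceneConfig,
                      rng: np.random.Generator,
                      lateral_location_index: int = 0) -> Iterator[BScanSeries]:
    """Stream the ``n_frames`` B-scan stacks of one trial (memory-light)."""
    truth = trial_flow_truth(protocol, scene)
    flows = np.ones(len(scene.vessels))
    for f in range(protocol.n_frames):
        for k in truth:
            flows[k] = truth[k][f]
        yield simulate_bscan_series(scene, flows, protocol.n_repeats_per_frame,
                                    rng, frame_index=f,
                                    lateral_location_index=lateral_location_index)


def simulate_trial(protocol: AcquisitionProtocol, scene: SceneConfig,
                   rng: np.random.Generator, lateral_location_index: int = 0
                   ) -> tuple[list[BScanSeries], dict[int, np.ndarray]]:
    """Simulate one stimulus presentation: all frames plus per-vessel truth.

    Materializes every stack; for large scenes prefer
    :func:`iter_trial_series`.
    """
    series = list(iter_trial_series(protocol, scene, rng,
                                    lateral_location_index))
    return series, trial_flow_truth(protocol, scene)


def simulate_dcs_waveform(protocol: AcquisitionProtocol,
                          response: GroundTruthResponse, noise_sd: float,
                          rng: np.random.Generator) -> FlowWaveform:
    """Diffuse-flow channel: 1 + ground-truth response + i.i.d. noise at 4.4 Hz."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = protocol.dcs_times
    values = 1.0 + response.curve(t - protocol.stim_onset)
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(t.size)
    return FlowWaveform(times=t, values=values,
                        baseline_window=protocol.baseline_window,
                        stim_window=protocol.stim_window,
                        source=WaveformSource(modality="DCS"))
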