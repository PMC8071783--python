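"""File formats: HDF5 B-scan stacks, TIFF exports, CSV waveforms, YAML config.

HDF5 is the primary volume container: one ``frames`` dataset of complex64
with axes (frame, repeat, depth, lateral) plus pixel-scale and protocol
metadata attributes; the round trip is lossless at complex64 precision.
TIFF export writes magnitudes only (documented lossy).  Waveforms travel as
tidy CSV with one row per time point.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .angiography import AngiogramFrame, BScanSeries
from .protocol import AcquisitionProtocol, make_protocol
from .response import FlowWaveform, WaveformSource

__all__ = [
    "write_stack", "read_stack", "write_magnitude_tiff", "write_frames_tiff",
    "waveforms_to_frame", "write_waveforms_csv", "read_waveforms_csv",
    "load_config", "save_config",
]

_AXES = "frame,repeat,depth,lateral"


def write_stack(path, series_seq: Sequence[BScanSeries],
                protocol: Optional[AcquisitionProtocol] = None) -> None:
    """Write a trial's B-scan stacks to HDF5 (complex64, lossless round trip)."""
    series_seq = list(series_seq)
    if not series_seq:
        raise ValueError("no series to write")
    shapes = {s.data.shape for s in series_seq}
    if len(shapes) != 1:
        raise ValueError("all series must share (repeat, depth, lateral) shape")
    with h5py.File(path, "w") as f:
        data = np.stack([s.data for s in series_seq]).astype(np.complex64)
        ds = f.create_dataset("frames", data=data)
        ds.attrs["axes"] = _AXES
        ds.attrs["pixel_size_um"] = series_seq[0].pixel_size_um
        ds.attrs["lateral_location_index"] = [
            s.lateral_location_index for s in series_seq]
        if protocol is not None:
            ds.attrs["protocol"] = json.dumps(dataclasses.asdict(protocol))


def read_stack(path) -> tuple[list[BScanSeries], Optional[AcquisitionProtocol]]:
    """Read back a trial written by :func:`write_stack`."""
    try:
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise ValueError(
                    f"{path}: dataset 'frames' missing (axes {_AXES} expected)")
            ds = f["frames"]
            if ds.ndim != 4:
                raise ValueError(f"{path}: dataset 'frames' must be 4-D "
                                 f"({_AXES}), got {ds.ndim}-D")
            data = ds[()]
            pixel_size = tuple(float(x) for x in ds.attrs["pixel_size_um"])
            loc = list(ds.attrs.get("lateral_location_index",
                                    [0] * data.shape[0]))
            protocol = None
            if "protocol" in ds.attrs:
                protocol = make_protocol(**json.loads(ds.attrs["protocol"]))
    except OSError as exc:
        raise ValueError(f"{path}: not a readable HDF5 stack "
                         f"(dataset 'frames'): {exc}") from exc
    series = [BScanSeries(data=data[i], pixel_size_um=pixel_size,
                          frame_index=i, lateral_location_index=int(loc[i]))
              for i in range(data.shape[0])]
    return series, protocol


def write_magnitude_tiff(path, series_seq: Sequence[BScanSeries]) -> None:
    """Export repeat-stack magnitudes as multi-page float32 TIFF (lossy)."""
    pages = np.concatenate([np.abs(s.data).astype(np.float32)
                            for s in series_seq])
    tifffile.imwrite(path, pages)


def write_frames_tiff(path, frames: Sequence, sidecar: Optional[dict] = None
                      ) -> None:
    """Write angiogram/reflectance frames as multi-page float32 TIFF.

    An optional JSON sidecar (same stem, ``.json``) records provenance.
    """
    arr = np.stack([f.values if isinstance(f, AngiogramFrame) else np.asarray(f)
                    for f in frames]).astype(np.float32)
    tifffile.imwrite(path, arr)
    if sidecar is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def waveforms_to_frame(waveforms: Sequence[FlowWaveform]) -> pd.DataFrame:
    """Tidy table: one row per (waveform, time point)."""
    rows = []
    for w in waveforms:
        for i, t in enumerate(w.times):
            rows.append({
                "animal_id": w.source.animal_id, "modality": w.source.modality,
                "vessel_class": w.source.vessel_class,
                "current_ma": w.source.stimulus_current_ma,
                "time_s": float(t), "rel_flow": float(w.values[i]),
                "sem": float(w.sem[i]) if w.sem is not None else np.nan,
                "n_averaged": w.n_averaged,
                "baseline_t0": w.baseline_window[0],
                "baseline_t1": w.baseline_window[1],
                "stim_on": w.stim_window[0], "stim_off": w.stim_window[1],
            })
    return pd.DataFrame(rows)


def write_waveforms_csv(path, waveforms: Sequence[FlowWaveform]) -> None:
    waveforms_to_frame(waveforms).to_csv(path, index=False)


def read_waveforms_csv(path) -> list[FlowWaveform]:
    df = pd.read_csv(path)
    out = []
    group_cols = ["animal_id", "modality", "vessel_class", "current_ma"]
    for key, g in df.groupby(group_cols, dropna=False, sort=False):
        g = g.sort_values("time_s")
        first = g.iloc[0]
        sem = g["sem"].to_numpy()
        out.append(FlowWaveform(
            times=g["time_s"].to_numpy(), values=g["rel_flow"].to_numpy(),
            baseline_window=(first["baseline_t0"], first["baseline_t1"]),
            stim_window=(first["stim_on"], first["stim_off"]),
            n_averaged=int(first["n_averaged"]),
            source=WaveformSource(
                modality=None if pd.isna(key[1]) else key[1],
                vessel_class=None if pd.isna(key[2]) else key[2],
                stimulus_current_ma=None if pd.isna(key[3]) else float(key[3]),
                animal_id=None if pd.isna(key[0]) else key[0]),
            sem=None if np.all(np.isnan(sem)) else sem))
    return out


def save_config(path, config) -> None:
    yaml.safe_dump(dataclasses.asdict(config), open(path, "w"),
                   default_flow_style=False)


def load_config(path, config_cls):
    """Load a YAML config into ``config_cls``; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(config_cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("currents_ma", "scene_shape_px"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return config_cls(**raw)
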