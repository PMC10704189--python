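"""HDF5 channel-frame storage and detections JSON files.

Frames live under ``/frames/<id>/samples`` (float32) with ``sound_speed``
and ``snr_db`` attributes; ground truths go to a JSON sidecar next to the
HDF5 file so they stay human-readable.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .detector import detections_from_json, detections_to_json
from .evaluate import Detection
from .simulate import ChannelFrame, SourceTruth

__all__ = ["save_frames_hdf5", "load_frames_hdf5",
           "save_detections_json", "load_detections_json"]


def save_frames_hdf5(frames: list[ChannelFrame], path: str | Path) -> None:
    path = Path(path)
    truths_sidecar = {}
    with h5py.File(path, "w") as f:
        grp = f.create_group("frames")
        for frame in frames:
            fid = frame.frame_id if frame.frame_id is not None else len(truths_sidecar)
            g = grp.create_group(str(fid))
            g.create_dataset("samples", data=frame.samples.astype(np.float32))
            g.attrs["sound_speed"] = frame.sound_speed_mps
            if frame.snr_db is not None:
                g.attrs["snr_db"] = frame.snr_db
            truths_sidecar[str(fid)] = [asdict(t) for t in frame.truths]
    path.with_suffix(".truths.json").write_text(json.dumps(truths_sidecar))


def load_frames_hdf5(path: str | Path) -> list[ChannelFrame]:
    path = Path(path)
    sidecar = path.with_suffix(".truths.json")
    truths_sidecar = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    frames = []
    with h5py.File(path, "r") as f:
        for fid in sorted(f["frames"], key=int):
            g = f["frames"][fid]
            truths = [SourceTruth(**t) for t in truths_sidecar.get(fid, [])]
            frames.append(ChannelFrame(
                samples=np.asarray(g["samples"], dtype=float),
                sound_speed_mps=float(g.attrs["sound_speed"]),
                truths=truths,
                frame_id=int(fid),
                snr_db=float(g.attrs["snr_db"]) if "snr_db" in g.attrs else None,
            ))
    return frames


def save_detections_json(detections: list[Detection], path: str | Path) -> None:
    Path(path).write_text(json.dumps(detections_to_json(detections), indent=1))


def load_detections_json(path: str | Path) -> list[Detection]:
    return detections_from_json(json.loads(Path(path).read_text()))
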