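"""Build processed, annotated frames from raw channel data.

A phased-array sector image is laterally much wider than the physical
aperture, so the 8-bit channel image is first zero-padded to the
scan-converted grid (1132 x 3117 for the defaults), then resized by area
averaging to the processed size (256 x 256).  Fixed 32 x 16 pixel bounding
boxes are centered on the (possibly extrapolated) wavefront-apex positions
of sources and artifacts; boxes may extend into the zero-padded region.

Datasets are serialized as 8-bit grayscale PNGs plus COCO-style JSON
annotations (categories: source=1, artifact=2) and a split manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize_local_mean

from .geometry import (GridGeometry, ImagingConfig, InvalidConfigurationError,
                       TransducerSpec, element_positions, processed_grid,
                       scan_grid)
from .simulate import ARTIFACT, SOURCE, ChannelFrame, SourceTruth, quantize_frame

__all__ = [
    "BoxAnnotation",
    "ProcessedFrame",
    "BOX_WIDTH_PX",
    "BOX_HEIGHT_PX",
    "CATEGORY_IDS",
    "zero_pad",
    "resize_to_processed",
    "process_frame",
    "make_annotations",
    "write_dataset",
    "read_dataset",
]

BOX_WIDTH_PX = 32
BOX_HEIGHT_PX = 16
CATEGORY_IDS = {SOURCE: 1, ARTIFACT: 2}
_CATEGORY_NAMES = {v: k for k, v in CATEGORY_IDS.items()}


@dataclass(frozen=True)
class BoxAnnotation:
    """Fixed-size detection box in processed-frame pixel coordinates."""

    object_class: str
    center_col: float
    center_row: float
    width: float = BOX_WIDTH_PX
    height: float = BOX_HEIGHT_PX

    @property
    def x_min(self) -> float:
        return self.center_col - self.width / 2.0

    @property
    def y_min(self) -> float:
        return self.center_row - self.height / 2.0

    @property
    def bbox_xywh(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.width, self.height)


@dataclass
class ProcessedFrame:
    """Zero-padded, resized 8-bit frame aligned to the scan-converted FOV."""

    image: np.ndarray
    grid: GridGeometry
    channel_cols: tuple[int, int]  # half-open column interval with channel data
    frame_id: int | None = None
    annotations: list[BoxAnnotation] = field(default_factory=list)


def _lateral_resample_weights(spec: TransducerSpec, grid: GridGeometry):
    """Linear-interpolation weights from element centers to channel columns.

    Channel data occupies round(aperture / pixel_width) centered columns
    (64 elements -> 128 columns for the defaults), aligning the element
    pitch to the lateral pixel raster.  Columns outside the element span
    take the nearest element's value (edge clamp).
    """
    n_ch = int(round(spec.aperture_width_mm / grid.pixel_width_mm))
    if n_ch > grid.n_cols:
        raise InvalidConfigurationError("aperture wider than the scan grid")
    col0 = (grid.n_cols - n_ch) // 2
    x_cols = (np.arange(n_ch) + col0 - (grid.n_cols - 1) / 2.0) * grid.pixel_width_mm
    xe = element_positions(spec)
    W = np.zeros((n_ch, spec.n_elements))
    if spec.n_elements == 1:
        W[:, 0] = 1.0
        return col0, n_ch, W
    idx = np.clip(np.searchsorted(xe, x_cols) - 1, 0, spec.n_elements - 2)
    frac = (x_cols - xe[idx]) / (xe[idx + 1] - xe[idx])
    frac = np.clip(frac, 0.0, 1.0)  # edge clamp beyond the element span
    W[np.arange(n_ch), idx] = 1.0 - frac
    W[np.arange(n_ch), idx + 1] = frac
    return col0, n_ch, W


def zero_pad(frame8: np.ndarray, grid: GridGeometry,
             spec: TransducerSpec) -> tuple[np.ndarray, tuple[int, int]]:
    """Embed the 8-bit channel image in the scan-converted grid.

    Rows map 1:1; the n_elements traces are laterally resampled to the
    channel-column raster by linear interpolation and centered; every other
    pixel is exactly 0.  Returns (padded image, channel column interval).
    """
    frame8 = np.asarray(frame8)
    if frame8.shape[0] != grid.n_rows:
        raise ValueError(
            f"frame has {frame8.shape[0]} rows, grid expects {grid.n_rows}")
    col0, n_ch, W = _lateral_resample_weights(spec, grid)
    resampled = frame8.astype(float) @ W.T
    padded = np.zeros((grid.n_rows, grid.n_cols), dtype=np.uint8)
    padded[:, col0:col0 + n_ch] = np.round(np.clip(resampled, 0, 255)).astype(np.uint8)
    return padded, (col0, col0 + n_ch)


def resize_to_processed(padded: np.ndarray, processed_size: int) -> np.ndarray:
    """Area-averaged (anti-aliased) downsampling to processed_size^2, rescaled to 8-bit.

    Area averaging preserves faint waveform edges better than decimation;
    0 is preserved as 0 so the padded region stays identifiable.
    """
    if padded.size == 0:
        raise ValueError("empty image")
    small = resize_local_mean(padded.astype(float),
                              (processed_size, processed_size))
    peak = small.max()
    if peak == 0.0:
        return np.zeros((processed_size, processed_size), dtype=np.uint8)
    return np.round(255.0 * small / peak).astype(np.uint8)


def make_annotations(truths: list[SourceTruth], config: ImagingConfig,
                     spec: TransducerSpec,
                     sound_speed_mps: float | None = None) -> list[BoxAnnotation]:
    """32x16 boxes centered on each truth's apex position *within the frame*.

    Boxes mark the recorded wavefront peak: when the medium sound speed c
    differs from the nominal sound speed the frame rows are laid out with,
    a source at depth z arrives at t = z / c and therefore appears at the
    apparent depth z * c_nominal / c.  Artifact truths already carry their
    (depth-shifted) apparent position; the same sound-speed scaling applies
    on top.  Boxes whose centers fall in the zero-padded region are kept
    unclipped.
    """
    grid = processed_grid(config, spec)
    scale = (config.sound_speed_mps / sound_speed_mps
             if sound_speed_mps else 1.0)
    out = []
    for t in truths:
        col, row = grid.world_to_pixel(t.lateral_mm, t.axial_mm * scale)
        out.append(BoxAnnotation(t.object_class, float(col), float(row)))
    return out


def process_frame(frame: ChannelFrame, spec: TransducerSpec,
                  config: ImagingConfig) -> ProcessedFrame:
    """Quantize, zero-pad, resize, and annotate one channel frame."""
    grid = scan_grid(config, spec)
    padded, (c0, c1) = zero_pad(quantize_frame(frame), grid, spec)
    image = resize_to_processed(padded, config.processed_size)
    scale = config.processed_size / grid.n_cols
    channel_cols = (int(np.floor(c0 * scale)), int(np.ceil(c1 * scale)))
    return ProcessedFrame(
        image=image,
        grid=processed_grid(config, spec),
        channel_cols=channel_cols,
        frame_id=frame.frame_id,
        annotations=make_annotations(frame.truths, config, spec,
                                     sound_speed_mps=frame.sound_speed_mps),
    )


def write_dataset(frames: list[ProcessedFrame], path: str | Path,
                  train_ids: list[int] | None = None,
                  val_ids: list[int] | None = None) -> None:
    """Serialize frames as PNGs plus COCO-style annotations and a split manifest."""
    path = Path(path)
    img_dir = path / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    images, annotations = [], []
    ann_id = 1
    for pf in frames:
        fid = pf.frame_id if pf.frame_id is not None else len(images)
        name = f"frame_{fid:06d}.png"
        Image.fromarray(pf.image, mode="L").save(img_dir / name)
        h, w = pf.image.shape
        images.append({"id": int(fid), "file_name": name,
                       "width": int(w), "height": int(h),
                       "channel_cols": list(pf.channel_cols)})
        for box in pf.annotations:
            x, y, bw, bh = box.bbox_xywh
            in_padding = (box.center_col < pf.channel_cols[0]
                          or box.center_col >= pf.channel_cols[1])
            annotations.append({
                "id": ann_id, "image_id": int(fid),
                "category_id": CATEGORY_IDS[box.object_class],
                "bbox": [float(x), float(y), float(bw), float(bh)],
                "area": float(bw * bh), "iscrowd": 0,
                "in_zero_padding": bool(in_padding),
            })
            ann_id += 1
    coco = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": i, "name": n} for n, i in CATEGORY_IDS.items()],
    }
    (path / "annotations.json").write_text(json.dumps(coco))
    if train_ids is not None or val_ids is not None:
        split = {"train": list(train_ids or []), "val": list(val_ids or [])}
        (path / "split.json").write_text(json.dumps(split))


def read_dataset(path: str | Path) -> list[ProcessedFrame]:
    """Inverse of :func:`write_dataset` (lossless round trip)."""
    path = Path(path)
    ann_path = path / "annotations.json"
    if not ann_path.exists():
        raise FileNotFoundError(f"no annotations.json under {path}")
    try:
        coco = json.loads(ann_path.read_text())
    except json.JSONDecodeError as e:
        raise OSError(f"malformed annotations JSON at {ann_path}: {e}") from e
    by_image: dict[int, list[BoxAnnotation]] = {}
    for a in coco["annotations"]:
        x, y, w, h = a["bbox"]
        box = BoxAnnotation(_CATEGORY_NAMES[a["category_id"]],
                            x + w / 2.0, y + h / 2.0, w, h)
        by_image.setdefault(a["image_id"], []).append(box)
    frames = []
    for im in coco["images"]:
        img_path = path / "images" / im["file_name"]
        if not img_path.exists():
            raise OSError(f"missing image file {img_path}")
        image = np.asarray(Image.open(img_path), dtype=np.uint8)
        n = image.shape[0]
        frames.append(ProcessedFrame(
            image=image,
            grid=GridGeometry(n_rows=image.shape[0], n_cols=image.shape[1],
                              pixel_height_mm=float("nan"),
                              pixel_width_mm=float("nan")),
            channel_cols=tuple(im.get("channel_cols", (0, image.shape[1]))),
            frame_id=im["id"],
            annotations=by_image.get(im["id"], []),
        ))
    return frames
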