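"""Template-correlation baseline detector and the external-detector contract.

The baseline slides normalized cross-correlation templates — wavefront
patches synthesized by the simulator on a (lateral, depth) grid — over the
processed frame, applies non-maximum suppression, and emits fixed 32x16
boxes with confidence (score + 1) / 2.  It is a
GPU-free detector that exercises every downstream contract (detection
format, evaluation, rendering); it assigns every detection the source
class and does not attempt artifact discrimination.

External learned detectors plug in through the detections JSON schema:
a list of {frame_id, class, bbox [x, y, w, h], score} records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

from .dataset import (BOX_HEIGHT_PX, BOX_WIDTH_PX, ProcessedFrame,
                      process_frame)
from .evaluate import Detection
from .geometry import ImagingConfig, TransducerSpec
from .simulate import SOURCE, ChannelFrame, SourceTruth, synthesize_wavefront

__all__ = ["TemplateBank", "build_template_bank", "detect",
           "detections_to_json", "detections_from_json",
           "validate_detections"]

# Template patch half-sizes in processed pixels (rows x cols = 17 x 33):
# tall enough to cover the wavefront's axial extent, wide enough to span
# the channel region plus the hyperbola's curvature.
_PATCH_HALF_ROWS = 8
_PATCH_HALF_COLS = 16


@dataclass
class Template:
    """One wavefront patch plus the apex offset from the patch center."""

    patch: np.ndarray
    apex_offset: tuple[float, float]  # (d_row, d_col): apex - patch center
    lateral_mm: float
    axial_mm: float


@dataclass
class TemplateBank:
    """Wavefront templates on a (lateral, axial) synthesis grid."""

    templates: list[Template]
    sound_speed_mps: float


def build_template_bank(spec: TransducerSpec, config: ImagingConfig,
                        depths_mm: tuple[float, ...] | None = None,
                        laterals_mm: tuple[float, ...] | None = None,
                        sound_speed_mps: float = 1540.0) -> TemplateBank:
    """Synthesize noiseless frames on a position grid and cut apex patches.

    The default depth grid spans 1/6 to 5/6 of the imaging depth in nine
    steps (20-100 mm in 10 mm increments for the default 120 mm view); the
    default lateral grid covers the aperture in nine steps, capturing the
    truncated-hyperbola appearance of off-center sources.  Each patch
    records the offset of the wavefront apex from the patch center so a
    correlation peak maps back to a source position.
    """
    if depths_mm is None:
        depths_mm = tuple(np.linspace(config.depth_max_mm / 6.0,
                                      config.depth_max_mm * 5.0 / 6.0, 9))
    if laterals_mm is None:
        half = spec.aperture_width_mm / 2.0
        laterals_mm = tuple(np.linspace(-half * 0.9, half * 0.9, 9))
    templates = []
    for depth in depths_mm:
        for lateral in laterals_mm:
            truth = SourceTruth(SOURCE, float(lateral), float(depth))
            samples = synthesize_wavefront(truth, spec, config,
                                           sound_speed_mps)
            frame = ChannelFrame(samples=samples,
                                 sound_speed_mps=sound_speed_mps,
                                 truths=[truth])
            pf = process_frame(frame, spec, config)
            ann = pf.annotations[0]
            r, c = int(round(ann.center_row)), int(round(ann.center_col))
            r0 = min(max(0, r - _PATCH_HALF_ROWS),
                     pf.image.shape[0] - 2 * _PATCH_HALF_ROWS - 1)
            c0 = min(max(0, c - _PATCH_HALF_COLS),
                     pf.image.shape[1] - 2 * _PATCH_HALF_COLS - 1)
            patch = pf.image[r0:r0 + 2 * _PATCH_HALF_ROWS + 1,
                             c0:c0 + 2 * _PATCH_HALF_COLS + 1].astype(float)
            center = (r0 + _PATCH_HALF_ROWS, c0 + _PATCH_HALF_COLS)
            templates.append(Template(
                patch=patch,
                apex_offset=(ann.center_row - center[0],
                             ann.center_col - center[1]),
                lateral_mm=float(lateral), axial_mm=float(depth)))
    return TemplateBank(templates=templates, sound_speed_mps=sound_speed_mps)


def detect(frame: ProcessedFrame, bank: TemplateBank,
           score_floor: float = 0.5, max_detections: int = 10) -> list[Detection]:
    """Correlate every template, keep NMS-surviving peaks above the floor.

    Scores are normalized cross-correlation values in [-1, 1] (invariant
    to amplitude scaling of the frame), mapped to confidence
    (score + 1) / 2.  Each pixel keeps its best template; a surviving
    correlation peak becomes a box centered at peak + that template's apex
    offset.  Peaks within one template footprint of a stronger peak are
    suppressed so a single wavefront yields a single detection.
    """
    image = frame.image.astype(float)
    if image.max() == image.min():
        return []
    score_map = np.full(image.shape, -1.0)
    best_template = np.zeros(image.shape, dtype=int)
    for ti, tmpl in enumerate(bank.templates):
        if tmpl.patch.max() == tmpl.patch.min():
            continue
        cc = match_template(image, tmpl.patch, pad_input=True)
        better = cc > score_map
        score_map[better] = cc[better]
        best_template[better] = ti

    detections: list[Detection] = []
    work = score_map.copy()
    for _ in range(max_detections):
        idx = np.unravel_index(np.argmax(work), work.shape)
        score = work[idx]
        if score < score_floor:
            break
        r, c = int(idx[0]), int(idx[1])
        dr, dc = bank.templates[best_template[r, c]].apex_offset
        detections.append(Detection(
            object_class=SOURCE, center_col=float(c + dc),
            center_row=float(r + dr),
            confidence=(float(score) + 1.0) / 2.0, frame_id=frame.frame_id,
            width=float(BOX_WIDTH_PX), height=float(BOX_HEIGHT_PX)))
        # suppress the whole template footprint: the flanks of one
        # wavefront must not resurface as extra peaks
        r0 = max(0, r - 2 * _PATCH_HALF_ROWS)
        c0 = max(0, c - 2 * _PATCH_HALF_COLS)
        work[r0:r + 2 * _PATCH_HALF_ROWS + 1,
             c0:c + 2 * _PATCH_HALF_COLS + 1] = -1.0
    return detections


def detections_to_json(detections: list[Detection]) -> list[dict]:
    """Serialize to the external-detector interchange records."""
    return [{
        "frame_id": d.frame_id,
        "class": d.object_class,
        "bbox": [d.center_col - d.width / 2, d.center_row - d.height / 2,
                 d.width, d.height],
        "score": d.confidence,
    } for d in detections]


def validate_detections(records: list) -> None:
    """Schema-check interchange records; errors name the offending entry."""
    if not isinstance(records, list):
        raise ValueError("detections JSON must be a list of records")
    for i, rec in enumerate(records):
        where = f"record {i}"
        if not isinstance(rec, dict):
            raise ValueError(f"{where}: not an object")
        for key in ("frame_id", "class", "bbox", "score"):
            if key not in rec:
                raise ValueError(f"{where}: missing key {key!r}")
        if rec["class"] not in ("source", "artifact"):
            raise ValueError(f"{where}: unknown class {rec['class']!r}")
        bbox = rec["bbox"]
        if (not isinstance(bbox, (list, tuple)) or len(bbox) != 4
                or not all(isinstance(v, (int, float)) for v in bbox)):
            raise ValueError(f"{where}: bbox must be [x, y, w, h]")
        if bbox[2] <= 0 or bbox[3] <= 0:
            raise ValueError(f"{where}: bbox width/height must be positive")
        score = rec["score"]
        if not isinstance(score, (int, float)) or not 0.0 <= score <= 1.0:
            raise ValueError(f"{where}: score {score!r} outside [0, 1]")


def detections_from_json(records: list) -> list[Detection]:
    """Parse and validate interchange records into :class:`Detection` objects."""
    validate_detections(records)
    out = []
    for rec in records:
        x, y, w, h = rec["bbox"]
        out.append(Detection(
            object_class=rec["class"], center_col=x + w / 2.0,
            center_row=y + h / 2.0, confidence=float(rec["score"]),
            frame_id=rec["frame_id"], width=float(w), height=float(h)))
    return out
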