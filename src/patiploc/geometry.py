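"""Acquisition geometry for a phased-array photoacoustic imaging system.

All coordinate mappings in the pipeline derive from two configuration
objects: :class:`TransducerSpec` (the physical array — element layout and
sampling) and :class:`ImagingConfig` (the imaging view — depth, sector
angle, nominal sound speed, and rendering pixel sizes).

World coordinates are (lateral mm, axial mm) with the origin at the center
of the transducer face, lateral positive to the right and axial positive
into the medium.  Pixel coordinates are (col, row), 0-based, continuous,
with pixel centers at integer coordinates; row 0 is the transducer face and
the central image column corresponds to lateral 0.  The same convention is
used for the raw scan-converted grid and the processed 256x256 grid, so a
single :class:`GridGeometry` type serves both.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "TransducerSpec",
    "ImagingConfig",
    "GridGeometry",
    "InvalidConfigurationError",
    "record_length",
    "element_positions",
    "scan_grid",
    "processed_grid",
    "processed_pixel_size",
    "load_config",
    "save_config",
]


class InvalidConfigurationError(ValueError):
    """Raised when a transducer or imaging configuration is inconsistent."""


@dataclass(frozen=True)
class TransducerSpec:
    """Phased-array transducer description.

    Defaults describe a 64-element cardiac phased array with 220 um element
    width, 80 um kerf (hence 300 um pitch and a 19.2 mm aperture) sampled
    at 40 MHz.  Center frequency and fractional bandwidth are used only for
    pulse synthesis in the simulator.
    """

    n_elements: int = 64
    element_width_um: float = 220.0
    kerf_um: float = 80.0
    sampling_frequency_hz: float = 40e6
    center_frequency_hz: float = 3e6
    fractional_bandwidth: float = 0.6

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise InvalidConfigurationError("n_elements must be >= 1")
        for name in ("element_width_um", "kerf_um", "sampling_frequency_hz",
                     "center_frequency_hz"):
            if getattr(self, name) < 0 or (name != "kerf_um" and getattr(self, name) == 0):
                raise InvalidConfigurationError(f"{name} must be positive")

    @property
    def pitch_um(self) -> float:
        """Element pitch = element width + kerf (um)."""
        return self.element_width_um + self.kerf_um

    @property
    def pitch_mm(self) -> float:
        return self.pitch_um / 1000.0

    @property
    def aperture_width_mm(self) -> float:
        """Physical aperture width: n_elements x pitch (19.2 mm for defaults)."""
        return self.n_elements * self.pitch_mm


@dataclass(frozen=True)
class ImagingConfig:
    """Imaging view configuration.

    ``sector_half_angle_deg`` defaults to 45 degrees: the value is not a
    directly measured property of the transducer but is the unique angle
    consistent with the default scan-converted grid width (1132 columns of
    150 um covering 2 x 120 mm x sin 45 deg).  ``scan_pixel_lateral_um``
    defaults to half the element pitch.
    """

    depth_max_mm: float = 120.0
    sector_half_angle_deg: float = 45.0
    sound_speed_mps: float = 1540.0
    scan_pixel_lateral_um: float = 150.0
    processed_size: int = 256

    def __post_init__(self) -> None:
        if self.depth_max_mm <= 0:
            raise InvalidConfigurationError("depth_max_mm must be positive")
        if not 0 < self.sector_half_angle_deg < 90:
            raise InvalidConfigurationError("sector_half_angle_deg must be in (0, 90)")
        if self.sound_speed_mps <= 0:
            raise InvalidConfigurationError("sound_speed_mps must be positive")
        if self.scan_pixel_lateral_um <= 0:
            raise InvalidConfigurationError("scan_pixel_lateral_um must be positive")
        if self.processed_size < 2:
            raise InvalidConfigurationError("processed_size must be >= 2")

    @property
    def sector_half_angle_rad(self) -> float:
        return math.radians(self.sector_half_angle_deg)

    @property
    def fov_width_mm(self) -> float:
        """Full lateral extent of the scan-converted sector at max depth."""
        return 2.0 * self.depth_max_mm * math.sin(self.sector_half_angle_rad)


@dataclass(frozen=True)
class GridGeometry:
    """A Cartesian pixel grid aligned to the imaging FOV.

    Row 0 is the transducer face; the array axis (lateral 0) maps to column
    (n_cols - 1) / 2.  Pixel centers sit at integer coordinates.
    """

    n_rows: int
    n_cols: int
    pixel_height_mm: float
    pixel_width_mm: float

    def world_to_pixel(self, lateral_mm, axial_mm):
        """Map world (lateral mm, axial mm) to continuous (col, row)."""
        lateral_mm = np.asarray(lateral_mm, dtype=float)
        axial_mm = np.asarray(axial_mm, dtype=float)
        col = (self.n_cols - 1) / 2.0 + lateral_mm / self.pixel_width_mm
        row = axial_mm / self.pixel_height_mm
        return col, row

    def pixel_to_world(self, col, row):
        """Inverse of :meth:`world_to_pixel` (exact affine inverse)."""
        col = np.asarray(col, dtype=float)
        row = np.asarray(row, dtype=float)
        lateral = (col - (self.n_cols - 1) / 2.0) * self.pixel_width_mm
        axial = row * self.pixel_height_mm
        return lateral, axial


def record_length(config: ImagingConfig, spec: TransducerSpec) -> int:
    """Number of axial samples recorded over one-way travel to max depth.

    Photoacoustic reception is one-way: a source at depth z arrives at
    t = z / c, so the record holds round(fs * depth / c) samples
    (3117 for 120 mm, 1540 m/s, 40 MHz).
    """
    if config.depth_max_mm <= 0 or config.sound_speed_mps <= 0:
        raise InvalidConfigurationError("depth and sound speed must be positive")
    if spec.sampling_frequency_hz <= 0:
        raise InvalidConfigurationError("sampling frequency must be positive")
    t_max = (config.depth_max_mm / 1000.0) / config.sound_speed_mps
    return int(round(spec.sampling_frequency_hz * t_max))


def element_positions(spec: TransducerSpec) -> np.ndarray:
    """Lateral element-center coordinates (mm), symmetric about 0."""
    n = spec.n_elements
    return (np.arange(n) - (n - 1) / 2.0) * spec.pitch_mm


def scan_grid(config: ImagingConfig, spec: TransducerSpec) -> GridGeometry:
    """Geometry of the scan-converted sector image the channel data is padded to.

    Rows map 1:1 to the axial record samples; columns cover the full sector
    width at ``scan_pixel_lateral_um`` spacing (ceiling, so the FOV is fully
    covered: 1132 columns for the defaults).
    """
    n_rows = record_length(config, spec)
    pixel_height_mm = config.depth_max_mm / n_rows
    pixel_width_mm = config.scan_pixel_lateral_um / 1000.0
    n_cols = int(math.ceil(config.fov_width_mm / pixel_width_mm))
    return GridGeometry(n_rows=n_rows, n_cols=n_cols,
                        pixel_height_mm=pixel_height_mm,
                        pixel_width_mm=pixel_width_mm)


def processed_grid(config: ImagingConfig, spec: TransducerSpec) -> GridGeometry:
    """Geometry of the processed (resized, default 256x256) frame."""
    n = config.processed_size
    return GridGeometry(
        n_rows=n, n_cols=n,
        pixel_height_mm=config.depth_max_mm / n,
        pixel_width_mm=config.fov_width_mm / n,
    )


def processed_pixel_size(config: ImagingConfig, spec: TransducerSpec) -> tuple[float, float]:
    """(lateral um, axial um) pixel size of the processed frame.

    For the defaults this is (662.9, 468.8) um: the sector FOV width and
    the 120 mm depth each divided by 256.
    """
    grid = processed_grid(config, spec)
    return grid.pixel_width_mm * 1000.0, grid.pixel_height_mm * 1000.0


def _config_dict(spec: TransducerSpec, config: ImagingConfig) -> dict:
    return {"transducer": asdict(spec), "imaging": asdict(config)}


def save_config(path: str | Path, spec: TransducerSpec, config: ImagingConfig) -> None:
    """Write a YAML (or JSON, by extension) configuration file."""
    path = Path(path)
    data = _config_dict(spec, config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))


def load_config(path: str | Path | None) -> tuple[TransducerSpec, ImagingConfig]:
    """Load (TransducerSpec, ImagingConfig) from YAML/JSON; defaults if None."""
    if path is None:
        return TransducerSpec(), ImagingConfig()
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    spec = TransducerSpec(**data.get("transducer", {}))
    config = ImagingConfig(**data.get("imaging", {}))
    return spec, config
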