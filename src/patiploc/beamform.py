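"""Delay-and-sum beamforming, envelope display chain, and resolution measurement.

Receive-only (one-way) DAS for photoacoustic reception: the focus at range
r on scanline angle theta receives each element's trace delayed by the
element-to-focus time of flight, and the delayed traces are summed without
apodization.  The polar (range x angle) image is envelope-detected per
scanline with the analytic signal, log-compressed for display, and scan
converted onto the Cartesian sector grid by bilinear interpolation.
Resolution is measured as the full width at half maximum of a point
target's lateral or axial profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import hilbert

from .geometry import (GridGeometry, ImagingConfig, TransducerSpec,
                       element_positions)
from .simulate import ChannelFrame

__all__ = [
    "PolarImage",
    "das_beamform",
    "envelope_detect",
    "log_compress",
    "scan_convert",
    "locate_peak",
    "measure_fwhm",
]


@dataclass
class PolarImage:
    """Beamformed sector data on a (range x angle) grid."""

    data: np.ndarray        # [n_ranges x n_scanlines]
    ranges_mm: np.ndarray
    thetas_rad: np.ndarray


def das_beamform(frame: ChannelFrame, spec: TransducerSpec,
                 config: ImagingConfig, n_scanlines: int = 128) -> PolarImage:
    """One-way delay-and-sum over a fan of scanlines spanning the sector.

    output(r, theta) = sum_j samples_j(|p - element_j| / c) with linear
    interpolation of sample times and no apodization.  Range samples match
    the axial record raster (r_k = k c / f_s).
    """
    samples = np.asarray(frame.samples, dtype=float)
    n_samples, n_el = samples.shape
    if n_el != spec.n_elements:
        raise ValueError(f"frame has {n_el} element traces, spec expects "
                         f"{spec.n_elements}")
    c = frame.sound_speed_mps
    fs = spec.sampling_frequency_hz
    xe = element_positions(spec)
    half = config.sector_half_angle_rad
    thetas = np.linspace(-half, half, n_scanlines)
    ranges_mm = np.arange(n_samples) * (c / fs) * 1000.0

    out = np.zeros((n_samples, n_scanlines))
    pad = np.vstack([samples, np.zeros((1, n_el))])  # out-of-window taps -> 0
    for k, th in enumerate(thetas):
        x = ranges_mm * np.sin(th)
        z = ranges_mm * np.cos(th)
        dist_mm = np.hypot(x[:, None] - xe[None, :], z[:, None])
        idx = dist_mm / 1000.0 / c * fs
        i0 = np.floor(idx).astype(int)
        frac = idx - i0
        valid = i0 < n_samples - 1
        i0 = np.where(valid, i0, n_samples)  # points at the zero pad row
        cols = np.broadcast_to(np.arange(n_el), i0.shape)
        tap0 = pad[i0, cols]
        tap1 = pad[np.minimum(i0 + 1, n_samples), cols]
        out[:, k] = np.sum(tap0 + np.where(valid, frac, 0.0) * (tap1 - tap0),
                           axis=1)
    return PolarImage(data=out, ranges_mm=ranges_mm, thetas_rad=thetas)


def envelope_detect(polar: PolarImage) -> PolarImage:
    """Analytic-signal magnitude per scanline (along the range axis)."""
    env = np.abs(hilbert(polar.data, axis=0))
    return PolarImage(data=env, ranges_mm=polar.ranges_mm,
                      thetas_rad=polar.thetas_rad)


def log_compress(env: PolarImage, dynamic_range_db: float = 40.0) -> PolarImage:
    """Normalize to peak = 0 dB and clip at -dynamic_range (display image)."""
    data = np.asarray(env.data, dtype=float)
    peak = data.max()
    if peak <= 0:
        comp = np.full_like(data, -dynamic_range_db)
    else:
        with np.errstate(divide="ignore"):
            comp = 20.0 * np.log10(data / peak)
        comp = np.maximum(comp, -dynamic_range_db)
    return PolarImage(data=comp, ranges_mm=env.ranges_mm,
                      thetas_rad=env.thetas_rad)


def scan_convert(polar: PolarImage, grid: GridGeometry,
                 fill: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear resampling from (r, theta) onto the Cartesian sector grid.

    Returns (image, valid_mask); pixels outside the sector carry ``fill``
    and are flagged invalid rather than being confused with signal.
    """
    rows = np.arange(grid.n_rows)
    cols = np.arange(grid.n_cols)
    x = (cols - (grid.n_cols - 1) / 2.0) * grid.pixel_width_mm
    z = rows * grid.pixel_height_mm
    xx, zz = np.meshgrid(x, z)
    r = np.hypot(xx, zz)
    th = np.arctan2(xx, zz)

    dr = polar.ranges_mm[1] - polar.ranges_mm[0]
    dth = polar.thetas_rad[1] - polar.thetas_rad[0]
    ri = (r - polar.ranges_mm[0]) / dr
    ti = (th - polar.thetas_rad[0]) / dth
    valid = ((r <= polar.ranges_mm[-1]) & (th >= polar.thetas_rad[0])
             & (th <= polar.thetas_rad[-1]))
    image = map_coordinates(polar.data, [ri, ti], order=1, mode="constant",
                            cval=fill)
    image[~valid] = fill
    return image, valid


def _parabolic_offset(y0: float, y1: float, y2: float) -> float:
    """Sub-bin offset of the vertex of a parabola through three samples."""
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


def locate_peak(env: PolarImage) -> tuple[float, float]:
    """World position (lateral mm, axial mm) of the envelope peak.

    The integer argmax is refined by independent quadratic fits along the
    range and angle axes, giving sub-bin accuracy well below the
    scan-grid pixel size for a smooth mainlobe.
    """
    data = env.data
    i, j = np.unravel_index(np.argmax(data), data.shape)
    di = dj = 0.0
    if 0 < i < data.shape[0] - 1:
        di = _parabolic_offset(data[i - 1, j], data[i, j], data[i + 1, j])
    if 0 < j < data.shape[1] - 1:
        dj = _parabolic_offset(data[i, j - 1], data[i, j], data[i, j + 1])
    dr = env.ranges_mm[1] - env.ranges_mm[0]
    dth = env.thetas_rad[1] - env.thetas_rad[0]
    r = env.ranges_mm[i] + di * dr
    th = env.thetas_rad[j] + dj * dth
    return r * float(np.sin(th)), r * float(np.cos(th))


def measure_fwhm(image: np.ndarray, peak: tuple[int, int], axis: str,
                 pixel_size_mm: float) -> float:
    """Full width at half maximum of the profile through ``peak``.

    ``peak`` is (col, row); ``axis`` is 'lateral' (profile along the row)
    or 'axial' (along the column).  Half-maximum crossings on each side of
    the peak are linearly interpolated; if a side never falls below half
    maximum, the profile does not resolve and an error is raised.
    """
    col, row = int(round(peak[0])), int(round(peak[1]))
    if axis == "lateral":
        profile = np.asarray(image[row, :], dtype=float)
        center = col
    elif axis == "axial":
        profile = np.asarray(image[:, col], dtype=float)
        center = row
    else:
        raise ValueError("axis must be 'lateral' or 'axial'")
    peak_val = profile[center]
    if peak_val <= 0:
        raise ValueError("profile peak is not positive")
    half = peak_val / 2.0

    def _cross(direction: int) -> float:
        i = center
        while 0 <= i + direction < len(profile):
            j = i + direction
            if profile[j] <= half:
                # linear interpolation between i and j
                frac = (profile[i] - half) / (profile[i] - profile[j])
                return abs(i - center) + frac
            i = j
        raise ValueError(f"half maximum not reached on side {direction:+d}")

    return (_cross(-1) + _cross(+1)) * pixel_size_mm
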