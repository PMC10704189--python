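"""Histogram-based domain-gap and detectability metrics.

Simulation-trained detectors degrade on experimental channel data partly
because the amplitude distributions differ.  This module quantifies that
gap with three histogram dissimilarities between an experimental frame
histogram h_e and a simulated reference histogram h_s over bins with mean
values x_k:

    TVD  = 1 - sum_k min{h_e(x_k), h_s(x_k)}                   in [0, 1]
    JD   = sum_k [ h_e log(h_e / (h_e+h_s))
                 + h_s log(h_s / (h_e+h_s)) ]                  in [-2 ln 2, 0]
    chi2 = sum_k (h_e - h_s)^2 / (h_e + h_s)                   in [0, 2]

and reduces it by monotone 64-bin CDF histogram matching that maps pixel
value 0 to 0 (the zero-padded region is never altered).  Waveform
detectability in the channel data is measured by the channel gCNR: 1 minus
the overlap of target and background ROI amplitude histograms (256 bins
over [0, 1] after normalizing to the brightest pixel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import GridGeometry
from .simulate import SourceTruth

__all__ = [
    "AmplitudeHistogram",
    "RoiPair",
    "build_histogram",
    "histogram_match",
    "tvd",
    "jd",
    "chi2",
    "gcnr_channel",
    "roi_pair",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AmplitudeHistogram:
    """Normalized amplitude histogram over an inclusive value range."""

    counts: np.ndarray       # normalized, sums to 1
    bin_edges: np.ndarray    # length n_bins + 1

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_means(self) -> np.ndarray:
        """x_k: mean value of bin k."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def build_histogram(values: np.ndarray, n_bins: int,
                    value_range: tuple[float, float]) -> AmplitudeHistogram:
    """Normalized histogram with the upper range edge inclusive in the last bin."""
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("cannot histogram an empty region")
    counts, edges = np.histogram(values, bins=n_bins, range=value_range)
    total = counts.sum()
    if total == 0:
        raise ValueError("no values fall inside the histogram range")
    return AmplitudeHistogram(counts=counts / total, bin_edges=edges)


def _check_pair(he: AmplitudeHistogram, hs: AmplitudeHistogram) -> None:
    if he.n_bins != hs.n_bins or not np.allclose(he.bin_edges, hs.bin_edges):
        raise ValueError("histograms must share the same binning")


def tvd(he: AmplitudeHistogram, hs: AmplitudeHistogram) -> float:
    """Total variation distance: 1 - sum of per-bin minima.  Symmetric, [0, 1]."""
    _check_pair(he, hs)
    return float(np.clip(1.0 - np.minimum(he.counts, hs.counts).sum(), 0.0, 1.0))


def jd(he: AmplitudeHistogram, hs: AmplitudeHistogram) -> float:
    """Jeffrey divergence with natural log and 0*log(.) = 0.

    0 for disjoint histograms, -2 ln 2 for identical ones; always in
    [-2 ln 2, 0].
    """
    _check_pair(he, hs)
    p, q = he.counts, hs.counts
    s = p + q
    total = 0.0
    for h in (p, q):
        mask = h > 0  # s >= h > 0 there, so the ratio lies in (0, 1]
        total += float(np.sum(h[mask] * np.log(h[mask] / s[mask])))
    return total


def chi2(he: AmplitudeHistogram, hs: AmplitudeHistogram) -> float:
    """Chi-squared statistic; symmetric, bounded by 2 for normalized histograms."""
    _check_pair(he, hs)
    p, q = he.counts, hs.counts
    s = p + q
    mask = s > 0
    return float(max(0.0, (((p - q) ** 2)[mask] / s[mask]).sum()))


def histogram_match(image: np.ndarray, reference: np.ndarray,
                    n_bins: int = 64) -> np.ndarray:
    """Monotone CDF matching of an 8-bit image to an 8-bit reference.

    Histograms use ``n_bins`` bins over the inclusive range 0-255.  The
    lookup maps each gray level to the reference level of equal cumulative
    probability; pixel value 0 is pinned to 0 so zero-padded regions pass
    through bitwise-unchanged.  A constant reference leaves the image
    unchanged (with a warning).
    """
    image = np.asarray(image, dtype=np.uint8)
    reference = np.asarray(reference, dtype=np.uint8)
    if reference.min() == reference.max():
        logger.warning("degenerate constant reference; returning image unchanged")
        return image.copy()

    edges = np.linspace(0.0, 255.0, n_bins + 1)
    src_counts, _ = np.histogram(image, bins=n_bins, range=(0, 255))
    ref_counts, _ = np.histogram(reference, bins=n_bins, range=(0, 255))
    src_cdf = np.cumsum(src_counts) / src_counts.sum()
    ref_cdf = np.cumsum(ref_counts) / ref_counts.sum()

    levels = np.arange(256, dtype=float)
    # cumulative probability of each gray level under the source histogram
    # (piecewise-linear within bins; exact at bin upper edges)
    q = np.interp(levels, edges[1:], src_cdf)
    # invert the reference CDF at those quantiles
    mapped = np.interp(q, np.concatenate(([0.0], ref_cdf)), edges)
    lut = np.round(np.clip(mapped, 0, 255)).astype(np.uint8)
    lut[0] = 0
    lut = np.maximum.accumulate(lut)  # enforce monotonicity after rounding
    return lut[image]


@dataclass(frozen=True)
class RoiPair:
    """Target/background ROI pixel windows: (row0, row1, col0, col1), half-open."""

    target: tuple[int, int, int, int]
    background: tuple[int, int, int, int]


def roi_pair(truth: SourceTruth, grid: GridGeometry,
             image_shape: tuple[int, int],
             roi_width_mm: float = 18.2, roi_height_mm: float = 5.0,
             target_axial_offset_mm: float = 1.0,
             background_offset_mm: float = 10.0) -> RoiPair:
    """Place target and background ROIs around a ground-truth source.

    Both ROIs are 18.2 mm x 5 mm and laterally centered in the image.  The
    target ROI center sits 1 mm distal to (deeper than) the source depth,
    surrounding the waveform; the background ROI center is 10 mm proximal
    to the target center, leaving a 5 mm gap that guarantees separation.
    """
    n_rows, n_cols = image_shape

    def _rect(center_axial_mm: float, label: str):
        cc = (n_cols - 1) / 2.0
        _, cr = grid.world_to_pixel(0.0, center_axial_mm)
        half_w = roi_width_mm / 2.0 / grid.pixel_width_mm
        half_h = roi_height_mm / 2.0 / grid.pixel_height_mm
        r0, r1 = int(round(cr - half_h)), int(round(cr + half_h))
        c0, c1 = int(round(cc - half_w)), int(round(cc + half_w))
        if r0 < 0 or r1 > n_rows or c0 < 0 or c1 > n_cols or r0 >= r1 or c0 >= c1:
            raise ValueError(
                f"{label} ROI rows {r0}:{r1} cols {c0}:{c1} outside image "
                f"{image_shape}")
        return (r0, r1, c0, c1)

    target_center = truth.axial_mm + target_axial_offset_mm
    return RoiPair(
        target=_rect(target_center, "target"),
        background=_rect(target_center - background_offset_mm, "background"),
    )


def gcnr_channel(image: np.ndarray, truth: SourceTruth, grid: GridGeometry,
                 n_bins: int = 256, power: bool = False, **roi_kwargs) -> float:
    """Channel gCNR: histogram separability of target vs background ROI.

    The image is normalized to its brightest pixel; amplitude histograms
    h_i (target) and h_o (background) use 256 bins over the inclusive
    range [0, 1]; the statistic is 1 - sum_k min{h_i, h_o}, in [0, 1].
    With ``power=True`` squared amplitudes are histogrammed instead.
    """
    image = np.asarray(image, dtype=float)
    peak = image.max()
    norm = image / peak if peak > 0 else image
    if power:
        norm = norm ** 2
    rois = roi_pair(truth, grid, image.shape, **roi_kwargs)
    r0, r1, c0, c1 = rois.target
    hi = build_histogram(norm[r0:r1, c0:c1], n_bins, (0.0, 1.0))
    r0, r1, c0, c1 = rois.background
    ho = build_histogram(norm[r0:r1, c0:c1], n_bins, (0.0, 1.0))
    return float(1.0 - np.minimum(hi.counts, ho.counts).sum())
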