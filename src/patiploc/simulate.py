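"""Analytic time-of-flight simulator for phased-array photoacoustic channel data.

Each frame contains one point-source wavefront (a hyperbolic arrival-time
locus across the array) and, optionally, one reflection-artifact wavefront.
The artifact models sound from the true source bouncing off an echogenic
reflector: its wavefront emanates from the reflector position delayed by
the source-reflector distance d, so its apparent position is the reflector
position shifted deeper by d.

The recorded pulse is a Gaussian-enveloped sinusoid at the transducer
center frequency with per-element 1/sqrt(r) (2-D cylindrical) amplitude
decay.  This replaces full-wave acoustic propagation: the downstream
pipeline consumes only wavefront geometry and amplitude statistics, and the
analytic model runs in milliseconds per frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ImagingConfig, TransducerSpec, element_positions, record_length

__all__ = [
    "SourceTruth",
    "ChannelFrame",
    "SimulationParams",
    "FrameSpec",
    "DatasetManifest",
    "synthesize_wavefront",
    "inject_reflection",
    "add_noise",
    "quantize_frame",
    "simulate_dataset",
    "realize_frame",
]

logger = logging.getLogger(__name__)

SOURCE = "source"
ARTIFACT = "artifact"

# Gaussian envelope is truncated at this many envelope standard deviations;
# beyond it the trace is exactly zero, which defines the wavefront support
# used by add_noise.
_ENVELOPE_TRUNCATION_SIGMAS = 4.0


@dataclass(frozen=True)
class SourceTruth:
    """Ground-truth object in a frame.

    For artifacts, ``lateral_mm``/``axial_mm`` hold the *apparent* position
    (reflector position shifted deeper by the source-reflector distance);
    the reflector's own location is kept alongside.
    """

    object_class: str
    lateral_mm: float
    axial_mm: float
    amplitude_multiplier: float = 1.0
    reflector_lateral_mm: float | None = None
    reflector_axial_mm: float | None = None

    def __post_init__(self) -> None:
        if self.object_class not in (SOURCE, ARTIFACT):
            raise ValueError(f"unknown object class {self.object_class!r}")


@dataclass
class ChannelFrame:
    """Raw channel data: samples [record_length x n_elements] plus truths."""

    samples: np.ndarray
    sound_speed_mps: float
    truths: list[SourceTruth] = field(default_factory=list)
    frame_id: int | None = None
    snr_db: float | None = None
    rng_seed: int | None = None


def _pulse(t: np.ndarray, spec: TransducerSpec) -> np.ndarray:
    """Band-limited wavelet: cos at f_c under a Gaussian envelope.

    The envelope width follows from the fractional bandwidth: a Gaussian
    spectrum with FWHM = fbw * f_c has sigma_f = fbw * f_c / 2.3548 and
    time-domain sigma_t = 1 / (2 pi sigma_f).
    """
    fc = spec.center_frequency_hz
    sigma_f = spec.fractional_bandwidth * fc / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sigma_t = 1.0 / (2.0 * math.pi * sigma_f)
    out = np.cos(2.0 * math.pi * fc * t) * np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    out[np.abs(t) > _ENVELOPE_TRUNCATION_SIGMAS * sigma_t] = 0.0
    return out


def _wavefront(arrival_s: np.ndarray, amplitudes: np.ndarray,
               spec: TransducerSpec, config: ImagingConfig) -> np.ndarray:
    n_samples = record_length(config, spec)
    t = np.arange(n_samples) / spec.sampling_frequency_hz
    if np.min(arrival_s) > t[-1]:
        logger.warning("wavefront arrives after the record window; truncated")
    # (n_samples, n_elements) time offsets
    dt = t[:, None] - arrival_s[None, :]
    return amplitudes[None, :] * _pulse(dt, spec)


def synthesize_wavefront(truth: SourceTruth, spec: TransducerSpec,
                         config: ImagingConfig, sound_speed_mps: float) -> np.ndarray:
    """Channel-data contribution of a point source.

    Element j at lateral x_j records the pulse at
    t_j = sqrt((lateral - x_j)^2 + axial^2) / c with amplitude
    amplitude_multiplier * sqrt(axial / distance_j): unit amplitude is
    referenced to the on-axis distance, and the apex (earliest, strongest
    arrival) falls on the element nearest the source lateral position.
    """
    if sound_speed_mps <= 0:
        raise ValueError("sound speed must be positive")
    xe = element_positions(spec)
    dist_mm = np.hypot(truth.lateral_mm - xe, truth.axial_mm)
    arrival_s = dist_mm / 1000.0 / sound_speed_mps
    amp = truth.amplitude_multiplier * np.sqrt(truth.axial_mm / dist_mm)
    return _wavefront(arrival_s, amp, spec, config)


def inject_reflection(frame: ChannelFrame, source: SourceTruth,
                      reflector: tuple[float, float],
                      spec: TransducerSpec, config: ImagingConfig,
                      pure_shift: bool = False) -> ChannelFrame:
    """Add a reflection-artifact wavefront to ``frame`` (in place) and annotate it.

    The artifact wavefront reaches element j at
    t_j = (|reflector - element_j| + d) / c where d is the source-reflector
    Euclidean distance, i.e. a wavefront radiating from the reflector
    delayed by d/c; its apparent position is (reflector_lateral,
    reflector_axial + d).  With ``pure_shift=True`` the source wavefront is
    instead replicated shifted deeper by d (apex stays at the source
    lateral position).
    """
    refl_lat, refl_ax = reflector
    d_mm = math.hypot(source.lateral_mm - refl_lat, source.axial_mm - refl_ax)
    apparent_ax = refl_ax + d_mm
    if apparent_ax > config.depth_max_mm:
        logger.warning("artifact apparent depth %.1f mm beyond record; truncated",
                       apparent_ax)

    xe = element_positions(spec)
    c = frame.sound_speed_mps
    if pure_shift:
        dist_mm = np.hypot(source.lateral_mm - xe, source.axial_mm) + d_mm
        apparent_lat = source.lateral_mm
    else:
        dist_mm = np.hypot(refl_lat - xe, refl_ax) + d_mm
        apparent_lat = refl_lat
    arrival_s = dist_mm / 1000.0 / c
    amp = source.amplitude_multiplier * np.sqrt(apparent_ax / dist_mm)
    frame.samples = frame.samples + _wavefront(arrival_s, amp, spec, config)
    frame.truths.append(SourceTruth(
        object_class=ARTIFACT,
        lateral_mm=apparent_lat,
        axial_mm=apparent_ax,
        amplitude_multiplier=source.amplitude_multiplier,
        reflector_lateral_mm=refl_lat,
        reflector_axial_mm=refl_ax,
    ))
    return frame


def add_noise(frame: ChannelFrame, snr_db: float, rng_seed: int) -> ChannelFrame:
    """Add white Gaussian noise at the requested channel SNR.

    Signal power is the mean squared amplitude over the wavefront support
    (samples inside the truncated pulse envelope, where the clean frame is
    nonzero); noise variance is signal_power / 10^(snr_db/10).  The same
    seed yields bit-identical noise.
    """
    support = frame.samples != 0.0
    if not support.any():
        raise ValueError("cannot set SNR on an all-zero frame")
    signal_power = float(np.mean(frame.samples[support] ** 2))
    noise_power = signal_power / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(rng_seed)
    noise = rng.normal(0.0, math.sqrt(noise_power), size=frame.samples.shape)
    return replace_samples(frame, frame.samples + noise, snr_db=snr_db,
                           rng_seed=rng_seed)


def replace_samples(frame: ChannelFrame, samples: np.ndarray, **updates) -> ChannelFrame:
    new = ChannelFrame(samples=samples, sound_speed_mps=frame.sound_speed_mps,
                       truths=list(frame.truths), frame_id=frame.frame_id,
                       snr_db=frame.snr_db, rng_seed=frame.rng_seed)
    for k, v in updates.items():
        setattr(new, k, v)
    return new


def quantize_frame(frame: ChannelFrame | np.ndarray) -> np.ndarray:
    """Map samples to 8-bit: round(255 |s| / max|s|); all-zero stays all-zero.

    Absolute value (rather than a signed offset-128 mapping) keeps
    zero-padding at pixel value 0, which the histogram-matching transform
    preserves by construction.
    """
    samples = frame.samples if isinstance(frame, ChannelFrame) else frame
    if not np.all(np.isfinite(samples)):
        raise ValueError("frame contains non-finite samples")
    peak = np.max(np.abs(samples))
    if peak == 0.0:
        return np.zeros(samples.shape, dtype=np.uint8)
    return np.round(255.0 * np.abs(samples) / peak).astype(np.uint8)


@dataclass(frozen=True)
class SimulationParams:
    """Sampling ranges for the simulated dataset (all ranges inclusive).

    Positions are drawn on 0.25 mm grids (axial 20-100 mm, lateral
    +/-57 mm), sound speed on a 6 m/s grid over 1440-1640 m/s, channel SNR
    uniformly over -5 to 2 dB and source intensity uniformly over
    0.75-1.1.  Half the frames carry a reflection artifact by default.
    """

    n_frames: int = 20000
    artifact_fraction: float = 0.5
    train_fraction: float = 0.8
    axial_range_mm: tuple[float, float] = (20.0, 100.0)
    axial_increment_mm: float = 0.25
    lateral_range_mm: tuple[float, float] = (-57.0, 57.0)
    lateral_increment_mm: float = 0.25
    snr_range_db: tuple[float, float] = (-5.0, 2.0)
    intensity_range: tuple[float, float] = (0.75, 1.1)
    sound_speed_range_mps: tuple[float, float] = (1440.0, 1640.0)
    sound_speed_increment_mps: float = 6.0
    rng_seed: int = 0

    @classmethod
    def for_view(cls, config: ImagingConfig, **overrides) -> "SimulationParams":
        """Position ranges scaled to a (possibly non-default) imaging view.

        Axial positions span 1/6 to 5/6 of the imaging depth and lateral
        positions 67.2% of the sector half-width (the fraction the default
        ranges occupy in the default 120 mm view), rounded to the 0.25 mm
        grid; for the default view this reproduces the 20-100 mm axial and
        +/-57 mm lateral ranges.
        """
        step = cls.axial_increment_mm

        def snap(v: float) -> float:
            return round(v / step) * step

        axial = (snap(config.depth_max_mm / 6.0),
                 snap(config.depth_max_mm * 5.0 / 6.0))
        half_lat = snap(config.fov_width_mm / 2.0 * 0.67175)
        defaults = dict(axial_range_mm=axial,
                        lateral_range_mm=(-half_lat, half_lat))
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class FrameSpec:
    """Everything needed to (re)synthesize one frame deterministically."""

    frame_id: int
    source: SourceTruth
    reflector: tuple[float, float] | None
    sound_speed_mps: float
    snr_db: float
    noise_seed: int


@dataclass
class DatasetManifest:
    """Lazy dataset description: frame specs plus the train/validation split."""

    frames: list[FrameSpec]
    train_ids: list[int]
    val_ids: list[int]
    params: SimulationParams


def _grid_choice(rng: np.random.Generator, lo: float, hi: float, step: float,
                 size=None):
    n = int(round((hi - lo) / step)) + 1
    return lo + step * rng.integers(0, n, size=size)


def simulate_dataset(params: SimulationParams, spec: TransducerSpec,
                     config: ImagingConfig) -> DatasetManifest:
    """Draw per-frame parameters and the 80/20 split from one master seed.

    All randomness flows from ``params.rng_seed`` through named substreams
    (positions, artifact geometry, levels, noise seeds, split), so the
    manifest is bit-reproducible.  Frames themselves are synthesized on
    demand by :func:`realize_frame`.
    """
    ss = np.random.SeedSequence(params.rng_seed)
    kids = ss.spawn(5)
    rng_pos, rng_art, rng_lev, rng_noise, rng_split = (
        np.random.default_rng(k) for k in kids)

    n = params.n_frames
    lat = _grid_choice(rng_pos, *params.lateral_range_mm,
                       params.lateral_increment_mm, size=n)
    ax = _grid_choice(rng_pos, *params.axial_range_mm,
                      params.axial_increment_mm, size=n)
    has_artifact = rng_art.random(n) < params.artifact_fraction
    refl_lat = _grid_choice(rng_art, *params.lateral_range_mm,
                            params.lateral_increment_mm, size=n)
    refl_ax = _grid_choice(rng_art, *params.axial_range_mm,
                           params.axial_increment_mm, size=n)
    snr = rng_lev.uniform(*params.snr_range_db, size=n)
    amp = rng_lev.uniform(*params.intensity_range, size=n)
    c = _grid_choice(rng_lev, *params.sound_speed_range_mps,
                     params.sound_speed_increment_mps, size=n)
    noise_seeds = rng_noise.integers(0, 2 ** 31 - 1, size=n)

    frames = []
    for i in range(n):
        source = SourceTruth(SOURCE, float(lat[i]), float(ax[i]), float(amp[i]))
        reflector = (float(refl_lat[i]), float(refl_ax[i])) if has_artifact[i] else None
        frames.append(FrameSpec(
            frame_id=i, source=source, reflector=reflector,
            sound_speed_mps=float(c[i]), snr_db=float(snr[i]),
            noise_seed=int(noise_seeds[i]),
        ))

    ids = rng_split.permutation(n)
    n_train = int(round(params.train_fraction * n))
    return DatasetManifest(
        frames=frames,
        train_ids=sorted(int(i) for i in ids[:n_train]),
        val_ids=sorted(int(i) for i in ids[n_train:]),
        params=params,
    )


def realize_frame(fs: FrameSpec, spec: TransducerSpec, config: ImagingConfig,
                  noiseless: bool = False) -> ChannelFrame:
    """Synthesize the channel data described by a :class:`FrameSpec`."""
    samples = synthesize_wavefront(fs.source, spec, config, fs.sound_speed_mps)
    frame = ChannelFrame(samples=samples, sound_speed_mps=fs.sound_speed_mps,
                         truths=[fs.source], frame_id=fs.frame_id)
    if fs.reflector is not None:
        frame = inject_reflection(frame, fs.source, fs.reflector, spec, config)
    if not noiseless:
        frame = add_noise(frame, fs.snr_db, fs.noise_seed)
    return frame
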