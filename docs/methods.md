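# Methods

This note documents the models, conventions, and numerical choices behind
`patiploc`, and what the synthetic data can and cannot establish.

## Acquisition geometry

All coordinate mappings derive from the transducer (64 elements, 220 µm
element width, 80 µm kerf → 300 µm pitch, 19.2 mm aperture, 40 MHz
sampling) and the imaging view (120 mm depth, 1540 m/s nominal sound
speed). Photoacoustic reception is one-way, so the record holds
round(f_s · depth / c) = 3117 axial samples.

The sector half-angle is not a measured property of the probe; 45° is the
unique value consistent with the scan-converted grid the pipeline targets
(1132 columns × 150 µm ≈ 2 × 120 mm × sin 45°) and is configurable. The
lateral scan pixel (150 µm) equals half the element pitch. Column count
uses a ceiling so the grid always covers the full sector width; record
length uses round-to-nearest (round and ceil agree for the defaults).

Pixel convention: 0-based continuous coordinates, pixel centers at integer
positions, row 0 at the transducer face, the array axis at column
(n_cols − 1)/2. `world_to_pixel`/`pixel_to_world` are exact affine
inverses. The same convention serves the raw scan grid and the processed
256×256 grid, so one grid type covers both.

## Channel-data simulation

Full-wave propagation is replaced by an analytic time-of-flight model: a
point source at (x₀, z₀) reaches element j at lateral x_j after
t_j = √((x₀−x_j)² + z₀²)/c; the recorded trace is a Gaussian-enveloped
cosine at the transducer center frequency (default 3 MHz, 60 % fractional
bandwidth — placeholders used only for pulse synthesis) with 2-D
cylindrical 1/√r amplitude decay referenced to the on-axis distance. The
envelope is truncated at 4σ, which gives the wavefront a well-defined
support. The rationale for the analytic model: every downstream consumer
(dataset building, histogram metrics, beamforming, detection) uses only
wavefront geometry and amplitude statistics, and the analytic model runs in
milliseconds per frame. What it omits: acoustic heterogeneity, attenuation,
element directivity, finite source size, and multiple scattering.

**Reflection artifacts** model source sound bouncing off an echogenic
reflector: the artifact wavefront radiates from the reflector position
delayed by the source–reflector distance d, so per element
t_j = (|reflector − element_j| + d)/c and the apparent position is the
reflector position shifted deeper by d. This reproduces the case of an
artifact apex at a different lateral position than the source; a pure
depth-shift variant (`pure_shift=True`) replicates the source wavefront
translated deeper instead.

**Noise.** White Gaussian noise is scaled so that
10·log₁₀(signal power / noise power) equals the requested channel SNR,
where signal power is the mean square over the wavefront support. Realized
SNR is within 5 % (power ratio) across the −5 to 2 dB range.

**Study conditions.** Per-frame draws: axial 20–100 mm and lateral ±57 mm
on 0.25 mm grids, intensity multiplier uniform on [0.75, 1.1], SNR uniform
on [−5, 2] dB (uniform sampling assumed where the sampling law is
unstated), sound speed on a 6 m/s grid over 1440–1640 m/s, artifact on a
Bernoulli(0.5) subset (the artifact fraction is configurable; reflector
positions are drawn from the same position grids). All randomness flows
from one master seed through named substreams (positions, artifact
geometry, levels, noise, split), so a manifest is bit-reproducible. The
80/20 split is a seeded permutation. `SimulationParams.for_view` rescales
the position ranges proportionally for non-default imaging depths.

## Dataset building

Frames are quantized to 8 bits as round(255·|s|/max|s|). Absolute value —
not a signed offset-128 mapping — keeps zero-padding at pixel value 0,
which histogram matching then preserves exactly.

The 64 element traces are laterally resampled by linear interpolation onto
round(aperture/pixel width) = 128 columns aligned to the 150 µm raster and
centered in the 1132-column grid (all other pixels exactly 0), then the
padded frame is downsampled to 256×256 by area averaging
(`resize_local_mean`) and rescaled to the 8-bit range with 0 preserved.
Area averaging retains faint waveform edges that decimation would drop;
some contrast loss at this step is inherent and is exactly what the
channel-gCNR metric quantifies.

**Annotations** are fixed 32×16 pixel boxes (32 lateral × 16 axial:
wavefronts are laterally extended and axially compact) centered on the
wavefront apex *as recorded in the frame*: a source at depth z in a medium
with sound speed c arrives at t = z/c and therefore appears at apparent
depth z·c_nominal/c on the frame's row raster. At c = 1540 m/s this reduces
to the plain world-to-pixel mapping. Boxes may extend into the zero-padded
region and are serialized unclipped with an `in_zero_padding` flag, in
COCO-style JSON (source = 1, artifact = 2).

## Histogram matching and domain metrics

Matching uses 64-bin histograms over the inclusive range 0–255 and a
monotone CDF-matching lookup; gray level 0 is pinned to 0 and the LUT is
re-monotonized after rounding. Each experimental frame is matched to one
seeded randomly drawn simulated reference frame (a per-frame draw; the
alternative of one shared reference is a caller choice). A constant
reference degenerates to the identity with a warning.

The three distances (TVD, Jeffrey divergence, χ²) use 256-bin histograms
computed on the channel-data region only — the zero-padding spike would
otherwise dominate all three. JD uses the natural logarithm and both
summands (hₑ and hₛ); its range is [−2 ln 2, 0] with −2 ln 2 ≈ −1.386 at
identity and 0 at disjoint support, so *more negative is more similar*.
Bins with no mass contribute zero in all three sums.

**Channel gCNR** measures waveform detectability before any beamforming:
the frame is normalized to its brightest pixel, amplitudes ("power
histograms" read as normalized amplitudes; a squared-amplitude option is
provided) are histogrammed over [0, 1] with 256 bins inside two
18.2 × 5 mm ROIs, and gCNR = 1 − Σ min. The target ROI is laterally
centered with its axial center 1 mm distal to the source depth; the
background ROI center is 10 mm proximal to the target center, leaving a
5 mm gap (center-anchored offsets; edge-anchored variants would shift both
by half a ROI height). ROIs are defined once on the zero-padded frame and
reused identically on processed and histogram-matched frames.

## Beamforming

Receive-only delay-and-sum over 128 scanlines spanning ±45°: the focus at
range r on angle θ sums each element's trace linearly interpolated at
|p − element|/c. No apodization; range samples match the record raster.
These are the plainest DAS choices — beamforming exists here for annotation
and comparison, not as the localization path. Envelope detection is the
analytic-signal magnitude per scanline; display images are log-compressed
to a 40 dB range; scan conversion is bilinear with out-of-sector pixels
flagged invalid rather than zeroed into the data.

`locate_peak` refines the envelope argmax with independent quadratic fits
along range and angle. This matters because scanline spacing at 100 mm
depth (≈1.2 mm) is far coarser than the 150 µm lateral pixel; with the
refinement, noiseless on-axis sources localize to micrometers across
20–100 mm. FWHM is measured on a lateral or axial profile through the peak
with linearly interpolated half-maximum crossings; lateral FWHM grows
roughly linearly with depth for the fixed aperture while axial FWHM is
depth-independent, the expected diffraction behavior.

## Baseline detector

The baseline slides normalized cross-correlation templates over the
processed frame: noiseless wavefront patches synthesized on a 9 (depth,
1/6–5/6 of the view) × 9 (lateral, ±90 % of the half-aperture) grid at
1540 m/s, cut as 17×33 patches with the apex offset from the patch center
recorded so a correlation peak maps back to a source position. Per pixel
the best template wins; peaks survive non-maximum suppression over a full
template footprint (one wavefront's flanks must not re-fire) and become
32×16 source-class boxes with confidence (score+1)/2.

Limitations, by design: the baseline cannot classify artifacts (every
detection is source-class, so artifact wavefronts become false positives),
it degrades for sources far outside the aperture where only a wavefront
tail is visible, and its correlation scores collapse on frames at the study
SNR range (−5 to 2 dB) — it is specified and tested in the noiseless
closed-loop regime. Its purpose is to exercise every downstream contract
(dataset → detections JSON → evaluation → rendering) without GPU training,
not to match a learned detector's metrics.

## Evaluation

A detection is retained if its confidence strictly exceeds its class
threshold. Retained detections are matched greedily in descending
confidence order; each ground truth is consumed at most once, by a
same-class true positive (IoU > 0.5) or else by an opposite-class
misclassification (IoU > 0.5). Every other retained detection is a plain
false positive; misclassifications are a subset of false positives on the
detection side. Each truth is therefore exactly one of detected /
misclassified / missed, giving the partition identity
recall + misclassification rate + missed rate = 100 % per class.

ROC curves sweep thresholds over the observed confidences. Object
detection has no true negatives, so FPR(τ) = FP(τ)/FP(0), making
FPR(0) = 1 (an FP-per-image normalization is the configurable
alternative). AUC is the trapezoid integral. The operating point slides a
line of slope FP₀/TP₀ from (FPR 0, TPR 1) down-and-right; the first curve
point touched maximizes TPR − slope·FPR, with ties taken at the smallest
FPR. The selected point is invariant to strictly monotone re-scalings of
the confidences.

Position errors convert matched box centers to world millimetres and are
stratified by aperture coverage (under: |lateral| ≤ 9.6 mm) and 10 mm
depth bins, left-open right-closed (group 1 = (15, 25] mm; a truth at
exactly 25 mm falls in group 1, at 25.01 mm in group 2).

## Rendering

Each source-class detection is drawn as a filled circle of radius 2σ on
the sector-masked grid, where σ is the Euclidean-error standard deviation
from the evaluation report (not a hard-coded constant). The pixel grid is
anisotropic, so circles are drawn as ellipses with radii radius/pixel
height rows × radius/pixel width columns — metrically round. Artifact
detections are never rendered; that omission is the artifact-removal
property of the display. Rendering is idempotent and order-independent.

## Problem sizes and what the tests show

The test suite and acceptance script run at desk scale: full-geometry
frames (3117×64), a handful of beamforming cases per property, 40-frame
evaluation fixtures, and a reduced 16-element/40 mm configuration for
brute-force oracles and the CLI round trip. Properties verified in the
closed loop — sub-pixel DAS localization, detector localization within two
processed pixels, SNR calibration, partition identities, histogram-metric
bounds — hold for the analytic wavefront model under the stated study
conditions. They do not establish performance on experimental channel
data, where waveform distortion, clutter, and annotation uncertainty enter;
the histogram-matching metrics (TVD/JD/χ², channel gCNR) are precisely the
instruments for quantifying that gap when such data is supplied through the
HDF5/JSON interfaces.
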