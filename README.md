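# patiploc

Photoacoustic catheter-tip localization pipeline for phased-array
transducers: channel-data simulation with reflection artifacts, sector-FOV
dataset building, histogram-matching domain adaptation with its similarity
and detectability metrics, delay-and-sum beamforming, object-detection
evaluation with ROC operating-point selection, and detector-based source
rendering.

## The problem

Guiding a cardiac catheter with photoacoustic imaging means finding the tip
of an optical fiber — a point source — in the raw channel data recorded by
a phased-array ultrasound transducer. Two things make this hard. First, a
phased array's scan-converted sector image is laterally much wider than its
physical aperture, so a source can sit far outside the aperture with only a
partial wavefront visible in the channel data. Second, sound bouncing off
echogenic structures creates *reflection artifacts*: duplicate wavefronts
that appear deeper than the true source by the source–reflector distance
and fool segmentation-based trackers.

A detector trained on simulated channel data can localize sources and
reject artifacts, but only if (a) the training frames are formatted to the
sector FOV — zero-padded to the scan-converted grid, then resized — and (b)
the amplitude-distribution gap between simulation and experiment is closed,
here by monotone histogram matching.

This package implements that full desk-scale pipeline with a classical
normalized-cross-correlation baseline detector standing in for a learned
network; any external detector can plug into the same evaluation through a
JSON interchange format.

## What it computes

- **Geometry.** For the default 64-element, 300 µm-pitch array sampled at
  40 MHz imaging to 120 mm at 1540 m/s: 3117 axial samples, a 1132-column
  scan grid (38.5 × 150 µm pixels), and 256×256 processed frames with
  662.9 × 468.8 µm pixels.
- **Simulation.** One point-source wavefront per frame (analytic
  time-of-flight hyperbola, Gaussian-enveloped pulse, 1/√r decay), optional
  reflection artifact, with axial position 20–100 mm, lateral ±57 mm,
  channel SNR −5 to 2 dB, intensity 0.75–1.1, and sound speed
  1440–1640 m/s in 6 m/s steps; 80/20 train/validation split.
- **Domain metrics.** Histogram distances between experimental (hₑ) and
  simulated (hₛ) frame histograms over 256 bins with bin means xₖ:
  TVD = 1 − Σₖ min{hₑ(xₖ), hₛ(xₖ)} ∈ [0, 1];
  JD = Σₖ [hₑ ln(hₑ/(hₑ+hₛ)) + hₛ ln(hₛ/(hₑ+hₛ))] ∈ [−2 ln 2, 0];
  χ² = Σₖ (hₑ−hₛ)²/(hₑ+hₛ) ∈ [0, 2];
  and the channel gCNR = 1 − Σₖ min{hᵢ, hₒ} between 18.2 × 5 mm target and
  background ROIs.
- **Evaluation.** IoU > 0.5 greedy matching; recall, precision, F1,
  misclassification and missed-detection rates (the three truth-side rates
  sum to 100 % per class); ROC curves with FPR normalized by the
  threshold-zero false-positive count; the optimal threshold by sliding a
  line of slope FP₀/TP₀ from the ideal corner; position errors stratified
  by aperture coverage and 10 mm depth bins.
- **Rendering.** Detected sources drawn as filled circles of radius 2σ
  (σ = the validation Euclidean-error standard deviation) on the sector
  FOV; artifact detections are never drawn.

## Worked example

```python
from patiploc import (TransducerSpec, ImagingConfig, SimulationParams,
                      simulate_dataset, realize_frame, process_frame,
                      build_template_bank, detect, categorize, compute_metrics,
                      position_errors, processed_grid)

spec, config = TransducerSpec(), ImagingConfig()
params = SimulationParams(n_frames=8, artifact_fraction=0.0,
                          lateral_range_mm=(-9.0, 9.0), rng_seed=42)
manifest = simulate_dataset(params, spec, config)

bank = build_template_bank(spec, config)
matched = []
for fs in manifest.frames:
    frame = realize_frame(fs, spec, config, noiseless=True)
    pf = process_frame(frame, spec, config)
    dets = detect(pf, bank, score_floor=0.5)
    matched.append(categorize(dets, pf.annotations,
                              {"source": 0.6, "artifact": 0.6}))

report = compute_metrics(matched)
m = report.per_class["source"]
print(f"source recall    {m.recall_pct:5.1f} %")
print(f"source precision {m.precision_pct:5.1f} %")
print(f"source F1        {m.f1_pct:5.1f} %")
errors = position_errors(matched, processed_grid(config, spec), spec)
print(f"mean Euclidean error {errors.euclidean_error_mm.mean():.2f} mm (n = {len(errors)})")
```

prints

```
source recall    100.0 %
source precision  88.9 %
source F1         94.1 %
mean Euclidean error 0.59 mm (n = 8)
```

Eight noiseless under-aperture sources are all found (recall 100 %); one
flank of a wavefront survives non-maximum suppression as a false positive
(precision 88.9 %), and the matched detections localize their sources to
0.59 mm on average — under one processed pixel in each dimension.

The same flow is available from the shell:

```sh
patiploc simulate --n-frames 20 --seed 1 --out frames.h5
patiploc build-dataset --input frames.h5 --out dataset/
patiploc detect --dataset dataset/ --out detections.json
patiploc evaluate --detections detections.json --dataset dataset/ \
    --thresholds auto --out report.json
patiploc render --detections detections.json --sigma 0.84 --out sources.png
```

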