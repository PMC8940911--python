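# Methods

This note documents the models, parameter choices, and numerical conventions
behind `somatrace`, and what the synthetic benchmarks do and do not show
about real data.

## Pipeline model and assumptions

The pipeline assumes raster-scanned grayscale fluorescence movies in which
neuronal somata are compact bright regions a detector can box frame-by-frame,
and in which the dominant nuisance signals are (i) additive per-pixel noise,
(ii) a slow multiplicatively-uniform background ("neuropil") signal shared
across the field of view, and (iii) rigid lateral drift. Non-rigid
deformation, photobleaching, and scan-line artifacts are out of scope.

Detection is decoupled from trace extraction: detection updates arrive at the
cadence of the averaging buffer, while every raw frame produces one trace
sample per known identity. This decoupling is a *contract*: the outputs of
any scheduling of the work must equal the sequential reference
implementation (`run_online`); `run_online_threaded` demonstrates the
contract with a producer/consumer schedule and is tested for bitwise
equality.

### Overlap measure

The pairwise overlap used for duplicate suppression and identity association
is intersection area over the **sum** of the two areas, `I/(A₁+A₂)`, bounded
by 0.5. All 20 %/25 % thresholds in the pipeline refer to this measure; it is
deliberately kept distinct from standard IoU (`I/(A₁+A₂−I)`), which is used
only for the mean-IoU quality score of matched detections and offered as a
config alternative elsewhere. For ground-truth matching at the 0.5 cutoff the
measure is intersection over the *smaller* box area — the most permissive
reading compatible with a 0.5 threshold, chosen because a tight detection
fully inside a generous hand-drawn box should count as a hit; standard IoU is
again available by argument.

### Tracking

Matching is greedy (candidate pairs sorted by descending overlap, accepted
one-to-one) with deterministic tie-breaks; a globally optimal assignment
(Hungarian) is available via `matching="optimal"`. Greedy is the default
because it is fast, deterministic, and on well-separated somata identical to
the optimal assignment. The new-identity threshold defaults to 0.2; 0.25 is a
documented alternative preset. Unmatched identities are rigid-shifted by the
mean center displacement of the matched ones (rounded to 0.1 px), clipped to
the FOV, and never deleted; if nothing matched, they stay in place. A
detection that overlaps an already-claimed identity above threshold but loses
the one-to-one race is dropped rather than allowed to found a duplicate
identity.

### Segmentation and background

Percentiles use linear interpolation between order statistics (the numpy
default), pinned by a sort-based brute-force oracle in the tests. The
[P80, P95] window is closed on both ends. In small boxes the closed interval
can be empty (no data point falls between two interpolated order
statistics); the pixel nearest the window is then used, so a soma mean is
always defined. Pixels inside two overlapping boxes contribute to both
cells' distributions — no exclusivity rule. The background is the mean of
*all* non-box pixels; the local (doubled concentric box) background exists as
an analysis utility only, since global and local background traces are
nearly identical in practice and the global form is O(FOV) per frame.
Inactive identities keep being extracted at their last (rigid-shifted) box;
freezing them instead is a flag (`shift_inactive=False`).

## Detector

The reference detector is multiscale Laplacian-of-Gaussian blob detection:
scale-normalised responses `−σ²∇²G` over σ ∈ [2, 8] px, peak-picked in scale
space; each blob becomes a square box of side 2√2·σ; scores are the blob
responses normalised by the image's maximum response, so scores are relative
within one image (a consequence: the score threshold selects relative
prominence, not absolute brightness). A trained neural-network detector can
be plugged in through `cnn_adapter`, which binds an external ONNX model to
the same interface; its absence never blocks the library. Boxes come back in
detector-input coordinates and are divided by the upscale factor and rounded
half-up in exactly one place (`boxes_to_native`).

## Preprocessing conventions

* 8-bit conversion rescales with the image's own min/max.
* The enhancement used for annotation images (sharpen with the 3×3 high-boost
  kernel, γ = 0.3 on [0, 1]-normalised values, renormalise to the full 8-bit
  range) uses reflect padding for the convolution, so borders do not acquire
  dark rims that would distort the rescale; a constant image maps to mid-gray
  with a logged warning.
* Registration is phase correlation against the raw median projection,
  corrections clipped to ±13 px and quantised to 0.1 px; integer-only mode is
  the `subpixel=False` flag. The buffer warm-up lag is strictly
  n / frame-rate seconds.
* The sliding buffer is a running sum with add/subtract update; the contract
  (equality with the brute-force window mean) is what the tests pin.

## Synthetic data: what it emulates, and what it does not

A scene is a set of disk somata (hard disk, 1-px Gaussian edge — crisp
in-focus cells) with double-exponential GECI transients
`e^(−t/τ_d) − e^(−t/τ_r)` (unit peak; defaults τ_r = 0.1 s, τ_d = 0.6 s,
GCaMP6-like at the default 3 Hz frame rate), Poisson spike trains
(0.15 Hz/cell), a shared low-pass-filtered Gaussian neuropil signal, i.i.d.
Gaussian pixel noise, and optional rigid drift applied as a linear ramp with
sub-pixel bilinear interpolation, with the ground-truth boxes translated
per frame. Off-FOV pixels exposed by the shift are filled with the baseline
value; cropping the maximal-displacement margin instead is an option.
Ground-truth traces are the cells' intrinsic (noiseless) somatic signals, so
they are exact to machine precision rather than re-measured from the movie.

The reference study conditions are 256×256 px at 0.8 µm/px, 3 Hz, 300
frames, 20 cells with ≥3-radii spacing, baseline 20 a.u., soma brightness
40–80 a.u.; the "noisy" condition adds σ = 4 a.u. pixel noise, which brings
the movie mean/SD SNR to ≈ 2.

What passing these benchmarks does **not** show: real somata are not
disks, neuropil is not spatially uniform, noise is not Gaussian or
stationary, drift is not the only motion, and real detector scores are not
relative LoG responses. The synthetic results validate the *pipeline
machinery* — bookkeeping, thresholds, subtraction, and their interactions —
not detector performance on biological images, which is a property of the
plugged-in model.

## Numerical choices and degenerate inputs

* Box convention: 0-based, half-open, x = column; VOC's 1-based inclusive
  coordinates are converted only at the XML boundary. Sub-pixel box edges
  snap to the grid by round-half-up.
* NMS ties: descending score, then smaller (y_min, x_min).
* Precision with no predictions is 0; recall with no ground truth is 1; F-1
  with both components 0 is 0.
* SNR uses the population (divide-by-N) standard deviation and is undefined
  (an error) for constant input.
* Constant traces get NaN rows in the correlation matrix (logged), the
  diagonal stays 1.
* A box pushed fully outside the FOV is frozen at the border with 1 px of
  extent rather than deleted, so its identity survives.
* An empty detection list, an empty registry, and a frames-before-detection
  prefix are all representable and round-trip through the I/O layer (missing
  values stay missing).

## Benchmark problem sizes

The bundled end-to-end checks use 256×256 × 300-frame movies for detection
recovery, 192×192 × 150 frames for the decorrelation analysis, 256×256 × 120
frames for the drift runs, and 1000-sample traces for event detection —
sizes at which every check completes in seconds on one CPU while still
exercising the full pipeline. Drift conditions are 8 µm over 20 s (slow; the
tracker must hold all identities) and 16 µm over 0.5 s (fast; the per-frame
jump exceeds the overlap-association radius, so duplicated identities are
the expected, documented degradation).

## Known limitations

* The mesoscopic tiling keeps full recall but admits partial-cell fragments
  at tile cut edges (the paired full box and fragment overlap too little
  under the area-sum measure to be suppressed); precision at seams is
  correspondingly lower.
* The online F-1 of the grid searches is measured on the final tracked box
  set; per-emission curves are available via `evaluate_online_run`.
* Identity merging after creation is deliberately absent: duplicated
  identities under fast drift persist, matching the retained-identity design.
* The frame-replay driver simulates a streaming source; integrating a real
  microscope feed means pushing frames into `run_online`'s iterator — no
  vendor API is included.
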