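# Methods

This note records the models, conventions and numerical choices behind
`endocube`, and what its simulation-based tests do and do not demonstrate.

## Acquisition model and the simulator

The instrument model is a line-scan (pushbroom) hyperspectral endoscope:
every exposure yields a 2-D spectral slice (spatial *y* × wavelength *λ*)
through the spectrograph entrance slit, plus an intrinsically co-registered
monochrome wide-field frame.  Because both views share the optical path up
to a beam splitter, a geometric transform estimated between wide-field
frames applies verbatim to the slices taken at the same instants.

The simulator (`endocube.simulation`) emulates this acquisition against a
known scene so that every downstream stage can be scored against ground
truth:

* **Scene** — a procedurally rendered USAF-1951-style chart: rows of
  three-bar elements with graded bar widths (default 10–31 px, cycling row
  by row), each element assigned one of *n* spectral profiles.  Profiles
  are random mixtures of 2–3 Gaussians over the channel axis, clipped to
  [0, 1]; the shapes are implementer-defined since only "smooth distinct
  reflectance profiles" is specified by the validation design.  Defaults:
  1120 × 560 px, 6 profiles, 100 channels — sized so a default scan holds
  exactly 74 frames of 512 px stepping 8 px.
* **View distortions** — frame *k* translates by *k*·8 px along the scan
  axis and draws, independently and uniformly, a y-shift in [2, 7] px, a
  rotation in [0.54, 0.71]° and a magnification in [−0.15, +1.36] %,
  applied about the frame centre.  These per-frame absolute draws emulate
  freehand jitter around a nominal scan; an *incremental* reading of the
  y-shift would walk off any plausible scene within tens of frames.
* **Sensor signature** — the wide-field frame is the spectral sum of the
  warped crop, multiplied by a circular field mask (radius 250 px on a
  512 px crop) and a honeycomb lattice (three cosines at 60° spacing,
  pitch 6 px, depth 0.5, static in frame coordinates — the fibre bundle
  moves with the camera, not the scene), plus additive uniform dark noise
  in [0, 0.02·max].  Whether real dark noise is uniform or Gaussian is not
  critical at this amplitude; uniform was chosen and kept.
* **Spectral slice** — the per-wavelength mean over the `slit_width`
  central columns of the warped crop (default 10 px), centred on the
  optical axis.  Slices are generated noise-free; the sensitivity of the
  pipeline to noise enters through the wide-field registration arm.

What the simulator does **not** model: optical PSF and chromatic
aberration, shot noise, fibre-to-fibre crosstalk, specular reflections,
non-rigid tissue deformation, and illumination inhomogeneity beyond the
field mask.  Tests passing on simulated data therefore demonstrate the
correctness of the *computational* pipeline under the stated geometric and
noise conditions, not robustness to every physical effect of a real
endoscope.

## Pre-processing

Fixed order: reflectance normalisation → lens correction → honeycomb
removal → field crop.

* **Normalisation** `(I − I_dark)/(I_white − I_dark)` with the denominator
  guarded at ε = 1e−6; non-positive-denominator pixels are flagged in the
  validity mask, never filled.
* **Lens correction** is a uniform radial rescale by α about the optical
  centre (bilinear resampling), with an optional polynomial α(r) for
  radially varying magnification.  No auto-calibration: α is a config
  parameter (α = 1 for simulated data, which has no barrel distortion).
* **Honeycomb removal** is a hard radial low-pass in the 2-D Fourier
  domain.  A hard mask was chosen over a smooth roll-off because it is
  exactly idempotent and preserves the mean.  The `auto` cutoff is 0.6 ×
  the lattice fundamental, which is found as the strongest detrended peak
  of the radially binned power spectrum above 0.06 cycles/px; when no
  prominent peak exists the cutoff falls back to 0.25 cycles/px.
  Limitation: a multiplicative lattice over a sharp-edged scene produces
  difference-frequency moiré *below* any cutoff that preserves the scene;
  this residual is why registration is feature-based rather than
  intensity-based (see below).
* **Field crop** thresholds at 0.1 × the 99.5th-percentile intensity and
  takes the convex hull (bridging dark scene regions inside the field),
  then crops to its bounding box; `inscribed=True` instead crops to the
  largest axis-aligned square inside the field.  The crop updates the
  frame origin so keypoint coordinates stay in acquisition coordinates.

## Registration

* **Features** — SIFT (`upsampling=1, n_octaves=3`; ~20× faster than the
  detector defaults on 512 px frames at equal pairwise accuracy on these
  targets).  Keypoints are discarded when their distance to the field
  boundary is below max(4 px, 3 × their detection scale σ): the bundle
  edge is identical in every frame, and a keypoint whose Gaussian support
  touches it has its localisation dragged toward zero motion.  This
  scale-proportional margin removed a measured ~0.03 px/pair systematic
  bias while keeping the small-scale keypoints that carry most of the
  alignment information.
* **Pairwise fit** — descriptor matching with cross-check and Lowe ratio
  0.8, then RANSAC (similarity model, inlier tolerance 1.5 px, minimum 8
  inliers, ≤ 2000 trials, seeded), followed by two least-squares re-fits on
  matches within ⅔ of the tolerance.  The tighter re-fit measurably halves
  rotation/scale noise by trimming boundary inliers.  Failure is a status,
  not an exception.
* **Topology** — anchored sequential chaining: every 8th frame is an
  anchor matched directly to the previous anchor; every other frame is
  matched directly to its nearest anchor.  Plain consecutive chaining was
  implemented first (`anchor_span=1` still provides it, and
  `chain_to_global` composes externally supplied consecutive pairs), but
  measurement showed it accumulates a random-plus-bias drift of ~1–2 px
  over 74 frames — above the 0.5 px recovery tolerance — whereas anchoring
  crosses ~k/8 links instead of k and stays well inside it.  This is still
  strictly sequential matching with no global bundle adjustment.  Failed
  anchor links are bridged by composing the consecutive pairs across the
  gap (status `fallback`); unreachable frames are `failed` and excluded
  downstream.
* **Reference frame** — the full-scale validation driver registers to the
  frame at the middle of the scan rather than the first.  A per-link scale
  error ε, compounded along the chain, displaces a frame's centre by
  roughly ε × (distance to the reference); with an end reference the far
  end of a 74-frame scan sits ~580 px away and scene-dependent per-link
  scale biases of ~1e−4 turn into 0.6–1 px of translation drift, while a
  central reference halves both the number of links and the lever arm
  (measured: worst-case frame error drops from ~0.7–0.9 px to ~0.2–0.3 px
  across scenes).  Any reference yields the same mosaic up to a global
  similarity; `register_sequence` takes the reference index explicitly.
* **Panorama** — frames are warped bilinearly onto the union canvas in the
  reference frame's coordinates; overlaps are averaged via per-pixel sums
  and counts, so frame order is irrelevant.  Uncovered pixels are NaN with
  coverage 0 (distinct from a measured zero).

## Hypercube reconstruction

For each slice and wavelength, the slice column is replicated to the slit
width, positioned at the frame's central columns, warped by the frame's
global transform and accumulated on the canvas (sums + counts per
wavelength; a single wavelength-independent coverage map).  Conventions:

* slit centred on the frame's central column; slice rows map 1:1 to frame
  rows (the instrument's intrinsic co-registration), with a configurable
  offset if a real instrument needs one;
* the slit width in wide-field pixels equals the simulated slit width; for
  real data the wide-field↔spectrograph pixel-scale ratio is a config
  parameter (`slit_width_px` on the slice);
* within a strip, interpolation is bilinear along y; across the slit the
  profile is constant by construction, so membership is a half-open
  interval test — identical to bilinear warping except in the outermost
  half-pixel;
* the canvas is the union of warped strip footprints, in the same
  reference coordinates as the panorama, so cube and panorama overlay
  directly.

## Spectral endpoints

* **Absorbance** `A = −log10(I/I0)`: reflectance is clipped at 1e−6 before
  the log and clipped pixels are flagged invalid (NaN), never silently 0.
* **Synthetic RGB**: Rayleigh-pdf filters with modes at 442, 518, 579 nm
  (blue/green/red) and scale 45 nm (the width is not prescribed; 45 nm
  gives camera-like ~50 nm half-widths without inter-channel dead zones).
  Each filter is normalised to unit integral so a flat spectrum is grey,
  and the image is scaled so its 99th percentile maps to full range —
  "unsaturated" made precise.
* **NNLS unmixing**: for two endmembers the KKT conditions give a closed
  form (unconstrained solution if feasible, else the better single-
  endmember fit), vectorised over pixels and verified against
  `scipy.optimize.nnls`, which also serves the general k-endmember path.
  sO₂ = α/(α+β) is NaN where α+β = 0.
* **SAM group test**: per-pixel angles against the reference, one-way
  ANOVA across region angle distributions, Tukey HSD post-hoc (the
  post-hoc family is not prescribed; Tukey HSD controls the family-wise
  error over all pairs).
* **Clustering**: 5×5 mean pooling (NaN-aware), full-SVD PCA keeping the
  smallest component count reaching the variance target (default 99.9 %),
  k-means with k-means++ init, 10 restarts, fixed seed.

## Metrics

* **Michelson contrast** from a least-squares sinusoid fit (amplitude,
  offset, phase free; frequency fixed by the known element spacing, or
  taken from the dominant Fourier component when unknown); amplitude is
  clamped to the offset so implied intensities stay non-negative.
* **Spatial resolution**: contrast regressed linearly on spatial
  frequency; resolution = half-period at the 0.01-contrast crossing.  The
  cut-off phrase "1 % contrast" is read as absolute 0.01 and is
  configurable.
* **Spectral FWHM**: Gaussian-plus-background fit around the highest
  sample; background referenced to the median outside ±3σ; a peak must
  exceed background by 3 × the off-peak noise SD.
* **Cube fidelity**: per-channel Pearson r and RMSE plus mean per-pixel
  spectral angle on covered pixels, against the ground-truth scene sampled
  on the canvas.  The canvas-to-scene mapping needs the reference frame's
  true view transform, which only the simulator knows, so fidelity takes
  that transform explicitly rather than a registration chain.

## Problem sizes and determinism

The unit suite runs reduced scenes (≈ 480 × 280 px, 16–24 channels, 12–16
frames of 192–256 px) chosen to keep the full suite near ten seconds while
preserving every geometric ingredient; tolerance bounds there are scaled
for the reduced keypoint counts and angular lever arms, as noted in the
tests.  The acceptance suite and `scripts/acceptance.py` run the full
study conditions (74 frames of 512 px, 6 profiles × 100 channels, both
noise arms).  All randomness — scene, distortion draws, noise, RANSAC,
k-means — flows from explicit integer seeds; identical seeds give
identical outputs.

## Known limitations

* The honeycomb filter removes the lattice's own spectral peaks but not
  the low-frequency moiré of lattice × sharp scene edges; on real tissue
  (smoother scenes) this term is weaker than on bar targets.
* Similarity transforms cannot represent perspective or non-rigid tissue
  motion; an affine extension would capture shear but the validation
  conditions do not include it.
* Anchored chaining still accumulates error across anchors (~k/8 links);
  scans an order of magnitude longer than 74 frames would need loop
  closure or bundle adjustment, both out of scope.
* ENVI I/O covers the plain header + BSQ float layout this package writes,
  not the full ENVI dialect.
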