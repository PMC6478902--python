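# endocube

Reconstruction and analysis of **line-scan (pushbroom) hyperspectral
endoscopy** data.

A line-scan hyperspectral endoscope records, at every exposure, one spatial
line with a full spectrum (a *y* × *λ* slice through a spectrograph slit)
together with an intrinsically co-registered wide-field monochrome frame.
The second spatial axis is swept not by a motor but by the natural freehand
motion of the endoscope — which also introduces translation, rotation and
magnification changes between exposures.  `endocube` turns such a stream
into a clean 3-D hypercube (*x*, *y*, *λ*) and derives the clinical
endpoints a gastroenterology imaging group would ask for:

* **Registration** — SIFT features + RANSAC estimate each frame's 3×3
  geometric transformation matrix **GM** (similarity: translation,
  rotation, magnification); frames are chained to a global coordinate
  system and mosaicked into a panorama.
* **Reconstruction** — each spectral slice column is replicated to the
  physical slit width, warped by its frame's **GM**, and overlapping
  contributions are averaged per wavelength, yielding the hypercube.
* **Pre-processing** — reflectance normalisation
  *I*<sub>nor</sub> = (*I* − *I*<sub>dark</sub>)/(*I*<sub>white</sub> − *I*<sub>dark</sub>),
  radial lens-distortion correction (*x*<sub>c</sub> = *x*₀ + *αr* cos *θ*),
  fibre-bundle honeycomb removal by low-pass Fourier filtering, and field
  cropping.
* **Spectral endpoints** — Beer–Lambert absorbance
  *A* = −log₁₀(*I*/*I*₀); synthetic RGB through Rayleigh-shaped filters
  centred at 442/518/579 nm; NNLS unmixing
  *S* = *α S*<sub>oxy</sub> + *β S*<sub>deoxy</sub> with
  sO₂ = *α*/(*α*+*β*); the spectral angle mapper
  *θ* = cos⁻¹(⟨t, r⟩/‖t‖‖r‖); and unsupervised tissue segmentation by
  5×5 binning + PCA (≥ 99.9 % variance) + *k*-means.
* **Metrics** — Michelson contrast (*I*<sub>max</sub> − *I*<sub>min</sub>)/(*I*<sub>max</sub> + *I*<sub>min</sub>)
  with a 1 % cut-off for spatial resolution, Gaussian FWHM for spectral
  resolution, and fidelity scoring against simulation ground truth.
* **Simulation** — a built-in emulator renders a USAF-1951-style spectral
  target and replays the whole acquisition (512×512 crops, 250 px circular
  field, honeycomb lattice, 8 px x-steps, randomised y-shift 2–7 px,
  rotation 0.54–0.71°, magnification −0.15–1.36 %, ~2 % dark noise), so
  every stage is testable without instrument data.

## Worked example

`examples/01_simulate_and_reconstruct.py` scans a 4-profile target in 16
noisy frames, registers and reconstructs it:

```
registered 16/16 frames
median recovery error: 0.328 px translation, 0.0766 deg rotation, 0.448% scale
hypercube (259, 129, 24) (y, x, lambda), 98.1% of canvas covered
mean per-channel Pearson r vs ground truth: 0.936
profile spectral angles (rad): 0: 0.0037, 1: 0.0001, 2: 0.0035
```

Every frame registered despite the randomised distortions; the recovered
transforms are within a third of a pixel of the truth, and the rebuilt
per-pixel spectra point within a few milliradians of the profiles that
generated them.  The other examples demonstrate oxygen-saturation
unmixing, SAM region statistics with ANOVA/Tukey, resolution metrics and
tissue clustering — each prints its numbers and what they mean.

A thin CLI wraps the same library calls:

```bash
endocube simulate --out scan/ --seed 7
endocube register --frames scan/frames.tif --out scan/chain.json
endocube reconstruct --slices scan/slices.tif --chain scan/chain.json --out scan/cube
endocube unmix --cube scan/acube --endmembers lib.csv --out scan/coeffs.tif
```

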