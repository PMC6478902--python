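"""Simulate a small freehand scan, register it and reconstruct the hypercube.

A 4-profile spectral target is scanned in 16 frames of 256 x 256 px with
randomised y-shift, rotation, magnification and 2% dark noise.  The
wide-field frames are conditioned (honeycomb removal, field crop),
registered by SIFT + RANSAC into per-frame geometric transformation
matrices, and the line-scan slices are warped onto the global canvas to
form the (y, x, lambda) cube, which is then scored against ground truth.
"""

import numpy as np

from endocube import preprocess as pp
from endocube import registration as reg
from endocube.metrics import cube_fidelity, profile_recovery_angles
from endocube.reconstruction import reconstruct_hypercube
from endocube.simulation import DistortionParams, emulate_sequence, make_insilico_target

target = make_insilico_target(width=560, height=320, n_profiles=4, n_channels=24, seed=7)
params = DistortionParams(seed=7)  # 8 px steps, y 2-7 px, rot 0.54-0.71 deg, 2% noise
acq = emulate_sequence(target, params, n_frames=16, crop_size=256, mask_radius=125,
                       slit_width=10)

frames = [pp.preprocess_frame(f, cutoff="auto", crop=True) for f in acq.frames]
chain = reg.register_sequence(frames, seed=0)
print(f"registered {chain.n_registered}/{acq.n_frames} frames")

errs = [est.compare(true, extent=256)
        for est, true in zip(chain.transforms, acq.true_globals()) if est]
errs = np.array(errs)
print(f"median recovery error: {np.median(errs[:,0]):.3f} px translation, "
      f"{np.median(errs[:,1]):.4f} deg rotation, {100*np.median(errs[:,2]):.3f}% scale")

cube = reconstruct_hypercube(acq.slices, chain)
print(f"hypercube {cube.data.shape} (y, x, lambda), "
      f"{100*(cube.coverage>0).mean():.1f}% of canvas covered")

report = cube_fidelity(cube, target, acq.true_transforms[0])
angles = profile_recovery_angles(cube, target, acq.true_transforms[0])
print(f"mean per-channel Pearson r vs ground truth: {report.mean_pearson:.3f}")
print(f"profile spectral angles (rad): "
      + ", ".join(f"{k}: {v:.4f}" for k, v in sorted(angles.items())))
print("-> r near 1 and angles near 0 mean the scan geometry was recovered "
      "well enough to rebuild both spatial patterns and spectra.")
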