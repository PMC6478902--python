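"""Oxygen saturation by non-negative least-squares spectral unmixing.

Absorbance spectra of blood-like mixtures are modelled as
S(lambda) = alpha * S_oxy(lambda) + beta * S_deoxy(lambda); NNLS recovers
the non-negative coefficients and sO2 = alpha / (alpha + beta).  Here a
phantom of five oxygenation levels with 1% measurement noise is unmixed.
"""

import numpy as np

from endocube.spectral_analysis import (
    AbsorbanceCube,
    nnls_unmix,
    synthetic_hemoglobin_library,
)

lib = synthetic_hemoglobin_library()
rng = np.random.default_rng(0)

print("true sO2   recovered (mean +- sd over 400 noisy pixels)")
for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
    mix = frac * lib["oxy"] + (1 - frac) * lib["deoxy"]
    noisy = mix + rng.normal(0, 0.01 * mix.mean(), (1, 400, len(lib.wavelengths)))
    acube = AbsorbanceCube(noisy, lib.wavelengths, np.ones((1, 400), bool))
    res = nnls_unmix(acube, lib)
    print(f"  {frac:4.2f}     {np.nanmean(res.so2):.3f} +- {np.nanstd(res.so2):.3f}")
print("-> the recovered saturation tracks the mixing fraction; residual bias "
      "at the extremes comes from the non-negativity constraint clipping noise.")
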