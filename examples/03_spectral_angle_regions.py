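"""Compare tissue-region spectra with the spectral angle mapper (SAM).

The spectral angle arccos(<t, r> / |t||r|) measures similarity between a
target and a reference spectrum independent of absolute absorbance scale.
Three synthetic 'tissue' regions are scored against a reference; a one-way
ANOVA with Tukey HSD post-hoc tests asks which regions differ.
"""

import numpy as np

from endocube.spectral_analysis import AbsorbanceCube, sam_classify

rng = np.random.default_rng(1)
wl = np.linspace(450, 700, 40)
reference = 0.3 + 0.6 * np.exp(-0.5 * ((wl - 560) / 35) ** 2)  # "cancer-like"
profiles = [
    reference,                                                  # same as reference
    0.3 + 0.6 * np.exp(-0.5 * ((wl - 530) / 35) ** 2),          # shifted peak
    0.25 + 0.5 * np.exp(-0.5 * ((wl - 620) / 40) ** 2),         # distinct
]

n = 80
data = np.stack([p + rng.normal(0, 0.02, (n, 40)) for p in profiles], axis=0)
regions = np.repeat(np.arange(3)[:, None], n, axis=1)

res = sam_classify(AbsorbanceCube(data, wl, np.ones((3, n), bool)), reference, regions)
print(res.per_region.to_string(index=False))
print(f"one-way ANOVA: F = {res.anova_f:.1f}, p = {res.anova_p:.2e}")
print(res.posthoc.to_string(index=False))
print("-> region 0 matches the reference (angle near 0); the post-hoc table "
      "shows which pairwise differences in mean angle are significant.")
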