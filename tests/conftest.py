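"""Shared fixtures: small simulated scenes and acquisitions.

Everything is generated programmatically with fixed seeds; the scales are
reduced (smaller scenes, fewer channels and frames) so the whole unit
suite stays fast, while the acceptance tests run the full-scale study
conditions.
"""

import numpy as np
import pytest

from endocube import simulation as sim


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_target():
    """Dense 4-profile target, 16 channels; enough texture for registration."""
    return sim.make_insilico_target(
        width=480, height=280, n_profiles=4, n_channels=16, seed=11
    )


@pytest.fixture(scope="session")
def small_params():
    return sim.DistortionParams(seed=11)


@pytest.fixture(scope="session")
def small_acq(small_target, small_params):
    """12-frame scan of the small target with the default distortion ranges."""
    return sim.emulate_sequence(
        small_target,
        small_params,
        n_frames=12,
        crop_size=192,
        mask_radius=90,
        slit_width=6,
    )


@pytest.fixture(scope="session")
def clean_acq(small_target):
    """Zero-noise, honeycomb-free scan: the parameter-recovery round trip."""
    params = sim.DistortionParams(seed=5, noise_level=0.0)
    return sim.emulate_sequence(
        small_target,
        params,
        n_frames=12,
        crop_size=192,
        mask_radius=90,
        honeycomb_depth=0.0,
        slit_width=6,
    )
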