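"""Shared fixtures: small synthetic subjects and cohorts."""

import numpy as np
import pytest

from aneucloud import (
    CohortConfig,
    generate_cohort,
    make_sac_geometry,
    simulate_hemo_fields,
    two_harmonic_waveform,
)
from aneucloud.hemodynamics import derive_channels
from aneucloud.regions import extract_region

SMALL_COHORT_CONFIG = CohortConfig(n_geometry_points=400)


@pytest.fixture(scope="session")
def waveform():
    return two_harmonic_waveform()


@pytest.fixture(scope="session")
def hemisphere():
    """Hemispherical sac, radius 3 mm, on a 4 mm parent vessel."""
    return make_sac_geometry(radius=3, neck_width=6, parent_diameter=4,
                             n_points=2000, seed=7)


@pytest.fixture(scope="session")
def small_cloud(hemisphere, waveform):
    cloud = simulate_hemo_fields(hemisphere, waveform, label="ruptured",
                                 signal_mode="both", noise_sd=0.2, seed=3)
    derive_channels(cloud)
    return cloud


@pytest.fixture(scope="session")
def tiny_cohort():
    """20 balanced subjects with spatial class signal, small geometries."""
    cohort = generate_cohort(20, 0.5, "spatial", seed=5,
                             config=SMALL_COHORT_CONFIG)
    for cloud in cohort:
        derive_channels(cloud)
    return cohort


@pytest.fixture(scope="session")
def tiny_regions(tiny_cohort):
    return [extract_region(c, n=128, seed=i) for i, c in enumerate(tiny_cohort)]


@pytest.fixture(scope="session")
def tiny_labels(tiny_cohort):
    return np.array([1 if c.label == "ruptured" else 0 for c in tiny_cohort])
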