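"""Shared fixtures: synthetic images and cohorts, cached per session."""

import numpy as np
import pytest

from octava.image_io import AngioImage
from octava.synthetic_octa import (
    SyntheticParams,
    generate_cohort,
    generate_vessel_image,
)


def as_angio(sample, **kw):
    p = sample.params
    meta = {"fov_mm": p.fov_mm, "plexus": p.plexus, "laterality": p.laterality}
    meta.update(kw)
    return AngioImage(pixels=sample.image, **meta)


@pytest.fixture(scope="session")
def vessel_sample():
    """Default 320-px angiogram (5% sector densities, 0.35 mm FAZ)."""
    return generate_vessel_image(SyntheticParams(seed=3))


@pytest.fixture(scope="session")
def faz_radius_samples():
    """One angiogram per FAZ radius used in the recovery experiments."""
    return {
        r: generate_vessel_image(SyntheticParams(faz_radius_mm=r, seed=7))
        for r in (0.2, 0.3, 0.4, 0.5)
    }


@pytest.fixture(scope="session")
def density_target_samples():
    """Angiograms at global density targets 1/2/4% (monotonicity checks)."""
    return {
        t: generate_vessel_image(SyntheticParams(target_density=t, seed=11))
        for t in (1.0, 2.0, 4.0)
    }


@pytest.fixture(scope="session")
def recovery_cohort():
    """n=200 consultations with the default linear VA link, sigma=0.05."""
    return generate_cohort(n=200, seed=42, noise_sigma_va=0.05)


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    """Grid-searched SVR fitted on the recovery cohort's true features."""
    from octava.va_model import SearchConfig, VisualAcuityModel

    X = np.array([s.features_true for s in recovery_cohort.samples])
    va = np.array(recovery_cohort.va_true)
    return VisualAcuityModel(X, va).fit(SearchConfig(seed=0))


@pytest.fixture(scope="session")
def random_blobs():
    """50 random blobby binary masks for skeleton property checks."""
    rng = np.random.default_rng(2024)
    from scipy import ndimage

    blobs = []
    for _ in range(50):
        field = ndimage.gaussian_filter(rng.normal(size=(64, 64)), sigma=4.0)
        blobs.append(field > np.percentile(field, 70))
    return blobs
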