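"""Shared fixtures: programmatically generated phantom data.

The study-condition constants (spacing, background, blur, noise, lesion
sizes) are fixed here once and shared between the unit, property and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from petseg import (BinaryMask, LesionSpec, PhantomConfig, build_dataset,
                    generate_phantom)

# Desk-scale study conditions: 4 mm voxels, SUV-1 background, 7 mm PSF.
SPACING = (4.0, 4.0, 4.0)
GRID = (48, 48, 48)
PSF_FWHM = 7.0
MODERATE_NOISE = 0.2     # SUV; the TF regime
HIGH_CONTRAST_NOISE = 0.1  # SUV; the CNN high-contrast regime
BOX = (32, 32, 32)


def random_lesion_cfg(rng: np.random.Generator, seed: int,
                      peak_range=(4.0, 10.0), radii_range=(8.0, 16.0),
                      noise_sd=MODERATE_NOISE) -> PhantomConfig:
    """One random ellipsoidal lesion per phantom under the study conditions."""
    radii = rng.uniform(*radii_range, 3)
    centre = rng.uniform(70.0, 122.0, 3)
    peak = rng.uniform(*peak_range)
    return PhantomConfig(
        shape=GRID, spacing=SPACING,
        lesions=(LesionSpec(tuple(centre), tuple(radii), float(peak)),),
        psf_fwhm=PSF_FWHM, noise_sd=noise_sd, seed=seed,
    )


def make_dataset(n: int, seed: int, *, peak_range=(4.0, 10.0),
                 radii_range=(8.0, 16.0), noise_sd=MODERATE_NOISE,
                 box=BOX):
    """n single-lesion phantoms -> n bounding-box samples."""
    rng = np.random.default_rng(seed)
    cfgs = [random_lesion_cfg(rng, seed * 10000 + i, peak_range=peak_range,
                              radii_range=radii_range, noise_sd=noise_sd)
            for i in range(n)]
    return build_dataset(cfgs, seed=seed, box=box)


@pytest.fixture(scope="session")
def plateau_phantom():
    """Noise-free, blur-free sphere plateau (peak 8, background 1)."""
    cfg = PhantomConfig(
        shape=(32, 32, 32), spacing=SPACING,
        lesions=(LesionSpec((64.0, 64.0, 64.0), (12.0, 12.0, 12.0), 8.0),),
        psf_fwhm=0.0, noise_sd=0.0, seed=0,
    )
    vol, mask = generate_phantom(cfg)
    roi = BinaryMask(np.ones(vol.shape, dtype=bool), vol.spacing)
    return cfg, vol, mask, roi


def random_mask(rng: np.random.Generator, shape, p=0.5,
                spacing=SPACING) -> BinaryMask:
    return BinaryMask(rng.random(shape) < p, spacing)
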