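"""Synthetic PET phantom generation with ground-truth lesion masks.

The generator emulates the data regime of an EARL-style FDG-PET study:
4 mm isotropic voxels, a uniform soft-tissue background around SUV 1, hot
ellipsoidal lesions with tumor-to-background ratios of roughly 3-12, a
PSF-like Gaussian blur of ~7 mm FWHM, and additive Gaussian noise.  Optional
"confounder" lesions (heart/kidney analogs) appear in the image but never in
the ground-truth mask, reproducing the adjacent-high-uptake failure mode.

Ground truth is the *pre-blur* geometric ellipsoid (voxel centres inside the
ellipsoid), so accuracy targets are analytic and masks are invariant to the
blur and noise settings.

Test-retest pairs share lesion geometry up to a small seeded perturbation
(centre shift, uptake jitter) plus an independent noise realization,
emulating two whole-body scans of the same patient on consecutive days.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError
from .volumes import BinaryMask, BoundingBoxSample, SuvVolume, crop_bounding_box

__all__ = [
    "LesionSpec",
    "PhantomConfig",
    "TestRetestPerturbation",
    "TestRetestPair",
    "generate_phantom",
    "generate_test_retest_pair",
    "build_dataset",
    "SIZE_SPLIT_ML",
]

# MATV split between "smaller" and "bigger" lesions (ml); boundary inclusive
# on the smaller side.
SIZE_SPLIT_ML = 12.8

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class LesionSpec:
    """An ellipsoidal uptake region; ``is_tumor=False`` marks a confounder organ."""

    center: tuple[float, float, float]  # mm, (z, y, x)
    radii: tuple[float, float, float]   # mm semi-axes
    peak_suv: float
    is_tumor: bool = True

    def __post_init__(self):
        if any(r <= 0 for r in self.radii):
            raise ConfigError("lesion radii must be positive")

    def volume_ml(self) -> float:
        """Analytic ellipsoid volume 4/3*pi*a*b*c in ml."""
        return 4.0 / 3.0 * np.pi * float(np.prod(self.radii)) / 1000.0


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 1.0
    lesions: tuple[LesionSpec, ...] = ()
    confounders: tuple[LesionSpec, ...] = ()
    psf_fwhm: float = 7.0   # mm
    noise_sd: float = 0.15  # SUV
    seed: int = 0

    def __post_init__(self):
        if self.psf_fwhm < 0 or self.noise_sd < 0:
            raise ConfigError("psf_fwhm and noise_sd must be non-negative")
        extent = np.asarray(self.shape) * np.asarray(self.spacing)
        for les in list(self.lesions) + list(self.confounders):
            if np.any(np.asarray(les.center) < 0) or np.any(np.asarray(les.center) > extent):
                raise ConfigError(f"lesion centre {les.center} outside grid extent {tuple(extent)}")


@dataclass(frozen=True)
class TestRetestPerturbation:
    """Day-to-day perturbation model for a test-retest pair."""

    __test__ = False  # not a pytest class

    shift_sd: float = 1.0        # mm, per-axis Gaussian centre shift
    tbr_jitter_sd: float = 0.05  # sd of log uptake-multiplier (lognormal jitter)


@dataclass
class TestRetestPair:
    __test__ = False  # not a pytest class

    day1: tuple[SuvVolume, BinaryMask]
    day2: tuple[SuvVolume, BinaryMask]
    lesion_ids: list[str]
    config_day1: PhantomConfig
    config_day2: PhantomConfig
    shifts_mm: np.ndarray        # (n_lesions, 3)
    tbr_factors: np.ndarray      # (n_lesions,)
    noise_seeds: tuple[int, int]


def _ellipsoid_mask(cfg: PhantomConfig, lesion: LesionSpec) -> np.ndarray:
    coords = [
        (np.arange(n) + 0.5) * s for n, s in zip(cfg.shape, cfg.spacing)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
    cz, cy, cx = lesion.center
    rz, ry, rx = lesion.radii
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def lesion_mask(cfg: PhantomConfig, index: int) -> BinaryMask:
    """Ground-truth mask of one tumor lesion of the config."""
    return BinaryMask(_ellipsoid_mask(cfg, cfg.lesions[index]), cfg.spacing)


def generate_phantom(cfg: PhantomConfig, noise_seed: int | None = None
                     ) -> tuple[SuvVolume, BinaryMask]:
    """Render a phantom: plateau ellipsoids, PSF blur, additive noise.

    The ideal (pre-blur) image is background plus plateaus at each lesion's
    ``peak_suv``; the returned mask is the union of the *tumor* ellipsoids
    only.  Tumor lesions must be pairwise disjoint.
    """
    tumor_masks = [_ellipsoid_mask(cfg, les) for les in cfg.lesions]
    for i in range(len(tumor_masks)):
        for j in range(i + 1, len(tumor_masks)):
            if np.any(tumor_masks[i] & tumor_masks[j]):
                raise ConfigError(f"tumor lesions {i} and {j} overlap")

    ideal = np.full(cfg.shape, cfg.background_suv, dtype=np.float64)
    for les, m in zip(
        list(cfg.lesions) + list(cfg.confounders),
        tumor_masks + [_ellipsoid_mask(cfg, c) for c in cfg.confounders],
    ):
        ideal[m] = np.maximum(ideal[m], les.peak_suv)

    observed = ideal
    if cfg.psf_fwhm > 0:
        sigma_vox = [cfg.psf_fwhm * _FWHM_TO_SIGMA / s for s in cfg.spacing]
        observed = gaussian_filter(observed, sigma_vox, mode="reflect")
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed if noise_seed is None else noise_seed)
        observed = observed + rng.normal(0.0, cfg.noise_sd, cfg.shape)

    truth = np.zeros(cfg.shape, dtype=bool)
    for m in tumor_masks:
        truth |= m
    return SuvVolume(observed.astype(np.float32), cfg.spacing), BinaryMask(truth, cfg.spacing)


def generate_test_retest_pair(cfg: PhantomConfig,
                              trt: TestRetestPerturbation = TestRetestPerturbation(),
                              seed: int = 0) -> TestRetestPair:
    """Two realizations of the same phantom geometry on "consecutive days".

    Day 2 shifts each lesion centre by a seeded per-axis Gaussian
    (``shift_sd`` mm), multiplies peak uptake by a seeded lognormal factor
    (``exp(N(0, tbr_jitter_sd))``), and draws an independent noise
    realization.  Ground truth is regenerated from the day-2 geometry.
    """
    rng = np.random.default_rng(seed)
    all_lesions = list(cfg.lesions) + list(cfg.confounders)
    shifts = rng.normal(0.0, trt.shift_sd, (len(all_lesions), 3)) if trt.shift_sd > 0 \
        else np.zeros((len(all_lesions), 3))
    factors = np.exp(rng.normal(0.0, trt.tbr_jitter_sd, len(all_lesions))) \
        if trt.tbr_jitter_sd > 0 else np.ones(len(all_lesions))

    def perturb(les: LesionSpec, i: int) -> LesionSpec:
        return replace(
            les,
            center=tuple(float(c + d) for c, d in zip(les.center, shifts[i])),
            peak_suv=float(les.peak_suv * factors[i]),
        )

    n_t = len(cfg.lesions)
    cfg2 = replace(
        cfg,
        lesions=tuple(perturb(l, i) for i, l in enumerate(cfg.lesions)),
        confounders=tuple(perturb(c, n_t + i) for i, c in enumerate(cfg.confounders)),
    )
    seed1 = int(rng.integers(0, 2**31 - 1))
    seed2 = int(rng.integers(0, 2**31 - 1))
    day1 = generate_phantom(cfg, noise_seed=seed1)
    day2 = generate_phantom(cfg2, noise_seed=seed2)
    ids = [f"lesion{i}" for i in range(n_t)]
    return TestRetestPair(day1, day2, ids, cfg, cfg2,
                          shifts[:n_t], factors[:n_t], (seed1, seed2))


def size_class_of(matv_ml: float) -> str:
    """Size label used by the size-gated network: ≤ 12.8 ml is "smaller"."""
    return "smaller" if matv_ml <= SIZE_SPLIT_ML else "bigger"


def build_dataset(cfgs: list[PhantomConfig], seed: int = 0,
                  box=(64, 64, 64)) -> list[BoundingBoxSample]:
    """One bounding-box sample per tumor lesion across a list of phantoms.

    Each lesion is cropped with its own ground-truth mask (other lesions and
    confounders may still appear in the image, as in real scans) and labeled
    "smaller"/"bigger" by the MATV of the ground-truth mask.
    """
    rng = np.random.default_rng(seed)
    samples: list[BoundingBoxSample] = []
    for ci, cfg in enumerate(cfgs):
        vol, _ = generate_phantom(cfg)
        for li in range(len(cfg.lesions)):
            m = lesion_mask(cfg, li)
            s = crop_bounding_box(vol, m, box=box,
                                  seed=int(rng.integers(0, 2**31 - 1)),
                                  lesion_id=f"phantom{ci}_lesion{li}")
            s.size_class = size_class_of(m.volume_ml)
            samples.append(s)
    return samples
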