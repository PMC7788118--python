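"""Image/mask data model, NIfTI I/O, SUV conversion and bounding-box cropping.

Arrays are indexed ``(z, y, x)`` slices-first; ``spacing`` is millimetres per
voxel along the same axes.  The physical position of a voxel centre is
``(index + 0.5) * spacing``: grids are axis-aligned and NIfTI affines other
than diagonal scaling are rejected rather than silently reinterpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, InputError, SizeError

__all__ = [
    "SuvVolume",
    "BinaryMask",
    "BoundingBoxSample",
    "read_volume",
    "read_mask",
    "write_volume",
    "suv_convert",
    "crop_bounding_box",
]


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise InputError(f"spacing must be 3 positive components, got {spacing}")
    return spacing


@dataclass
class SuvVolume:
    """A 3D scalar grid in SUV units (dimensionless g/ml)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or 0 in self.values.shape:
            raise FormatError(f"volume must be 3D and non-empty, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("volume contains non-finite values")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class BinaryMask:
    """A 3D boolean grid aligned to a :class:`SuvVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3 or 0 in self.values.shape:
            raise FormatError(f"mask must be 3D and non-empty, got shape {self.values.shape}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.voxel_volume_ml


@dataclass
class BoundingBoxSample:
    """A cubic crop of volume + mask with the lesion randomly placed.

    ``lesion_offset`` is the (z, y, x) voxel index of the corner of the
    lesion's tight extent inside the box.
    """

    volume: SuvVolume
    mask: BinaryMask
    lesion_offset: tuple[int, int, int]
    lesion_id: str
    size_class: str | None = field(default=None)  # "smaller" / "bigger" when known

    def __post_init__(self):
        if self.volume.shape != self.mask.shape:
            raise InputError("sample volume and mask shapes differ")


def _diag_spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    rot = affine[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off)) > 1e-4 * max(1.0, np.max(np.abs(rot))):
        raise FormatError(
            "only axis-aligned (diagonal-affine) NIfTI images are supported"
        )
    return tuple(float(abs(d)) for d in np.diag(rot))


def read_volume(path) -> SuvVolume:
    """Read a scalar 3D NIfTI image as a :class:`SuvVolume`.

    nibabel yields data in (x, y, z) index order; it is transposed to the
    package's (z, y, x) convention, with spacing reordered to match.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D scalar image, got {data.ndim}D")
    sx, sy, sz = _diag_spacing_from_affine(img.affine)
    return SuvVolume(np.asarray(data, dtype=np.float32).T, (sz, sy, sx))


def read_mask(path) -> BinaryMask:
    """Read a NIfTI label image as a boolean mask (any nonzero voxel is true)."""
    vol = read_volume(path)
    return BinaryMask(vol.values != 0, vol.spacing)


def write_volume(vol: SuvVolume | BinaryMask, path) -> None:
    """Write a volume (32-bit float) or mask (8-bit 0/1) as NIfTI."""
    path = Path(path)
    if not path.parent.exists():
        raise InputError(f"directory does not exist: {path.parent}")
    if isinstance(vol, BinaryMask):
        data = vol.values.astype(np.uint8)
    else:
        data = vol.values.astype(np.float32)
    sz, sy, sx = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(data.T, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def suv_convert(activity: np.ndarray, injected_dose: float, body_weight: float,
                spacing=(4.0, 4.0, 4.0)) -> SuvVolume:
    """Convert an activity-concentration grid to SUV units.

    SUV = activity[kBq/ml] * body weight[g] / injected dose[kBq].  Body-weight
    SUV, no decay correction.
    """
    if injected_dose <= 0 or body_weight <= 0:
        raise InputError("injected dose and body weight must be positive")
    activity = np.asarray(activity, dtype=np.float64)
    if np.any(activity < 0):
        raise InputError("activity must be non-negative")
    return SuvVolume(activity * (body_weight / injected_dose), spacing)


def mask_bounding_extent(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tight (start, stop) voxel extents of the true region along each axis."""
    if not mask.any():
        raise InputError("mask is empty")
    idx = np.nonzero(mask)
    start = np.array([a.min() for a in idx])
    stop = np.array([a.max() + 1 for a in idx])
    return start, stop


def crop_bounding_box(vol: SuvVolume, mask: BinaryMask, box=(64, 64, 64),
                      seed: int = 0, lesion_id: str = "lesion") -> BoundingBoxSample:
    """Crop a box around the lesion with the lesion placed uniformly at random.

    Every true mask voxel is retained; the lesion's corner offset inside the
    box is drawn uniformly over all placements that keep the tight lesion
    extent fully inside.  Regions of the box outside the source grid are
    filled with the volume's robust background level (median of non-lesion
    voxels), avoiding zero-cliff artifacts at box edges.
    """
    if vol.shape != mask.shape:
        raise InputError("volume and mask shapes differ")
    box = np.asarray(box, dtype=int)
    start, stop = mask_bounding_extent(mask.values)
    extent = stop - start
    if np.any(extent > box):
        raise SizeError(
            f"lesion extent {tuple(extent)} exceeds box {tuple(box)}"
        )
    rng = np.random.default_rng(seed)
    offset = np.array([rng.integers(0, b - e + 1) for b, e in zip(box, extent)])
    src_start = start - offset
    src_stop = src_start + box

    background = float(np.median(vol.values[~mask.values])) if (~mask.values).any() else 0.0
    out_vol = np.full(tuple(box), background, dtype=np.float32)
    out_mask = np.zeros(tuple(box), dtype=bool)

    lo = np.maximum(src_start, 0)
    hi = np.minimum(src_stop, vol.shape)
    dst_lo = lo - src_start
    dst_hi = dst_lo + (hi - lo)
    src_sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    dst_sl = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
    out_vol[dst_sl] = vol.values[src_sl]
    out_mask[dst_sl] = mask.values[src_sl]

    return BoundingBoxSample(
        volume=SuvVolume(out_vol, vol.spacing),
        mask=BinaryMask(out_mask, vol.spacing),
        lesion_offset=tuple(int(o) for o in offset),
        lesion_id=lesion_id,
    )
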