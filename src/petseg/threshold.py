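"""Conventional threshold segmentations and majority-vote fusion.

Methods (strict ``>`` thresholds throughout):

* ``suv25`` / ``suv4`` — fixed SUV thresholds at 2.5 and 4.
* ``pct41`` — 41% of the maximum SUV inside the search region.
* ``pct50bg`` — 50% of SUVmax with background correction:
  ``thr = f*(SUVmax - BG) + BG``, BG estimated from a 2-voxel-thick shell
  displaced 2 voxels from the 70%-of-max core.
* ``mv2`` / ``mv3`` — voxel-wise consensus of at least 2 / 3 of the four
  thresholds above.

A connected-component policy (keep the 26-connected component with the
highest SUVmax) suppresses disconnected noise voxels; it is applied inside
each single-lesion search region.  ``majority_vote`` applies it only when
given the SUV volume, so that the raw vote mask remains available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, InputError
from .volumes import BinaryMask, SuvVolume

__all__ = [
    "SegmentationResult",
    "segment_fixed",
    "segment_relative_max",
    "segment_relative_bgcorr",
    "majority_vote",
    "matv",
    "keep_hottest_component",
    "segment",
    "CONVENTIONAL_METHODS",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationResult:
    mask: BinaryMask
    method: str
    lesion_id: str = "lesion"
    missed: bool = False

    @property
    def matv_ml(self) -> float:
        return self.mask.volume_ml


def matv(mask: BinaryMask) -> float:
    """Metabolic active tumor volume in ml: voxel count x voxel volume."""
    return mask.volume_ml


def keep_hottest_component(mask: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Keep the 26-connected component containing the highest value."""
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    if n <= 1:
        return mask
    peaks = ndimage.maximum(values, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(peaks)) + 1)


def _check_roi(vol: SuvVolume, roi: BinaryMask) -> None:
    if vol.shape != roi.shape:
        raise AlignmentError("roi shape differs from volume shape")
    if not roi.values.any():
        raise InputError("empty search region")


def segment_fixed(vol: SuvVolume, roi: BinaryMask, threshold: float,
                  method: str | None = None, lesion_id: str = "lesion",
                  component_policy: bool = True) -> SegmentationResult:
    """Voxels strictly above a fixed SUV threshold inside the search region."""
    _check_roi(vol, roi)
    m = roi.values & (vol.values > threshold)
    if component_policy:
        m = keep_hottest_component(m, vol.values)
    name = method or f"suv{threshold:g}"
    return SegmentationResult(BinaryMask(m, vol.spacing), name, lesion_id,
                              missed=not m.any())


def segment_relative_max(vol: SuvVolume, roi: BinaryMask, fraction: float = 0.41,
                         lesion_id: str = "lesion",
                         component_policy: bool = True) -> SegmentationResult:
    """Voxels strictly above ``fraction`` of the region's maximum SUV."""
    _check_roi(vol, roi)
    thr = fraction * float(vol.values[roi.values].max())
    m = roi.values & (vol.values > thr)
    if component_policy:
        m = keep_hottest_component(m, vol.values)
    return SegmentationResult(BinaryMask(m, vol.spacing),
                              f"pct{round(fraction * 100):d}", lesion_id,
                              missed=not m.any())


def background_corrected_threshold(vol: SuvVolume, roi: BinaryMask,
                                   fraction: float = 0.5,
                                   core_fraction: float = 0.7) -> float:
    """Threshold ``f*(SUVmax - BG) + BG``.

    BG is the mean SUV in a 2-voxel-thick shell dilated 2 voxels away from
    the core of voxels above ``core_fraction`` of SUVmax.  If the shell is
    empty (core fills the grid) the mean over the region border is used.
    """
    suv_max = float(vol.values[roi.values].max())
    core = roi.values & (vol.values > core_fraction * suv_max)
    if not core.any():  # flat region: fall back to max voxel as core
        core = roi.values & (vol.values >= suv_max)
    inner = ndimage.binary_dilation(core, _STRUCT26, iterations=2)
    outer = ndimage.binary_dilation(inner, _STRUCT26, iterations=2)
    shell = outer & ~inner
    if shell.any():
        bg = float(vol.values[shell].mean())
    else:
        warnings.warn("background shell empty; using search-region border mean",
                      stacklevel=2)
        border = roi.values & ~ndimage.binary_erosion(roi.values, _STRUCT26)
        bg = float(vol.values[border].mean())
    return fraction * (suv_max - bg) + bg


def segment_relative_bgcorr(vol: SuvVolume, roi: BinaryMask, fraction: float = 0.5,
                            lesion_id: str = "lesion",
                            component_policy: bool = True) -> SegmentationResult:
    """50%-of-SUVmax segmentation with background correction."""
    _check_roi(vol, roi)
    thr = background_corrected_threshold(vol, roi, fraction)
    m = roi.values & (vol.values > thr)
    if component_policy:
        m = keep_hottest_component(m, vol.values)
    return SegmentationResult(BinaryMask(m, vol.spacing),
                              f"pct{round(fraction * 100):d}bg", lesion_id,
                              missed=not m.any())


def majority_vote(masks: list[BinaryMask], min_votes: int,
                  vol: SuvVolume | None = None,
                  lesion_id: str = "lesion") -> SegmentationResult:
    """Voxel-wise consensus: include a voxel iff at least ``min_votes`` masks do.

    With ``vol`` supplied the hottest-component policy is applied afterwards;
    without it the raw vote mask is returned (raw voting guarantees the
    nesting MV3 ⊆ MV2).
    """
    if not masks:
        raise InputError("no masks to vote over")
    if not 1 <= min_votes <= len(masks):
        raise InputError(f"min_votes must be in [1, {len(masks)}]")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise AlignmentError("vote masks have differing shapes")
    votes = np.zeros(shape, dtype=np.int16)
    for m in masks:
        votes += m.values
    out = votes >= min_votes
    if vol is not None:
        out = keep_hottest_component(out, vol.values)
    return SegmentationResult(BinaryMask(out, masks[0].spacing),
                              f"mv{min_votes}", lesion_id, missed=not out.any())


#: The four standard approaches feeding the majority vote.
CONVENTIONAL_METHODS = ("suv25", "suv4", "pct41", "pct50bg")


def _mv_inputs(vol: SuvVolume, roi: BinaryMask, lesion_id: str) -> list[BinaryMask]:
    return [
        segment_fixed(vol, roi, 2.5, "suv25", lesion_id).mask,
        segment_fixed(vol, roi, 4.0, "suv4", lesion_id).mask,
        segment_relative_max(vol, roi, 0.41, lesion_id).mask,
        segment_relative_bgcorr(vol, roi, 0.5, lesion_id).mask,
    ]


def segment(vol: SuvVolume, roi: BinaryMask, method: str,
            lesion_id: str = "lesion") -> SegmentationResult:
    """Dispatch by method name: suv25, suv4, pct41, pct50bg, mv2, mv3."""
    if method == "suv25":
        return segment_fixed(vol, roi, 2.5, "suv25", lesion_id)
    if method == "suv4":
        return segment_fixed(vol, roi, 4.0, "suv4", lesion_id)
    if method == "pct41":
        return segment_relative_max(vol, roi, 0.41, lesion_id)
    if method == "pct50bg":
        return segment_relative_bgcorr(vol, roi, 0.5, lesion_id)
    if method in ("mv2", "mv3"):
        res = majority_vote(_mv_inputs(vol, roi, lesion_id), int(method[2]),
                            vol=vol, lesion_id=lesion_id)
        return res
    raise InputError(f"unknown method {method!r}")
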