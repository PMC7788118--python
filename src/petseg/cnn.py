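"""Size-gated 3D U-Net segmentation.

Two networks are trained, one for smaller lesions (MATV ≤ 12.8 ml by ground
truth) and one for bigger ones; at inference the appropriate network is
chosen from an initial majority-vote (MV2) volume estimate.  Training
minimizes the negative Dice coefficient with Adam; optional augmentation
applies seeded in-plane rotations, shifts, rescaling, intensity stretching
and Gaussian noise.

The full-scale profile is 3 levels / 8 initial features / kernel 5 /
64-cube boxes / 1000 epochs / batch 25 / lr 0.001.  ``tiny_spec`` /
``tiny_train_config`` give the desk-scale profile (2 levels, 4 features,
kernel 3, 32-cube boxes, ≤ 50 epochs) used by the bundled experiments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import InputError, StateError
from .nn import Adam, UNet3D
from .phantom import SIZE_SPLIT_ML
from .threshold import SegmentationResult, keep_hottest_component, segment
from .volumes import BinaryMask, BoundingBoxSample, SuvVolume

__all__ = [
    "UNetSpec", "TrainConfig", "AugmentParams", "SizeGatedModel",
    "build_unet", "negative_dice_loss", "augment_sample", "train_unet",
    "select_size_model", "cnn_segment", "tiny_spec", "tiny_train_config",
]


@dataclass(frozen=True)
class UNetSpec:
    levels: int = 3
    initial_features: int = 8
    kernel: int = 5
    dropout_rate: float = 0.2
    growth: int = 2

    def __post_init__(self):
        if self.levels < 1 or self.initial_features < 1:
            raise InputError("levels and initial_features must be >= 1")
        if self.kernel % 2 != 1:
            raise InputError("kernel must be odd")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 1000
    batch_size: int = 25
    learning_rate: float = 0.001
    seed: int = 0
    augment: "AugmentParams | None" = None
    augment_per_sample: int = 0  # extra augmented copies per sample per epoch

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise InputError("epochs, batch_size, learning_rate must be positive")


def tiny_spec() -> UNetSpec:
    """Desk-scale network: 2 levels, 4 features, kernel 3."""
    return UNetSpec(levels=2, initial_features=4, kernel=3)


def tiny_train_config(seed: int = 0, epochs: int = 50) -> TrainConfig:
    """Desk-scale training: small batches for more updates per epoch, higher lr."""
    return TrainConfig(epochs=epochs, batch_size=5, learning_rate=0.01, seed=seed)


@dataclass(frozen=True)
class AugmentParams:
    rotation_deg: float = 20.0      # in-plane rotation range ±
    shift_frac: float = 0.2         # shift range as fraction of side length
    rescale_frac: float = 0.25      # isotropic rescale range ±
    intensity_stretch: float = 0.1  # multiplicative intensity range ±
    noise_sd: float = 0.05          # additive Gaussian noise, SUV

    def __post_init__(self):
        if min(self.rotation_deg, self.shift_frac, self.rescale_frac,
               self.intensity_stretch, self.noise_sd) < 0:
            raise InputError("augmentation ranges must be non-negative")


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet3D:
    """Instantiate the network with seeded He-normal weights."""
    return UNet3D(levels=spec.levels, features=spec.initial_features,
                  kernel=spec.kernel, dropout=spec.dropout_rate,
                  growth=spec.growth, seed=seed)


def negative_dice_loss(pred: np.ndarray, target: np.ndarray,
                       smooth: float = 1e-5) -> float:
    """-(2 Σ p·t + s) / (Σ p + Σ t + s); -1 is perfect overlap, 0 disjoint."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise InputError("pred and target shapes differ")
    inter = float((pred * target).sum())
    return -(2.0 * inter + smooth) / (pred.sum() + target.sum() + smooth)


def _dice_loss_grad(p: np.ndarray, t: np.ndarray, smooth: float = 1e-5):
    """Batched soft-Dice loss (mean over samples) and its gradient w.r.t. p."""
    axes = (1, 2, 3, 4)
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes) + smooth
    d = (2.0 * inter + smooth) / denom
    loss = -float(d.mean())
    shape = (-1, 1, 1, 1, 1)
    grad = -(2.0 * t * denom.reshape(shape) -
             (2.0 * inter + smooth).reshape(shape)) / (denom ** 2).reshape(shape)
    return loss, (grad / p.shape[0]).astype(np.float32)


def augment_sample(sample: BoundingBoxSample, params: AugmentParams,
                   seed: int = 0) -> BoundingBoxSample:
    """Seeded augmentation: identical spatial transform for volume and mask.

    The volume is interpolated linearly, the mask nearest-neighbour and
    re-binarized; intensity stretch and noise touch the volume only.  All
    ranges zero -> the sample is returned bit-identical (copied).
    """
    rng = np.random.default_rng(seed)
    vol = sample.volume.values.astype(np.float32)
    mask = sample.mask.values
    spatial = (params.rotation_deg > 0 or params.shift_frac > 0
               or params.rescale_frac > 0)
    if spatial:
        angle = np.deg2rad(rng.uniform(-params.rotation_deg, params.rotation_deg))
        shifts = rng.uniform(-params.shift_frac, params.shift_frac, 2) \
            * np.asarray(vol.shape[1:])
        scale = 1.0 + rng.uniform(-params.rescale_frac, params.rescale_frac)
        c, s = np.cos(angle), np.sin(angle)
        # in-plane (y, x) rotation about the box centre, isotropic rescale,
        # then in-plane shift; matrix maps output coords to input coords
        rot = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]]) / scale
        centre = (np.asarray(vol.shape) - 1) / 2.0
        offset = centre - rot @ (centre + np.array([0.0, *shifts]))
        bgval = float(np.median(vol[~mask])) if (~mask).any() else 0.0
        vol = ndimage.affine_transform(vol, rot, offset=offset, order=1,
                                       mode="constant", cval=bgval)
        mask = ndimage.affine_transform(mask.astype(np.float32), rot,
                                        offset=offset, order=0,
                                        mode="constant", cval=0.0) > 0.5
    if params.intensity_stretch > 0:
        vol = vol * (1.0 + rng.uniform(-params.intensity_stretch,
                                       params.intensity_stretch))
    if params.noise_sd > 0:
        vol = vol + rng.normal(0.0, params.noise_sd, vol.shape).astype(np.float32)
    return BoundingBoxSample(
        volume=SuvVolume(vol.astype(np.float32), sample.volume.spacing),
        mask=BinaryMask(mask, sample.mask.spacing),
        lesion_offset=sample.lesion_offset,
        lesion_id=sample.lesion_id,
        size_class=sample.size_class,
    )


def train_unet(samples: list[BoundingBoxSample], spec: UNetSpec,
               cfg: TrainConfig, val_samples: list[BoundingBoxSample] | None = None
               ) -> tuple[UNet3D, dict]:
    """Train a U-Net on bounding-box samples with the negative Dice loss.

    Returns the trained network and a history dict with per-epoch mean
    training loss (and validation loss when ``val_samples`` is given).
    """
    if len(samples) < 2:
        raise InputError("need at least 2 training samples")
    shapes = {s.volume.shape for s in samples}
    if len(shapes) != 1:
        raise InputError(f"heterogeneous sample shapes: {shapes}")

    rng = np.random.default_rng(cfg.seed)
    net = build_unet(spec, seed=int(rng.integers(0, 2**31 - 1)))
    opt = Adam(net.params(), lr=cfg.learning_rate)

    def stack(ss):
        x = np.stack([s.volume.values for s in ss])[..., None].astype(np.float32)
        y = np.stack([s.mask.values for s in ss])[..., None].astype(np.float32)
        return x, y

    xval, yval = stack(val_samples) if val_samples else (None, None)
    history = {"train_loss": [], "val_loss": []}
    for _epoch in range(cfg.epochs):
        epoch_samples = list(samples)
        if cfg.augment is not None and cfg.augment_per_sample > 0:
            for s in samples:
                for _ in range(cfg.augment_per_sample):
                    epoch_samples.append(
                        augment_sample(s, cfg.augment,
                                       seed=int(rng.integers(0, 2**31 - 1))))
        order = rng.permutation(len(epoch_samples))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = stack([epoch_samples[i] for i in idx])
            p = net.forward(xb, train=True, rng=rng)
            loss, grad = _dice_loss_grad(p, yb)
            net.backward(grad)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if xval is not None:
            pv = net.predict(xval)
            history["val_loss"].append(_dice_loss_grad(pv, yval)[0])
    return net, history


@dataclass
class SizeGatedModel:
    """Pair of trained networks routed by an MV2 initial volume estimate."""

    small: UNet3D | None = None
    large: UNet3D | None = None
    gate_threshold_ml: float = SIZE_SPLIT_ML
    gate_method: str = "mv2"
    binarize_threshold: float = 0.5
    spec: UNetSpec = field(default_factory=UNetSpec)

    def network_for(self, route: str) -> UNet3D:
        net = self.small if route == "small" else self.large
        if net is None:
            other = self.large if route == "small" else self.small
            if other is None:
                raise StateError("size-gated model has no trained networks")
            warnings.warn(f"no {route}-lesion network trained; using the other",
                          stacklevel=2)
            return other
        return net


def select_size_model(vol: SuvVolume, roi: BinaryMask,
                      gate: SizeGatedModel) -> str:
    """Route a lesion to "small" or "large" from an MV volume estimate.

    MATV of the majority-vote segmentation ≤ 12.8 ml selects the
    small-lesion network; an empty vote mask falls back to "small" (an
    invisible-on-threshold lesion is most plausibly small).
    """
    mv = segment(vol, roi, gate.gate_method)
    if mv.mask.voxel_count == 0:
        warnings.warn("empty majority-vote mask; routing to small-lesion network",
                      stacklevel=2)
        return "small"
    return "small" if mv.matv_ml <= gate.gate_threshold_ml else "large"


def cnn_segment(sample: BoundingBoxSample, gate: SizeGatedModel
                ) -> SegmentationResult:
    """Segment a bounding-box sample with the size-gated U-Net."""
    if gate.small is None and gate.large is None:
        raise StateError("size-gated model is untrained")
    roi = BinaryMask(np.ones(sample.volume.shape, dtype=bool),
                     sample.volume.spacing)
    route = select_size_model(sample.volume, roi, gate)
    net = gate.network_for(route)
    p = net.predict(sample.volume.values[None, ..., None])[0, ..., 0]
    m = p > gate.binarize_threshold
    m = keep_hottest_component(m, sample.volume.values)
    return SegmentationResult(BinaryMask(m, sample.volume.spacing), "cnn",
                              sample.lesion_id, missed=not m.any())


# -- persistence ----------------------------------------------------------

def save_gated_model(gate: SizeGatedModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {"gate_threshold_ml": gate.gate_threshold_ml,
            "gate_method": gate.gate_method,
            "binarize_threshold": gate.binarize_threshold,
            "spec": asdict(gate.spec),
            "networks": []}
    for name, net in (("small", gate.small), ("large", gate.large)):
        if net is not None:
            np.savez(d / f"{name}.npz", **net.state_arrays())
            meta["networks"].append(name)
    (d / "model.json").write_text(json.dumps(meta, indent=2))


def load_gated_model(directory) -> SizeGatedModel:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    spec = UNetSpec(**meta["spec"])
    gate = SizeGatedModel(gate_threshold_ml=meta["gate_threshold_ml"],
                          gate_method=meta["gate_method"],
                          binarize_threshold=meta["binarize_threshold"],
                          spec=spec)
    for name in meta["networks"]:
        net = build_unet(spec)
        with np.load(d / f"{name}.npz") as arrs:
            net.load_state_arrays(dict(arrs))
        setattr(gate, name, net)
    return gate
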