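"""Textural-feature voxel-classification segmentation with per-view fusion.

Every voxel is the centre of a 2D scanning window in each of the three
standard views (axial, sagittal, coronal).  First-order statistics and
co-occurrence (GLCM) features of the window feed a per-view random-forest
voxel classifier; the three per-view tumor-probability maps are summed and
voxels with a summed probability strictly above 1.8 form the segmentation.

Windows at the volume border are clamped (edge-replicated).  Co-occurrence
features use a fixed-range quantization (32 levels over SUV [0, 20]) and the
two in-plane unit offsets, symmetrized, so features are comparable across
images.  Feature extraction is fully vectorized; co-occurrence statistics
are accumulated from the adjacent-pair lists directly, without materializing
per-voxel GLCM matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .errors import AlignmentError, InputError, StateError
from .threshold import SegmentationResult, keep_hottest_component
from .volumes import BinaryMask, BoundingBoxSample, SuvVolume

__all__ = [
    "VIEWS", "FEATURE_NAMES", "ProbabilityMap", "ViewClassifierBundle",
    "extract_window_features", "select_features", "train_voxel_classifier",
    "predict_view_probability", "fuse_views", "tf_segment", "train_view_bundle",
]

VIEWS = ("axial", "sagittal", "coronal")
_VIEW_AXIS = {"axial": 0, "coronal": 1, "sagittal": 2}  # (z, y, x) order

FIRST_ORDER = ("mean", "sd", "min", "max", "median", "skewness", "kurtosis",
               "energy", "entropy")
GLCM = ("glcm_contrast", "glcm_correlation", "glcm_homogeneity",
        "glcm_dissimilarity")
FEATURE_NAMES = FIRST_ORDER + GLCM

N_LEVELS = 32
SUV_RANGE = (0.0, 20.0)


def quantize(values: np.ndarray) -> np.ndarray:
    """Fixed-range quantization to N_LEVELS grey levels over SUV_RANGE."""
    lo, hi = SUV_RANGE
    q = np.floor((values - lo) / (hi - lo) * N_LEVELS)
    return np.clip(q, 0, N_LEVELS - 1).astype(np.int16)


@dataclass
class ProbabilityMap:
    """Per-voxel tumor probability; [0,1] per view, [0,3] after summation."""

    values: np.ndarray
    spacing: tuple[float, float, float]


def _window_stack(values: np.ndarray, view: str, window: int):
    """Per-voxel 2D windows: returns (windows, index_grids).

    ``windows`` has shape (n_voxels, window, window) in view-plane order;
    index grids recover (z, y, x) for each row.
    """
    axis = _VIEW_AXIS[view]
    planes = np.moveaxis(values, axis, 0)  # (slices, a, b)
    p = window // 2
    padded = np.pad(planes, ((0, 0), (p, p), (p, p)), mode="edge")
    win = sliding_window_view(padded, (window, window), axis=(1, 2))
    return win, planes.shape


def _first_order(flat: np.ndarray, q: np.ndarray) -> dict[str, np.ndarray]:
    n = flat.shape[1]
    mean = flat.mean(axis=1)
    cent = flat - mean[:, None]
    m2 = (cent ** 2).mean(axis=1)
    sd = np.sqrt(m2)
    ok = m2 > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(ok, (cent ** 3).mean(axis=1) / np.where(ok, m2, 1) ** 1.5, 0.0)
        kurt = np.where(ok, (cent ** 4).mean(axis=1) / np.where(ok, m2, 1) ** 2 - 3.0, 0.0)
    # histogram entropy on the quantized window, vectorized via bincount
    rows = np.repeat(np.arange(flat.shape[0]), n)
    counts = np.bincount(rows * N_LEVELS + q.reshape(-1),
                         minlength=flat.shape[0] * N_LEVELS
                         ).reshape(flat.shape[0], N_LEVELS)
    prob = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(prob > 0, prob * np.log2(np.where(prob > 0, prob, 1)), 0.0
                        ).sum(axis=1)
    return {
        "mean": mean, "sd": sd,
        "min": flat.min(axis=1), "max": flat.max(axis=1),
        "median": np.median(flat, axis=1),
        "skewness": skew, "kurtosis": kurt,
        "energy": (flat ** 2).sum(axis=1) / n,
        "entropy": ent,
    }


def _cooccurrence(qwin: np.ndarray) -> dict[str, np.ndarray]:
    """Symmetric co-occurrence features from in-plane adjacent pairs."""
    n, w, _ = qwin.shape
    i = np.concatenate([qwin[:, :, :-1].reshape(n, -1),
                        qwin[:, :-1, :].reshape(n, -1)], axis=1).astype(np.float32)
    j = np.concatenate([qwin[:, :, 1:].reshape(n, -1),
                        qwin[:, 1:, :].reshape(n, -1)], axis=1).astype(np.float32)
    d = i - j
    contrast = (d ** 2).mean(axis=1)
    dissim = np.abs(d).mean(axis=1)
    homog = (1.0 / (1.0 + d ** 2)).mean(axis=1)
    # symmetric GLCM: both marginals share mean and variance
    mu = 0.5 * (i.mean(axis=1) + j.mean(axis=1))
    var = 0.5 * ((i ** 2).mean(axis=1) + (j ** 2).mean(axis=1)) - mu ** 2
    cov = (i * j).mean(axis=1) - mu ** 2
    ok = var > 1e-12
    corr = np.where(ok, cov / np.where(ok, var, 1.0), 1.0)
    return {"glcm_contrast": contrast, "glcm_correlation": corr,
            "glcm_homogeneity": homog, "glcm_dissimilarity": dissim}


def extract_window_features(vol: SuvVolume, view: str, window: int = 5,
                            voxels: np.ndarray | None = None) -> pd.DataFrame:
    """Window features for each voxel (or a subset) in one view.

    ``voxels`` is an (n, 3) array of (z, y, x) indices; ``None`` means every
    voxel.  Returns a DataFrame with one row per voxel: z/y/x indices, the
    view tag and the feature columns of :data:`FEATURE_NAMES`.
    """
    if window % 2 != 1 or window < 3:
        raise InputError("window must be an odd integer >= 3")
    if view not in VIEWS:
        raise InputError(f"view must be one of {VIEWS}")
    axis = _VIEW_AXIS[view]
    win, view_shape = _window_stack(vol.values.astype(np.float32), view, window)

    if voxels is None:
        flat = win.reshape(-1, window * window)
        zyx = np.stack(np.meshgrid(*[np.arange(s) for s in vol.shape],
                                   indexing="ij"), axis=-1)
        zyx = np.moveaxis(zyx, axis, 0).reshape(-1, 3)
    else:
        voxels = np.asarray(voxels, dtype=int)
        if voxels.ndim != 2 or voxels.shape[1] != 3:
            raise InputError("voxels must be an (n, 3) index array")
        if np.any(voxels < 0) or np.any(voxels >= np.asarray(vol.shape)):
            raise InputError("voxel indices outside the volume")
        order = [axis] + [a for a in range(3) if a != axis]
        sel = voxels[:, order]
        flat = win[sel[:, 0], sel[:, 1], sel[:, 2]].reshape(-1, window * window)
        zyx = voxels

    flat = np.ascontiguousarray(flat, dtype=np.float32)
    q = quantize(flat)
    feats = _first_order(flat, q)
    feats.update(_cooccurrence(q.reshape(-1, window, window)))
    df = pd.DataFrame({k: feats[k] for k in FEATURE_NAMES})
    df.insert(0, "x", zyx[:, 2])
    df.insert(0, "y", zyx[:, 1])
    df.insert(0, "z", zyx[:, 0])
    df["view"] = view
    return df


def _check_table(table: pd.DataFrame, features) -> tuple[np.ndarray, np.ndarray]:
    if "label" not in table.columns:
        raise InputError("feature table has no 'label' column")
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise InputError("both classes must be present")
    return table[list(features)].to_numpy(), y


def select_features(table: pd.DataFrame, k: int, seed: int = 0,
                    features=FEATURE_NAMES, n_estimators: int = 100) -> list[str]:
    """Top-k features by mean impurity importance of a seeded random forest."""
    if k > len(features):
        raise InputError(f"k={k} exceeds {len(features)} available features")
    X, y = _check_table(table, features)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                n_jobs=1)
    rf.fit(X, y)
    order = np.argsort(rf.feature_importances_)[::-1][:k]
    return [features[i] for i in order]


def balance_table(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """All tumor rows plus an equal-size seeded sample of background rows."""
    tumor = table[table["label"] == 1]
    bg = table[table["label"] == 0]
    if len(tumor) == 0 or len(bg) == 0:
        raise InputError("both classes must be present")
    n = min(len(tumor), len(bg))
    bg = bg.sample(n=n, random_state=seed) if len(bg) > n else bg
    return pd.concat([tumor, bg], ignore_index=True)


def train_voxel_classifier(table: pd.DataFrame, selected, seed: int = 0,
                           n_estimators: int = 60, max_depth: int | None = 14
                           ) -> RandomForestClassifier:
    """Seeded random forest on the class-balanced table."""
    balanced = balance_table(table, seed=seed)
    X, y = _check_table(balanced, selected)
    rf = RandomForestClassifier(n_estimators=n_estimators, max_depth=max_depth,
                                random_state=seed, n_jobs=1)
    rf.fit(X, y)
    rf.petseg_features_ = list(selected)
    return rf


def predict_view_probability(vol: SuvVolume, classifier, view: str,
                             window: int = 5) -> ProbabilityMap:
    """Tumor probability for every voxel of the volume in one view."""
    features = getattr(classifier, "petseg_features_", None)
    if features is None:
        raise StateError("classifier was not trained by train_voxel_classifier")
    df = extract_window_features(vol, view, window)
    prob = classifier.predict_proba(df[features].to_numpy())[:, 1]
    out = np.zeros(vol.shape)  # float64: keeps the strict 1.8 sum threshold exact
    out[df["z"].to_numpy(), df["y"].to_numpy(), df["x"].to_numpy()] = prob
    return ProbabilityMap(out, vol.spacing)


def fuse_views(p_axial: ProbabilityMap, p_sagittal: ProbabilityMap,
               p_coronal: ProbabilityMap, threshold: float = 1.8,
               vol: SuvVolume | None = None, component_policy: bool = True,
               lesion_id: str = "lesion") -> SegmentationResult:
    """Sum the three view probabilities; keep voxels strictly above 1.8."""
    maps = (p_axial, p_sagittal, p_coronal)
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise AlignmentError(f"probability map shapes differ: {shapes}")
    total = p_axial.values + p_sagittal.values + p_coronal.values
    m = total > threshold
    if component_policy and m.any():
        intensity = vol.values if vol is not None else total
        m = keep_hottest_component(m, intensity)
    return SegmentationResult(BinaryMask(m, p_axial.spacing), "tf", lesion_id,
                              missed=not m.any())


@dataclass
class ViewClassifierBundle:
    """Three trained per-view voxel classifiers plus their feature schema."""

    classifiers: dict = field(default_factory=dict)   # view -> RandomForest
    selected: dict = field(default_factory=dict)      # view -> feature names
    window: int = 5
    fusion_threshold: float = 1.8
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.classifiers) - set(VIEWS)
        if unknown:
            raise InputError(f"unknown views: {unknown}")

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for view, clf in self.classifiers.items():
            joblib.dump(clf, d / f"{view}.joblib")
        (d / "bundle.json").write_text(json.dumps({
            "selected": self.selected, "window": self.window,
            "fusion_threshold": self.fusion_threshold, "seed": self.seed,
            "views": list(self.classifiers),
        }, indent=2))

    @classmethod
    def load(cls, directory) -> "ViewClassifierBundle":
        d = Path(directory)
        meta = json.loads((d / "bundle.json").read_text())
        clfs = {v: joblib.load(d / f"{v}.joblib") for v in meta["views"]}
        return cls(classifiers=clfs, selected=meta["selected"],
                   window=meta["window"],
                   fusion_threshold=meta["fusion_threshold"], seed=meta["seed"])


def _sample_training_voxels(sample: BoundingBoxSample, rng
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Tumor voxels plus an equal-count seeded background sample.

    Half of the background sample is drawn from a 3-voxel shell around the
    lesion, half uniformly from the remaining background: the blurred
    transition zone is where voxel classification is actually decided, and
    uniform sampling would leave it almost unrepresented.
    """
    tumor = np.argwhere(sample.mask.values)
    dilated = ndimage.binary_dilation(sample.mask.values,
                                      np.ones((3, 3, 3), bool), iterations=3)
    shell = np.argwhere(dilated & ~sample.mask.values)
    far = np.argwhere(~dilated)
    n = len(tumor)
    n_shell = min(n // 2, len(shell))
    picks = [shell[rng.choice(len(shell), size=n_shell, replace=False)]]
    n_far = min(n - n_shell, len(far))
    if n_far:
        picks.append(far[rng.choice(len(far), size=n_far, replace=False)])
    return tumor, np.concatenate(picks)


def train_view_bundle(samples: list[BoundingBoxSample], window: int = 5,
                      n_features: int = 8, seed: int = 0,
                      n_estimators: int = 60) -> ViewClassifierBundle:
    """Train the full per-view bundle on bounding-box samples."""
    if not samples:
        raise InputError("no training samples")
    rng = np.random.default_rng(seed)
    voxel_sets = [_sample_training_voxels(s, rng) for s in samples]
    bundle = ViewClassifierBundle(window=window, seed=seed)
    for view in VIEWS:
        tables = []
        for s, (tumor, bg) in zip(samples, voxel_sets):
            for voxels, label in ((tumor, 1), (bg, 0)):
                df = extract_window_features(s.volume, view, window, voxels)
                df["label"] = label
                tables.append(df)
        table = pd.concat(tables, ignore_index=True)
        sel = select_features(table, n_features,
                              seed=int(rng.integers(0, 2**31 - 1)))
        clf = train_voxel_classifier(table, sel,
                                     seed=int(rng.integers(0, 2**31 - 1)),
                                     n_estimators=n_estimators)
        bundle.classifiers[view] = clf
        bundle.selected[view] = sel
    return bundle


def tf_segment(sample: BoundingBoxSample, bundle: ViewClassifierBundle
               ) -> SegmentationResult:
    """Per-view prediction + probability-sum fusion for one sample."""
    if set(bundle.classifiers) != set(VIEWS):
        raise StateError("bundle must hold a classifier for every view")
    maps = {v: predict_view_probability(sample.volume, bundle.classifiers[v],
                                        v, bundle.window) for v in VIEWS}
    return fuse_views(maps["axial"], maps["sagittal"], maps["coronal"],
                      threshold=bundle.fusion_threshold, vol=sample.volume,
                      lesion_id=sample.lesion_id)
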