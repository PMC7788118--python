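"""End-to-end orchestration: cross-validation and test-retest studies.

``run_crossvalidation`` reproduces the fivefold 70/10/20 protocol: per fold
an independent seeded draw assigns whole phantoms (never individual lesions)
to train/validation/test, the requested method is trained on the training
portion and scored on the held-out portion with JC, volume ratio and
barycenter distance, pooled over folds and split by lesion size class.

``run_repeatability_study`` segments every lesion of every test-retest pair
on both days with every requested method, applies the missed-lesion discard
rule, and reports TRT%, RC and ICC per method plus the Friedman/Nemenyi/
Benjamini-Hochberg comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnn import SizeGatedModel, cnn_segment, tiny_spec, tiny_train_config, train_unet
from .errors import InputError, StateError
from .features import tf_segment, train_view_bundle
from .metrics import (MethodComparison, RepeatabilityReport, accuracy_record,
                      apply_discard_rule, compare_methods, icc_agreement,
                      repeatability_coefficient, trt_percent)
from .phantom import TestRetestPair, lesion_mask
from .threshold import SegmentationResult, segment, segment_fixed
from .volumes import BinaryMask, BoundingBoxSample, SuvVolume, crop_bounding_box

__all__ = [
    "SplitPlan", "make_split_plan", "run_crossvalidation",
    "run_repeatability_study", "make_reference_seed_mask", "CrossValReport",
]

THRESHOLD_METHODS = ("suv25", "suv4", "pct41", "pct50bg", "mv2", "mv3")


@dataclass
class SplitPlan:
    """Per-fold train/val/test assignments of group (phantom) indices."""

    folds: list[dict]
    proportions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0


def make_split_plan(groups: list, n_folds: int = 5,
                    proportions=(0.7, 0.1, 0.2), seed: int = 0,
                    labels: list | None = None,
                    rotating: bool = False) -> SplitPlan:
    """Seeded independent 70/10/20 draws per fold, stratified by label.

    ``rotating=True`` gives classical rotating cross-validation instead
    (each group tested exactly once; validation drawn from the remainder).
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise InputError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    n = len(groups)
    labels = list(labels) if labels is not None else [0] * n
    folds = []
    if rotating:
        order = rng.permutation(n)
        chunks = np.array_split(order, n_folds)
        for f in range(n_folds):
            test = sorted(chunks[f].tolist())
            rest = [i for i in order if i not in test]
            n_val = max(1, round(proportions[1] * n))
            folds.append({"train": sorted(rest[n_val:]), "val": sorted(rest[:n_val]),
                          "test": test})
    else:
        for _f in range(n_folds):
            train, val, test = [], [], []
            for lab in sorted(set(labels)):
                idx = [i for i in range(n) if labels[i] == lab]
                idx = rng.permutation(idx).tolist()
                m = len(idx)
                n_va = round(proportions[1] * m) if m > 2 else 0
                n_tr = max(1, round(proportions[0] * m))
                n_tr = min(n_tr, m - n_va - 1) if m > 1 else n_tr  # keep >= 1 test
                train += idx[:n_tr]
                val += idx[n_tr:n_tr + n_va]
                test += idx[n_tr + n_va:]
            if not test:  # guarantee a non-empty test portion
                test.append(train.pop())
            folds.append({"train": sorted(train), "val": sorted(val),
                          "test": sorted(test)})
    return SplitPlan(folds, tuple(proportions), seed)


@dataclass
class CrossValReport:
    records: pd.DataFrame          # one row per (fold, lesion): jc, ratio, barycenter
    summary: pd.DataFrame          # pooled quartiles, overall and per size class
    plan: SplitPlan
    method: str = ""


def _group_of(sample: BoundingBoxSample) -> str:
    return sample.lesion_id.split("_")[0]


def _train_tf(train_samples, seed, **kw):
    return train_view_bundle(train_samples, seed=seed, **kw)


def _train_cnn(train_samples, seed, spec=None, cfg=None):
    spec = spec or tiny_spec()
    cfg = cfg or tiny_train_config(seed=seed)
    gate = SizeGatedModel(spec=spec)
    for size, attr in (("smaller", "small"), ("bigger", "large")):
        subset = [s for s in train_samples if s.size_class == size]
        if len(subset) >= 2:
            net, _hist = train_unet(subset, spec, cfg)
            setattr(gate, attr, net)
    if gate.small is None and gate.large is None:
        net, _hist = train_unet(train_samples, spec, cfg)
        gate.small = net
    return gate


def _segment_with(method: str, sample: BoundingBoxSample, model) -> SegmentationResult:
    if method == "tf":
        return tf_segment(sample, model)
    if method == "cnn":
        return cnn_segment(sample, model)
    roi = BinaryMask(np.ones(sample.volume.shape, dtype=bool),
                     sample.volume.spacing)
    return segment(sample.volume, roi, method, lesion_id=sample.lesion_id)


def _quartile_row(df: pd.DataFrame, label: str) -> dict:
    q = df["jc"].quantile([0.25, 0.5, 0.75])
    return {"subset": label, "n": len(df),
            "jc_median": q.loc[0.5], "jc_q25": q.loc[0.25], "jc_q75": q.loc[0.75],
            "volume_ratio_median": df["volume_ratio"].median(),
            "barycenter_median_mm": df["barycenter_mm"].median()}


def run_crossvalidation(samples: list[BoundingBoxSample], method: str = "tf",
                        config: dict | None = None, seed: int = 0,
                        n_folds: int = 5) -> CrossValReport:
    """Fivefold 70/10/20 cross-validation of the TF or CNN method."""
    if method not in ("tf", "cnn"):
        raise InputError("cross-validation method must be 'tf' or 'cnn'")
    if len(samples) < 10:
        raise InputError(
            "need at least 10 samples for a 70/10/20 split; generate more phantoms")
    config = config or {}
    groups = sorted({_group_of(s) for s in samples})
    group_label = {g: max(s.size_class == "bigger" for s in samples
                          if _group_of(s) == g) for g in groups}
    plan = make_split_plan(groups, n_folds=n_folds, seed=seed,
                           labels=[group_label[g] for g in groups],
                           rotating=config.get("rotating", False))
    rng = np.random.default_rng(seed)
    rows = []
    for fold, assign in enumerate(plan.folds):
        train_g = {groups[i] for i in assign["train"]}
        test_g = {groups[i] for i in assign["test"]}
        train_s = [s for s in samples if _group_of(s) in train_g]
        test_s = [s for s in samples if _group_of(s) in test_g]
        fold_seed = int(rng.integers(0, 2**31 - 1))
        if method == "tf":
            model = _train_tf(train_s, fold_seed,
                              **{k: v for k, v in config.items()
                                 if k in ("window", "n_features", "n_estimators")})
        else:
            model = _train_cnn(train_s, fold_seed, spec=config.get("spec"),
                               cfg=config.get("train_config"))
        for s in test_s:
            res = _segment_with(method, s, model)
            rec = accuracy_record(res, s.mask)
            rows.append({"fold": fold, "lesion_id": s.lesion_id,
                         "size_class": s.size_class, "jc": rec.jc,
                         "volume_ratio": rec.volume_ratio,
                         "barycenter_mm": rec.barycenter_mm,
                         "missed": res.missed})
    records = pd.DataFrame(rows)
    parts = [_quartile_row(records, "all")]
    for sc in ("smaller", "bigger"):
        sub = records[records["size_class"] == sc]
        if len(sub):
            parts.append(_quartile_row(sub, sc))
    return CrossValReport(records, pd.DataFrame(parts), plan, method)


def run_repeatability_study(pairs: list[TestRetestPair], methods,
                            models: dict | None = None, seed: int = 0,
                            box=(32, 32, 32)) -> RepeatabilityReport:
    """Segment all lesions of all pairs on both days; score repeatability."""
    if len(pairs) < 3:
        raise InputError("need at least 3 test-retest pairs")
    models = models or {}
    for m in methods:
        if m in ("tf", "cnn") and m not in models:
            raise StateError(f"method {m!r} requested without a trained model")
        if m not in ("tf", "cnn") and m not in THRESHOLD_METHODS:
            raise InputError(f"unknown method {m!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for pi, pair in enumerate(pairs):
        for li in range(len(pair.config_day1.lesions)):
            lid = f"pair{pi}_lesion{li}"
            matvs = {}
            for day, (vol, _), cfg in (
                (1, pair.day1, pair.config_day1),
                (2, pair.day2, pair.config_day2),
            ):
                truth = lesion_mask(cfg, li)
                sample = crop_bounding_box(vol, truth, box=box,
                                           seed=int(rng.integers(0, 2**31 - 1)),
                                           lesion_id=lid)
                for m in methods:
                    res = _segment_with(m, sample, models.get(m))
                    matvs[(m, day)] = res.matv_ml
            for m in methods:
                rows.append({"lesion_id": lid, "method": m,
                             "day1_ml": matvs[(m, 1)], "day2_ml": matvs[(m, 2)]})
    table = pd.DataFrame(rows)
    kept, discarded = apply_discard_rule(table)
    if kept.empty:
        raise InputError("every lesion was missed by some method")
    kept = kept.copy()
    kept["trt_percent"] = [trt_percent(r.day1_ml, r.day2_ml)
                           for r in kept.itertuples()]
    summary_rows = []
    for m in methods:
        sub = kept[kept["method"] == m]
        trts = sub["trt_percent"].to_numpy()
        row = {"method": m, "n_lesions": len(sub),
               "mean_trt": float(np.mean(trts)), "sd_trt": float(np.std(trts, ddof=1))
               if len(trts) > 1 else np.nan}
        row["rc"] = repeatability_coefficient(trts) if len(trts) > 1 else np.nan
        try:
            row["icc"] = icc_agreement(sub["day1_ml"], sub["day2_ml"])
        except InputError:
            row["icc"] = np.nan
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    comparison: MethodComparison | None = None
    matrix = kept.pivot(index="lesion_id", columns="method", values="trt_percent")
    if matrix.shape[0] >= 3 and matrix.shape[1] >= 3 and matrix.std().sum() > 0:
        try:
            comparison = compare_methods(matrix)
        except ValueError:  # e.g. all-identical columns at tiny n
            comparison = None
    return RepeatabilityReport(kept, summary, discarded, comparison)


def make_reference_seed_mask(vol: SuvVolume, roi: BinaryMask) -> BinaryMask:
    """The SUV 2.5 seed used to initialize expert reference segmentations."""
    return segment_fixed(vol, roi, 2.5, method="suv25").mask
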