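"""Accuracy and test-retest repeatability metrics with comparison statistics.

Accuracy of a segmentation against a reference mask is summarized by the
Jaccard coefficient JC = |A∩B|/|A∪B|, the volume ratio MATV_seg/MATV_ref and
the barycenter (centroid) distance in mm.

Repeatability across two scans of the same geometry uses

    TRT% = |v1 - v2| / ((v1 + v2)/2) * 100
    RC   = 1.96 x SD(TRT%)
    ICC  = ICC(A,1): two-way model, single measures, absolute agreement

and method comparison uses a Friedman test on within-lesion ranks, pairwise
Nemenyi post-hoc tests, and Benjamini-Hochberg correction at alpha = 0.01.
A lesion missed (empty mask) by any method on either day is discarded from
every method's analysis so all methods score the same lesion set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, InputError
from .threshold import SegmentationResult
from .volumes import BinaryMask

__all__ = [
    "AccuracyRecord",
    "MethodComparison",
    "RepeatabilityReport",
    "jaccard",
    "dice",
    "volume_ratio",
    "barycenter_distance",
    "trt_percent",
    "repeatability_coefficient",
    "icc_agreement",
    "compare_methods",
    "apply_discard_rule",
    "accuracy_record",
]


def _check_pair(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise AlignmentError("masks have different shapes")


def jaccard(a: BinaryMask, b: BinaryMask) -> float:
    """|A∩B| / |A∪B|.  Two empty masks agree on absence -> 1.0."""
    _check_pair(a, b)
    union = int(np.logical_or(a.values, b.values).sum())
    if union == 0:
        return 1.0
    inter = int(np.logical_and(a.values, b.values).sum())
    return inter / union


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """2|A∩B| / (|A| + |B|); 1.0 when both masks are empty."""
    _check_pair(a, b)
    denom = a.voxel_count + b.voxel_count
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a.values, b.values).sum()) / denom


def volume_ratio(seg: SegmentationResult, ref: SegmentationResult) -> float:
    """MATV_seg / MATV_ref; >1 is over-estimation, <1 under-estimation."""
    if ref.matv_ml <= 0:
        raise InputError("reference MATV is zero; volume ratio undefined")
    return seg.matv_ml / ref.matv_ml


def _centroid_mm(mask: BinaryMask) -> np.ndarray:
    idx = np.argwhere(mask.values)
    return (idx.mean(axis=0) + 0.5) * np.asarray(mask.spacing)


def barycenter_distance(a: BinaryMask, b: BinaryMask,
                        weights: np.ndarray | None = None) -> float:
    """Euclidean distance (mm) between mask centroids.

    Unweighted voxel centroids by default; pass an intensity grid in
    ``weights`` for SUV-weighted barycenters.
    """
    _check_pair(a, b)
    if not a.values.any() or not b.values.any():
        raise InputError("barycenter distance undefined for an empty mask")
    if weights is None:
        ca, cb = _centroid_mm(a), _centroid_mm(b)
    else:
        sp = np.asarray(a.spacing)
        def wc(m):
            idx = np.argwhere(m.values)
            w = weights[m.values].astype(float)
            return ((idx * w[:, None]).sum(axis=0) / w.sum() + 0.5) * sp
        ca, cb = wc(a), wc(b)
    return float(np.linalg.norm(ca - cb))


@dataclass
class AccuracyRecord:
    lesion_id: str
    method: str
    jc: float
    volume_ratio: float | None
    barycenter_mm: float | None


def accuracy_record(seg: SegmentationResult, ref: BinaryMask,
                    ref_method: str = "reference") -> AccuracyRecord:
    """Score one segmentation against a reference mask."""
    ref_res = SegmentationResult(ref, ref_method, seg.lesion_id)
    vr = volume_ratio(seg, ref_res) if ref.voxel_count > 0 else None
    bc = (barycenter_distance(seg.mask, ref)
          if seg.mask.voxel_count > 0 and ref.voxel_count > 0 else None)
    return AccuracyRecord(seg.lesion_id, seg.method, jaccard(seg.mask, ref), vr, bc)


def trt_percent(vol_day1: float, vol_day2: float) -> float:
    """|v1 - v2| / ((v1 + v2)/2) * 100; symmetric; range [0, 200]."""
    if vol_day1 < 0 or vol_day2 < 0:
        raise InputError("volumes must be non-negative")
    if vol_day1 + vol_day2 == 0:
        raise InputError("TRT%% undefined when both volumes are zero (missed lesion)")
    return abs(vol_day1 - vol_day2) / ((vol_day1 + vol_day2) / 2.0) * 100.0


def repeatability_coefficient(trts) -> float:
    """RC = 1.96 x sample standard deviation of the TRT%% values."""
    trts = np.asarray(trts, dtype=float)
    if trts.size < 2:
        raise InputError("RC requires at least two TRT% values")
    return 1.96 * float(np.std(trts, ddof=1))


def icc_agreement(day1, day2) -> float:
    """ICC(A,1): two-way model, single measures, absolute agreement.

    From the two-way ANOVA decomposition with n subjects and k = 2 raters:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

    where MSR, MSC, MSE are the mean squares for rows (subjects), columns
    (days) and residual error.
    """
    y = np.column_stack([np.asarray(day1, float), np.asarray(day2, float)])
    n, k = y.shape
    if n < 3:
        raise InputError("ICC requires at least 3 subjects")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((y - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if abs(denom) < 1e-300:
        raise InputError("ICC undefined: zero total variance")
    return float((msr - mse) / denom)


@dataclass
class MethodComparison:
    friedman_statistic: float
    friedman_p: float
    nemenyi_p: pd.DataFrame              # methods x methods
    significant: pd.DataFrame | None     # BH-adjusted flags at alpha
    alpha: float = 0.01
    mean_ranks: pd.Series | None = None


def _nemenyi_p_matrix(ranks: np.ndarray, methods, exact: bool) -> pd.DataFrame:
    n, k = ranks.shape
    mean_ranks = ranks.mean(axis=0)
    p = np.ones((k, k))
    if exact:
        # Null distribution by exhaustive within-row rank permutations
        # (k!)^n cases; tiny n only.
        perms = list(itertools.permutations(range(k)))
        diffs = {pair: [] for pair in itertools.combinations(range(k), 2)}
        for assignment in itertools.product(perms, repeat=n):
            r = np.array([[ranks[i, assignment[i][j]] for j in range(k)]
                          for i in range(n)])
            mr = r.mean(axis=0)
            for (i, j) in diffs:
                diffs[(i, j)].append(abs(mr[i] - mr[j]))
        for (i, j), null in diffs.items():
            obs = abs(mean_ranks[i] - mean_ranks[j])
            null = np.asarray(null)
            p[i, j] = p[j, i] = float(np.mean(null >= obs - 1e-12))
    else:
        se = np.sqrt(k * (k + 1) / (12.0 * n))
        for i in range(k):
            for j in range(i + 1, k):
                q = abs(mean_ranks[i] - mean_ranks[j]) / se
                pv = float(stats.studentized_range.sf(q, k, np.inf))
                p[i, j] = p[j, i] = min(1.0, pv)
    return pd.DataFrame(p, index=methods, columns=methods)


def compare_methods(trt_matrix: pd.DataFrame, alpha: float = 0.01,
                    exact_nemenyi: bool = False) -> MethodComparison:
    """Friedman test + Nemenyi post-hoc + Benjamini-Hochberg flags.

    ``trt_matrix``: one row per lesion, one column per method, no missing
    cells (apply the discard rule first).
    """
    if trt_matrix.isna().any().any():
        raise InputError("missing cells; apply the discard rule first")
    n, k = trt_matrix.shape
    if n < 3 or k < 2:
        raise InputError("need >= 3 lesions and >= 2 methods")
    values = trt_matrix.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, values)  # average ranks on ties
    stat, pval = stats.friedmanchisquare(*[values[:, j] for j in range(k)])
    nem = _nemenyi_p_matrix(ranks, trt_matrix.columns, exact_nemenyi)

    iu = np.triu_indices(k, 1)
    raw = nem.to_numpy()[iu]
    reject, _, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    flags = np.zeros((k, k), dtype=bool)
    flags[iu] = reject
    flags |= flags.T
    sig = pd.DataFrame(flags, index=trt_matrix.columns, columns=trt_matrix.columns)
    return MethodComparison(float(stat), float(pval), nem, sig, alpha,
                            pd.Series(ranks.mean(axis=0), index=trt_matrix.columns))


def apply_discard_rule(matv_table: pd.DataFrame
                       ) -> tuple[pd.DataFrame, list]:
    """Drop every lesion missed by any method on either day.

    ``matv_table`` columns: lesion_id, method, day1_ml, day2_ml.  Returns the
    filtered table and the discarded lesion ids.
    """
    required = {"lesion_id", "method", "day1_ml", "day2_ml"}
    if not required.issubset(matv_table.columns):
        raise InputError(f"table must have columns {sorted(required)}")
    missed = (matv_table["day1_ml"] <= 0) | (matv_table["day2_ml"] <= 0)
    discarded = sorted(matv_table.loc[missed, "lesion_id"].unique().tolist())
    kept = matv_table[~matv_table["lesion_id"].isin(discarded)].reset_index(drop=True)
    return kept, discarded


@dataclass
class RepeatabilityReport:
    """Per-lesion TRT% plus per-method aggregates for a test-retest study."""

    trt_table: pd.DataFrame                  # lesion_id, method, day1_ml, day2_ml, trt_percent
    method_summary: pd.DataFrame             # method, mean/sd TRT%, RC, ICC
    discarded: list = field(default_factory=list)
    comparison: MethodComparison | None = None

    def trt_matrix(self) -> pd.DataFrame:
        return self.trt_table.pivot(index="lesion_id", columns="method",
                                    values="trt_percent")
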