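"""Segmentation and classification metrics.

Overlap metrics (DSC), boundary metrics (ASSD), vessel hit/error rates against
sparse annotations, one-vs-rest F1/AUC per class, row-normalized confusion
matrices, per-patient aggregation, and the percentile-based qualitative
ranking of example images. Percentages are on a 0-100 scale throughout,
matching how the numbers are usually reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.stats import rankdata

HEALTHY, TUMOR, VESSEL, DURA = 1, 2, 3, 4


@dataclass
class VesselEval:
    vhr: float
    ver: float
    counts: dict = field(default_factory=dict)


@dataclass
class ClassMetrics:
    f1: dict = field(default_factory=dict)    # class -> F1 in [0, 100]
    auc: dict = field(default_factory=dict)   # class -> AUC in [0, 100]
    counts: dict = field(default_factory=dict)  # class -> (tp, fp, tn, fn)


# ------------------------------------------------------------------ overlap
def dsc(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice similarity coefficient in percent; two empty masks score 100."""
    a = np.asarray(pred_mask, bool)
    b = np.asarray(ref_mask, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 100.0
    return 100.0 * 2.0 * np.logical_and(a, b).sum() / denom


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with a 4-neighbour outside the mask (outer boundary)."""
    er = ndi.binary_erosion(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool), border_value=0)
    return mask & ~er


def assd(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Average symmetric surface distance in pixels (Euclidean)."""
    a = np.asarray(pred_mask, bool)
    b = np.asarray(ref_mask, bool)
    if not a.any() or not b.any():
        raise ValueError("ASSD is undefined for empty masks")
    ba, bb = _boundary(a), _boundary(b)
    dist_to_b = ndi.distance_transform_edt(~bb)
    dist_to_a = ndi.distance_transform_edt(~ba)
    return 0.5 * (dist_to_b[ba].mean() + dist_to_a[bb].mean())


# ----------------------------------------------------------------- vessels
def vhr(vessel_mask: np.ndarray, gt: np.ndarray) -> float:
    """Vessel hit rate: percent of vessel-labeled pixels inside the mask."""
    av = gt == VESSEL
    n_av = int(av.sum())
    if n_av == 0:
        raise ValueError("ground truth has no vessel-labeled pixels")
    hits = int(np.logical_and(vessel_mask, av).sum())
    return 100.0 * hits / n_av


def ver(vessel_mask: np.ndarray, gt: np.ndarray) -> float:
    """Vessel error rate: percent of the mask on healthy/tumor-labeled pixels."""
    mv = np.asarray(vessel_mask, bool)
    n_mv = int(mv.sum())
    if n_mv == 0:
        warnings.warn("empty vessel mask; VER set to 0")
        return 0.0
    aht = (gt == HEALTHY) | (gt == TUMOR)
    errors = int(np.logical_and(mv, aht).sum())
    return 100.0 * errors / n_mv


def vessel_eval(vessel_mask: np.ndarray, gt: np.ndarray) -> VesselEval:
    mv = np.asarray(vessel_mask, bool)
    av = gt == VESSEL
    aht = (gt == HEALTHY) | (gt == TUMOR)
    return VesselEval(
        vhr=vhr(vessel_mask, gt), ver=ver(vessel_mask, gt),
        counts={"AV": int(av.sum()), "MV": int(mv.sum()),
                "hits": int((mv & av).sum()), "errors": int((mv & aht).sum())})


# ------------------------------------------------------------ classification
def f1_per_class(class_map: np.ndarray, gt: np.ndarray,
                 classes=(1, 2, 3, 4)) -> ClassMetrics:
    """One-vs-rest F1 = 2TP / (2TP + FP + FN) per class, on labeled pixels."""
    labeled = gt > 0
    cm = ClassMetrics()
    y, p = gt[labeled], np.asarray(class_map)[labeled]
    for cls in classes:
        if not np.any(y == cls):
            continue  # undefined; excluded from means
        tp = int(np.sum((p == cls) & (y == cls)))
        fp = int(np.sum((p == cls) & (y != cls)))
        fn = int(np.sum((p != cls) & (y == cls)))
        tn = int(np.sum((p != cls) & (y != cls)))
        cm.counts[cls] = (tp, fp, tn, fn)
        cm.f1[cls] = 100.0 * 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) \
            else 0.0
    return cm


def auc_per_class(prob_map: np.ndarray, gt: np.ndarray,
                  classes=(1, 2, 3, 4)) -> ClassMetrics:
    """One-vs-rest ROC AUC (Mann-Whitney rank statistic, midranks for ties)."""
    labeled = gt > 0
    y = gt[labeled]
    cm = ClassMetrics()
    for k, cls in enumerate(classes):
        pos = y == cls
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        scores = np.asarray(prob_map)[..., k][labeled]
        ranks = rankdata(scores)
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        cm.auc[cls] = 100.0 * u / (n_pos * n_neg)
    return cm


def confusion_matrix(class_map: np.ndarray, gt: np.ndarray,
                     row_normalize: bool = True,
                     dura_as_outside: bool = False) -> np.ndarray:
    """4x4 confusion matrix over labeled pixels, rows = true class.

    With ``dura_as_outside`` the dura row/column is merged into the 4th
    position interpreted as "outside" (for fused maps whose 4th class is
    background rather than dura).
    """
    labeled = gt > 0
    y = gt[labeled].astype(int)
    p = np.asarray(class_map)[labeled].astype(int)
    mat = np.zeros((4, 4), float)
    np.add.at(mat, (y - 1, np.clip(p - 1, 0, 3)), 1.0)
    if row_normalize:
        sums = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(sums > 0, 100.0 * mat / sums, 0.0)
    return mat


def aggregate(per_patient: list) -> dict:
    """Patient-level class means, then cohort mean +/- sample sd (n-1)."""
    if not per_patient:
        raise ValueError("need at least one patient")

    def patient_mean(cm: ClassMetrics, attr: str):
        vals = list(getattr(cm, attr).values())
        return float(np.mean(vals)) if vals else np.nan

    f1s = np.array([patient_mean(cm, "f1") for cm in per_patient])
    aucs = np.array([patient_mean(cm, "auc") for cm in per_patient])

    def stats(v):
        v = v[~np.isnan(v)]
        if v.size == 0:
            return (np.nan, np.nan)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return (float(v.mean()), sd)

    mf1, sf1 = stats(f1s)
    mauc, sauc = stats(aucs)
    return {"mF1": mf1, "mF1_sd": sf1, "mAUC": mauc, "mAUC_sd": sauc}


def percentile_rank(dsc_table: np.ndarray,
                    percentiles=(5.0, 50.0, 95.0)) -> dict:
    """Select exemplar images nearest the given percentiles of the per-image
    DSC averaged over models. ``dsc_table`` is (n_images, n_models)."""
    table = np.atleast_2d(np.asarray(dsc_table, float))
    if table.shape[0] < 3:
        raise ValueError("need at least 3 images")
    avg = table.mean(axis=1)
    out = {}
    names = ("bad", "intermediate", "good")
    for name, q in zip(names, percentiles):
        target = np.percentile(avg, q)  # linear interpolation
        out[name] = int(np.argmin(np.abs(avg - target)))
    return out
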