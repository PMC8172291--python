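"""Segmentation evaluation: confusion counts, Se/Sp/ACC/AUC, MCC, and CAL.

Two things are specific to this evaluation protocol and worth noting:

* **AUC** here is the balanced accuracy (Se + Sp)/2 computed from a single
  binary mask — not the area under an ROC curve swept over thresholds.
* **CAL** is the product of Connectivity (agreement in connected-component
  count), Area (overlap after dilating each mask by a disc of radius α)
  and Length (overlap of skeletons against the other mask's β-dilation).
  It rewards topologically faithful segmentations: pixel-accuracy metrics
  barely penalize a vessel broken into fragments, while C does.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CALReport",
    "confusion_counts",
    "basic_metrics",
    "mcc",
    "cal_metrics",
    "evaluate_pair",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """Se/Sp/ACC/AUC/MCC; an undefined metric (zero denominator) is NaN."""

    se: float
    sp: float
    acc: float
    auc: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class CALReport:
    c: float
    a: float
    l: float

    @property
    def cal(self) -> float:
        return self.c * self.a * self.l


def confusion_counts(pred: np.ndarray, gt: np.ndarray,
                     region: np.ndarray | None = None) -> ConfusionCounts:
    """Pixel confusion counts, restricted to ``region`` when given."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"dim mismatch: {pred.shape} vs {gt.shape}")
    if region is None:
        region = np.ones_like(pred)
    else:
        region = np.asarray(region, dtype=bool)
        if region.shape != pred.shape:
            raise ValueError("region mask dims must match")
        if not region.any():
            raise ValueError("empty evaluation region")
    p, g = pred[region], gt[region]
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def basic_metrics(c: ConfusionCounts) -> MetricsReport:
    """Se = TP/(TP+FN), Sp = TN/(TN+FP), ACC, AUC = (Se+Sp)/2, plus MCC."""
    se = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    acc = _ratio(c.tp + c.tn, c.total)
    auc = (se + sp) / 2.0
    return MetricsReport(se=se, sp=sp, acc=acc, auc=auc, mcc=mcc(c))


def mcc(c: ConfusionCounts, *, printed_variant: bool = False) -> float:
    """Matthews correlation coefficient.

    The standard numerator is TP·TN − FP·FN; ``printed_variant`` computes
    TP·TN − TP·FN instead, kept only for auditing against typeset sources.
    Returns 0 (by convention, logged) when any marginal sum is zero.
    """
    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        logger.debug("MCC undefined (a marginal sum is zero); returning 0 by convention")
        return 0.0
    num = c.tp * c.tn - (c.tp * c.fn if printed_variant else c.fp * c.fn)
    return num / math.sqrt(denom2)


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    return ndi.binary_dilation(mask, structure=morphology.disk(radius))


def _skeleton(mask: np.ndarray) -> np.ndarray:
    """Homotopic thinning to unit-width centerlines."""
    return morphology.skeletonize(mask)


def _n_components(mask: np.ndarray) -> int:
    return ndi.label(mask, structure=_EIGHT)[1]


def cal_metrics(s: np.ndarray, s_g: np.ndarray, alpha: int = 2, beta: int = 2) -> CALReport:
    """Connectivity, Area and Length agreement between prediction and truth.

    C = 1 − min(1, |#components(S_G) − #components(S)| / #pixels(S_G));
    A = #(δ_α(S)∩S_G ∪ δ_α(S_G)∩S) / #(S∪S_G);
    L = #(φ(S)∩δ_β(S_G) ∪ δ_β(S)∩φ(S_G)) / #(φ(S)∪φ(S_G)),
    with δ a disc dilation and φ the skeleton.  Components are 8-connected.
    """
    s = np.asarray(s, dtype=bool)
    s_g = np.asarray(s_g, dtype=bool)
    if s.shape != s_g.shape:
        raise ValueError(f"dim mismatch: {s.shape} vs {s_g.shape}")
    if not s_g.any():
        raise ValueError("ground truth mask is empty")

    c = 1.0 - min(1.0, abs(_n_components(s_g) - _n_components(s)) / s_g.sum())

    union = s | s_g
    a_num = (_dilate(s, alpha) & s_g) | (_dilate(s_g, alpha) & s)
    a = a_num.sum() / union.sum()

    phi_s, phi_g = _skeleton(s), _skeleton(s_g)
    l_den = (phi_s | phi_g).sum()
    if l_den == 0:
        l = 0.0
    else:
        l_num = (phi_s & _dilate(s_g, beta)) | (_dilate(s, beta) & phi_g)
        l = l_num.sum() / l_den
    return CALReport(c=c, a=a, l=l)


def evaluate_pair(pred: np.ndarray, gt: np.ndarray,
                  fov: np.ndarray | None = None) -> dict[str, float]:
    """All metrics for one prediction/truth pair (confusion inside FOV, CAL global)."""
    rep = basic_metrics(confusion_counts(pred, gt, fov))
    out = rep.as_dict()
    if gt.any():
        cal = cal_metrics(pred, gt)
        out.update({"c": cal.c, "a": cal.a, "l": cal.l, "cal": cal.cal})
    return out
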