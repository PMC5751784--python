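"""Confusion-matrix metrics and ROC/AUC for assessing DEG callers.

A call counts as a true positive only when the gene is truly
differentially expressed AND the called direction matches the true one;
an up-call on a truly down-regulated gene is a false positive. Undefined
ratios (0/0) are reported as NaN and flagged, never silently imputed as
zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np

from .errors import ParameterError, RocMonotonicityWarning

__all__ = ["EvalResult", "confusion", "roc_auc"]


@dataclass(frozen=True)
class EvalResult:
    """Confusion matrix and derived metrics for one caller on one dataset.

    ``undefined`` names the metrics whose denominator was zero; those
    fields hold NaN.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    ppv: float
    fscore: float
    fpr: float
    undefined: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "EvalResult":
        for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
            if v < 0 or int(v) != v:
                raise ParameterError(f"{name} must be a non-negative integer, got {v}")
        undefined = set()

        def ratio(num, den, name):
            if den == 0:
                undefined.add(name)
                return math.nan
            return num / den

        sensitivity = ratio(tp, tp + fn, "sensitivity")
        ppv = ratio(tp, tp + fp, "ppv")
        fpr = ratio(fp, fp + tn, "fpr")
        if "sensitivity" in undefined or "ppv" in undefined or sensitivity + ppv == 0:
            undefined.add("fscore")
            fscore = math.nan
        else:
            fscore = 2.0 * sensitivity * ppv / (sensitivity + ppv)
        return cls(
            tp=int(tp),
            fp=int(fp),
            fn=int(fn),
            tn=int(tn),
            sensitivity=sensitivity,
            ppv=ppv,
            fscore=fscore,
            fpr=fpr,
            undefined=frozenset(undefined),
        )


def confusion(
    calls: Mapping[str, str],
    truth: Mapping[str, str],
    universe: Iterable[str],
) -> EvalResult:
    """Direction-aware confusion matrix.

    ``calls`` and ``truth`` map gene id -> direction ('up' or 'down');
    ``universe`` lists every gene considered. A call is a TP only if the
    gene is truly differentially expressed and the direction matches;
    wrong-direction calls and calls on non-DE genes are FPs; missed or
    wrong-direction true DE genes are FNs.
    """
    universe = set(universe)
    for name, mapping in (("calls", calls), ("truth", truth)):
        extra = set(mapping) - universe
        if extra:
            raise ParameterError(
                f"{name} contains genes outside the universe: {sorted(extra)[:5]}"
            )
        bad = {g: d for g, d in mapping.items() if d not in ("up", "down")}
        if bad:
            raise ParameterError(f"{name} has invalid directions: {bad}")

    tp = sum(1 for g, d in calls.items() if truth.get(g) == d)
    fp = len(calls) - tp
    fn = len(truth) - tp
    tn = len(universe) - tp - fp - fn
    # a wrong-direction call on a true DE gene is both an FP (the call) and
    # an FN (the missed truth); it must not be double-removed from TN
    wrong_dir = sum(1 for g, d in calls.items() if g in truth and truth[g] != d)
    tn += wrong_dir
    return EvalResult.from_counts(tp, fp, fn, tn)


def roc_auc(points: Sequence[Tuple[float, float]]) -> float:
    """Trapezoid-rule area under an ROC curve.

    ``points`` are (FPR, TPR) pairs; (0,0) and (1,1) are appended before
    sorting by FPR. No convex-hull smoothing is applied (raw trapezoid).
    A decreasing TPR after sorting — possible for noisy stochastic sweeps
    — triggers a warning, not an error.
    """
    pts = [(float(f), float(t)) for f, t in points]
    for f, t in pts:
        if not (0.0 <= f <= 1.0) or not (0.0 <= t <= 1.0):
            raise ParameterError(f"ROC point ({f}, {t}) outside the unit square")
    pts.extend([(0.0, 0.0), (1.0, 1.0)])
    pts = sorted(set(pts))
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    if np.any(np.diff(tpr) < -1e-12):
        warnings.warn(
            "TPR is not monotone non-decreasing along the sorted ROC curve",
            RocMonotonicityWarning,
            stacklevel=2,
        )
    return float(np.trapezoid(tpr, fpr))
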