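"""Binary-call performance metrics: sensitivity, specificity, ROC/AUC.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), each with a 95%
normal-approximation interval p +/- 1.96*sqrt(p(1-p)/n) on the relevant
denominator, clipped to [0, 1]. The ROC curve sweeps thresholds over
the unique scores; the AUC is the trapezoid area, which with
rank-averaged ties equals the Mann-Whitney statistic
P(score+ > score-) + 0.5 * P(score+ = score-).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Z95 = 1.96


@dataclass
class MetricCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def binary_counts(calls, truths) -> MetricCounts:
    calls = np.asarray(calls, dtype=bool)
    truths = np.asarray(truths, dtype=bool)
    if calls.shape != truths.shape:
        raise ValueError("calls and truths must align")
    return MetricCounts(
        tp=int((calls & truths).sum()),
        tn=int((~calls & ~truths).sum()),
        fp=int((calls & ~truths).sum()),
        fn=int((~calls & truths).sum()),
    )


def _proportion_ci(p: float, n: int) -> tuple[float, float]:
    half = Z95 * np.sqrt(p * (1.0 - p) / n)
    return (float(np.clip(p - half, 0.0, 1.0)),
            float(np.clip(p + half, 0.0, 1.0)))


def compute_metrics(calls, truths) -> dict:
    """Sensitivity and specificity with 95% CIs for one lesion line.

    A zero denominator leaves the metric undefined (NaN) and flagged.
    """
    counts = binary_counts(calls, truths)
    out = {"counts": counts, "undefined": []}
    npos = counts.tp + counts.fn
    nneg = counts.tn + counts.fp
    if npos > 0:
        sens = counts.tp / npos
        out["sensitivity"] = sens
        out["sensitivity_ci"] = _proportion_ci(sens, npos)
    else:
        out["sensitivity"] = float("nan")
        out["sensitivity_ci"] = (float("nan"), float("nan"))
        out["undefined"].append("sensitivity")
    if nneg > 0:
        spec = counts.tn / nneg
        out["specificity"] = spec
        out["specificity_ci"] = _proportion_ci(spec, nneg)
    else:
        out["specificity"] = float("nan")
        out["specificity_ci"] = (float("nan"), float("nan"))
        out["undefined"].append("specificity")
    return out


def roc_auc(scores, truths) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) swept over unique scores, and trapezoid AUC."""
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=bool)
    npos = int(truths.sum())
    nneg = int((~truths).sum())
    if npos == 0 or nneg == 0:
        return [(0.0, 0.0), (1.0, 1.0)], float("nan")
    thresholds = np.unique(scores)[::-1]
    points = [(0.0, 0.0)]
    for t in thresholds:
        called = scores >= t
        tpr = (called & truths).sum() / npos
        fpr = (called & ~truths).sum() / nneg
        points.append((float(fpr), float(tpr)))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    fprs = np.array([p[0] for p in points])
    tprs = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return points, auc
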