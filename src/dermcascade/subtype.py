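"""Severity-ordered lesion subtyping for positive mel/BCC/ASL slides.

Each line carries a severity ladder (most severe first): melanocytic
severely_atypical > mildly_atypical > benign_nevi; ASL invasive SCC >
SCCIS > AK; BCC infiltrative > nodular > superficial. One binary
classifier per subtype (that subtype vs the line's other subtypes) is
trained on ROI windows expanded to the edges of the detected lesion
region. Inference walks the ladder most-severe-first and stops at the
first rung whose classifier fires on any expanded ROI; if no rung
fires the result is inconclusive. BCC additionally evaluates the
remaining rungs after a winner and reports ``mixed`` when two or more
distinct rungs fire.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SEVERITY_LADDERS
from .patches import PatchClassifier, ProbabilityMap
from .roi import EIGHT_CONN, Roi

logger = logging.getLogger(__name__)


@dataclass
class SeverityLadder:
    lesion_line: str
    subtypes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.subtypes:
            self.subtypes = list(SEVERITY_LADDERS[self.lesion_line])
        if len(set(self.subtypes)) != len(self.subtypes) or not self.subtypes:
            raise ValueError("severity ladder must be nonempty, no duplicates")

    def severity_index(self, subtype: str) -> int:
        return self.subtypes.index(subtype)


@dataclass
class SubtypeResult:
    label: str                               # subtype, 'mixed', 'inconclusive'
    supporting_rois: list[int] = field(default_factory=list)
    max_scores: dict[str, float] = field(default_factory=dict)


def expand_roi_to_lesion(roi: Roi, pmap: ProbabilityMap
                         ) -> tuple[int, int, int, int]:
    """Expand an ROI to the bounding box of its lesion component.

    The window is the pixel bounding box of the 8-connected positive
    component containing the ROI center, padded by one patch on each
    side and clipped to the slide; an off-component center returns the
    original window.
    """
    p = pmap.patch_size
    cx, cy = roi.center
    r = int(cy // p)
    c = int(cx // p)
    rows, cols = pmap.binary.shape
    if not (0 <= r < rows and 0 <= c < cols) or not pmap.binary[r, c]:
        return roi.window
    labeled, _ = ndimage.label(pmap.binary, structure=EIGHT_CONN)
    comp = labeled == labeled[r, c]
    rr, cc = np.nonzero(comp)
    h, w = pmap.slide_shape
    x0 = max(0, cc.min() * p - p)
    y0 = max(0, rr.min() * p - p)
    x1 = min(w, (cc.max() + 1) * p + p)
    y1 = min(h, (rr.max() + 1) * p + p)
    return (int(x0), int(y0), int(x1), int(y1))


def build_subtype_dataset(roi_records: list[dict],
                          ladder: SeverityLadder,
                          reviewer_table: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Assign exactly one subtype label to each expanded ROI.

    ``roi_records`` rows carry ``roi_id, wsi_name, split, supervised``
    plus either ``mask_subtypes`` (list of subtype labels overlapping
    the ROI, supervised slides) or nothing (weak slides, labeled via the
    reviewer table with columns ``roi_id, subtype``). Conflicting
    supervised subtypes resolve to the most severe (logged); weak ROIs
    without a reviewer label are excluded with a log entry.
    """
    review = {}
    if reviewer_table is not None:
        review = dict(zip(reviewer_table["roi_id"],
                          reviewer_table["subtype"]))
    rows = []
    for rec in roi_records:
        if rec.get("supervised", True):
            subs = [s for s in rec.get("mask_subtypes", [])
                    if s in ladder.subtypes]
            if not subs:
                logger.info("ROI %s has no subtype mask; excluded",
                            rec["roi_id"])
                continue
            label = min(subs, key=ladder.severity_index)
            if len(set(subs)) > 1:
                logger.info("ROI %s has conflicting subtypes %s; "
                            "most severe %s wins", rec["roi_id"],
                            sorted(set(subs)), label)
        else:
            if rec["roi_id"] not in review:
                logger.info("weak ROI %s lacks a reviewer label; excluded",
                            rec["roi_id"])
                continue
            label = review[rec["roi_id"]]
            if label not in ladder.subtypes:
                raise ValueError(f"reviewer subtype {label!r} not in ladder")
        rows.append({"roi_id": rec["roi_id"], "wsi_name": rec["wsi_name"],
                     "split": rec.get("split", "train"), "subtype": label})
    return pd.DataFrame(rows, columns=["roi_id", "wsi_name", "split",
                                       "subtype"])


class SubtypeClassifier(PatchClassifier):
    """One-vs-rest binary classifier for a single subtype rung.

    Positive = the subtype; negative = the line's other subtypes.
    Same backbone registry, loop, loss, optimizer, and scheduler as the
    patch classifier; trained only on line-positive slides.
    """


def _scores(classifier, images: np.ndarray) -> np.ndarray:
    if hasattr(classifier, "predict_proba"):
        return np.asarray(classifier.predict_proba(images), dtype=float)
    return np.asarray(classifier(images), dtype=float)


def subtype_cascade(expanded_roi_images: np.ndarray,
                    ladder: SeverityLadder,
                    classifiers: dict[str, object],
                    roi_threshold: float = 0.5) -> SubtypeResult:
    """Severity-ordered inference over the expanded ROIs of one slide.

    Walks the ladder most-severe-first; the first rung with any ROI
    score strictly above ``roi_threshold`` wins and, for mel/ASL, the
    remaining rungs are never consulted. For BCC the remaining rungs
    are still tested after a winner and ``mixed`` is reported when at
    least two distinct rungs fire.
    """
    if len(expanded_roi_images) == 0:
        raise ValueError("subtype cascade requires at least one ROI")
    max_scores: dict[str, float] = {}
    winner = None
    supporting: list[int] = []
    fired = []
    for subtype in ladder.subtypes:
        if winner is not None and ladder.lesion_line != "bcc":
            break
        scores = _scores(classifiers[subtype], expanded_roi_images)
        max_scores[subtype] = float(scores.max())
        if (scores > roi_threshold).any():
            fired.append(subtype)
            if winner is None:
                winner = subtype
                supporting = np.flatnonzero(scores > roi_threshold).tolist()
    if winner is None:
        return SubtypeResult(label="inconclusive", max_scores=max_scores)
    if ladder.lesion_line == "bcc" and len(fired) >= 2:
        return SubtypeResult(label="mixed", supporting_rois=supporting,
                             max_scores=max_scores)
    return SubtypeResult(label=winner, supporting_rois=supporting,
                         max_scores=max_scores)
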