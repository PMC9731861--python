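"""Semi-supervised phase: pseudo-labels, auto-generated masks, merging.

Weakly labeled slides (slide-level diagnosis only) are run through the
evaluation cascade; the slide call is compared with the diagnosis to
assign a pseudo-label per lesion line: agreement on positive (TP)
yields a positive label, agreement on negative (TN) and a false
positive (FP) both yield a negative "not this lesion" label, and a
false negative (FN) excludes the slide from mask auto-generation and
flags it for manual ROI review. Auto-generated masks are the line's
binary probability map cleaned of small/low-confidence components and
rescaled to the supervised annotation scale; a dermatopathologist
agreement table then drops disputed slides. The merged dataset keeps
the supervised split and splits weak slides by case order (first 80%
train, last 20% validation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from .patches import ProbabilityMap
from .roi import EIGHT_CONN
from .slide_io import save_mask

logger = logging.getLogger(__name__)

OUTCOMES = ("positive", "negative", "excluded")
PROVENANCES = ("TP", "TN", "FP", "FN")


@dataclass
class SSLLabel:
    wsi_name: str
    lesion_line: str
    outcome: str
    provenance: str
    reviewer_agreement: str = "pending"
    flagged_for_review: bool = False


def assign_ssl_label(prediction: bool, ground_truth: bool, line: str,
                     wsi_name: str = "") -> SSLLabel:
    """Pseudo-label truth table for one line.

    (pred+, gt+) -> TP/positive; (pred-, gt-) -> TN/negative;
    (pred+, gt-) -> FP/negative; (pred-, gt+) -> FN/excluded+flagged.
    """
    if prediction and ground_truth:
        return SSLLabel(wsi_name, line, "positive", "TP")
    if not prediction and not ground_truth:
        return SSLLabel(wsi_name, line, "negative", "TN")
    if prediction and not ground_truth:
        return SSLLabel(wsi_name, line, "negative", "FP")
    return SSLLabel(wsi_name, line, "excluded", "FN",
                    flagged_for_review=True)


def generate_ssl_masks(pmap: ProbabilityMap, ssl_label: SSLLabel,
                       annotation_scale: float, out_dir: str | Path,
                       map_mpp: float, min_component_patches: int = 3,
                       min_mean_prob: float = 0.9) -> pd.DataFrame:
    """Auto-generate annotation mask files from a probability map.

    Components smaller than ``min_component_patches`` cells or with mean
    raw probability below ``min_mean_prob`` are dropped as
    low-confidence/noisy; survivors are rescaled from the map's working
    resolution (``map_mpp``) to the supervised annotation scale and
    written one mask file + manifest row each. A negative label (or a
    positive map with no surviving components) yields a single
    empty-mask sentinel row so the slide enters patch training as an
    all-negative slide.
    """
    if ssl_label.outcome == "excluded":
        raise ValueError("excluded (FN) slides get no auto-generated masks")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    sentinel = {"wsi_name": ssl_label.wsi_name, "mask_file": "",
                "label": ssl_label.lesion_line, "x0": 0, "y0": 0,
                "scale": annotation_scale}
    if ssl_label.outcome == "negative":
        rows.append(sentinel)
    else:
        p = pmap.patch_size
        f = map_mpp / annotation_scale
        labeled, n = ndimage.label(pmap.binary, structure=EIGHT_CONN)
        k = 0
        for lab in range(1, n + 1):
            comp = labeled == lab
            if comp.sum() < min_component_patches:
                continue
            if pmap.raw[comp].mean() < min_mean_prob:
                continue
            rr, cc = np.nonzero(comp)
            local = comp[rr.min():rr.max() + 1, cc.min():cc.max() + 1]
            px = np.kron(local, np.ones((p, p), dtype=bool))
            if f != 1.0:
                hh = max(1, int(round(px.shape[0] * f)))
                ww = max(1, int(round(px.shape[1] * f)))
                px = resize(px.astype(float), (hh, ww), order=0,
                            anti_aliasing=False, preserve_range=True) > 0.5
            fname = f"{ssl_label.wsi_name}_{ssl_label.lesion_line}_ssl{k}.png"
            save_mask(px, out_dir / fname)
            rows.append({
                "wsi_name": ssl_label.wsi_name, "mask_file": fname,
                "label": ssl_label.lesion_line,
                "x0": int(round(cc.min() * p * f)),
                "y0": int(round(rr.min() * p * f)),
                "scale": annotation_scale,
            })
            k += 1
        if k == 0:
            rows.append(sentinel)
    return pd.DataFrame(rows, columns=["wsi_name", "mask_file", "label",
                                       "x0", "y0", "scale"])


def apply_review(labels: list[SSLLabel],
                 agreement_table: pd.DataFrame) -> list[SSLLabel]:
    """Drop slides whose reviewers disagreed; treat missing as pending.

    ``agreement_table`` columns: wsi_name, verdict in {agree, disagree}.
    """
    verdicts = dict(zip(agreement_table["wsi_name"],
                        agreement_table["verdict"]))
    kept = []
    for lab in labels:
        v = verdicts.get(lab.wsi_name, "pending")
        lab.reviewer_agreement = v
        if v == "agree":
            kept.append(lab)
        elif v == "pending":
            logger.warning("no reviewer verdict for %s; treated as dropped",
                           lab.wsi_name)
    return kept


def merge_datasets(supervised_split: dict[str, str],
                   weak_cases: list[tuple[str, int]],
                   weak_val_fraction: float = 0.2) -> pd.DataFrame:
    """Merge supervised and weak WSI sets with the ordered split.

    Supervised WSIs keep their original split; weak WSIs are sorted by
    case_id and split by order, the last ``weak_val_fraction`` going to
    validation. Splitting of the weak subset is deliberately not
    random, mirroring the order in which cases reach the lab. A
    wsi_name in both sets is an error.
    """
    dup = set(supervised_split) & {w for w, _ in weak_cases}
    if dup:
        raise ValueError(f"duplicate wsi_name across datasets: {sorted(dup)}")
    rows = [{"wsi_name": w, "split": s, "source": "supervised"}
            for w, s in supervised_split.items()]
    ordered = sorted(weak_cases, key=lambda t: t[1])
    n_train = int(round((1.0 - weak_val_fraction) * len(ordered)))
    for i, (w, _) in enumerate(ordered):
        rows.append({"wsi_name": w,
                     "split": "train" if i < n_train else "val",
                     "source": "weak"})
    return pd.DataFrame(rows, columns=["wsi_name", "split", "source"])


def finetune_all(slides, annotation_table, wsi_labels, merged_split,
                 prior_models, configs, seed: int, segmenter=None,
                 mask_loader=None, release_gate: bool = True):
    """Rerun the patch/ROI/WSI pipelines per line from prior checkpoints.

    With ``release_gate`` (default), each fine-tuned line stack must be
    equivalent or superior to its prior on the merged validation slides
    (end-to-end slide-level AUC) to be released; a regressing candidate
    is rejected and the prior stack stays in place. Returns
    ``(released_models, gated_lines)`` when the gate is on, else just
    the fine-tuned models.
    """
    from .training import predict_line, train_all_lines
    candidates = train_all_lines(slides, annotation_table, wsi_labels,
                                 configs, seed, segmenter=segmenter,
                                 mask_loader=mask_loader,
                                 split=merged_split, priors=prior_models)
    if not release_gate:
        return candidates
    if isinstance(merged_split, pd.DataFrame):
        split_map = dict(zip(merged_split["wsi_name"],
                             merged_split["split"]))
    else:
        split_map = dict(merged_split)
    val_names = [w for w, s in split_map.items()
                 if s == "val" and w in slides]
    from .metrics import roc_auc
    released, gated = {}, []
    for line, cand in candidates.items():
        y = np.array([bool(wsi_labels[line][w]) for w in val_names])
        if y.all() or not y.any():
            released[line] = cand
            continue
        def auc_of(lm):
            probs = np.array([predict_line(slides[w], lm)[0]
                              for w in val_names])
            _, auc = roc_auc(probs, y)
            return auc
        auc_new = auc_of(cand)
        auc_old = auc_of(prior_models[line])
        if np.isfinite(auc_new) and auc_new >= auc_old:
            released[line] = cand
        else:
            released[line] = prior_models[line]
            gated.append(line)
            logger.warning("line %s fine-tune regressed (val AUC %.3f < "
                           "%.3f); prior model retained", line, auc_new,
                           auc_old)
    return released, gated
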