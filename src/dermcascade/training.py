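"""Per-line training orchestration: patch -> ROI -> MIL.

``train_line`` runs one lesion line's full supervised stack on a set of
slides: build and split the patch dataset, train the patch classifier,
reconstruct per-slide probability maps with test-time augmentation,
select ROIs, train the ROI classifier warm-started from the patch
model (preserving the patch-level WSI split), extract GAP embedding
bags, and train the attention-MIL slide classifier. ``train_all_lines``
repeats this for every line and supports warm starts from a prior model
set (the semi-supervised fine-tuning phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import LESION_LINES, LineConfig
from .mil import AttentionMILClassifier
from .patches import (PatchClassifier, ProbabilityMap, apply_split,
                      build_patch_dataset, build_probmap, infer_patches_tta,
                      split_by_wsi)
from .roi import (RoiClassifier, Roi, assign_roi_labels, extract_embeddings,
                  extract_roi_images, postprocess_probmap, select_rois)
from .segmentation import filter_tissue_patches, segment_tissue
from .slide_io import SlideImage, rescale_to_mpp, tile


@dataclass
class LineModels:
    """The trained three-level stack of one lesion line."""

    line: str
    cfg: LineConfig
    patch: PatchClassifier
    roi: RoiClassifier
    mil: AttentionMILClassifier
    val_wsis: set[str]


def slide_probmap(slide: SlideImage, cfg: LineConfig,
                  patch_model: PatchClassifier, segmenter=None
                  ) -> tuple[ProbabilityMap, SlideImage]:
    """Rescale, tile, segment, TTA-infer, and reconstruct the probmap."""
    rescaled = rescale_to_mpp(slide, cfg.base_mpp)
    grid = tile(rescaled, cfg.patch_size)
    mask = segment_tissue(rescaled, segmenter)
    kept = filter_tissue_patches(grid, mask, cfg.min_tissue_fraction)
    raw = np.zeros((grid.n_rows, grid.n_cols))
    if kept:
        patches = np.stack([grid.extract(rescaled.pixels, r, c)
                            for r, c in kept])
        probs = infer_patches_tta(patch_model, patches)
        for (r, c), p in zip(kept, probs):
            raw[r, c] = p
    pmap = build_probmap(grid, raw, kept, threshold=cfg.positive_threshold,
                         lesion_line=cfg.lesion_line)
    return pmap, rescaled


def _slide_rng(name: str) -> np.random.Generator:
    """Per-slide RNG for the random-ROI fallback: reproducible across
    training, gating, and evaluation so a slide's bag is always the
    same."""
    import zlib
    return np.random.default_rng([0xD37, zlib.crc32(name.encode())])


def slide_rois(slide: SlideImage, cfg: LineConfig,
               patch_model: PatchClassifier, segmenter=None,
               rng: np.random.Generator | None = None
               ) -> tuple[list[Roi], np.ndarray, ProbabilityMap, SlideImage]:
    """ROIs and their pixel windows for one slide."""
    pmap, rescaled = slide_probmap(slide, cfg, patch_model, segmenter)
    cleaned = postprocess_probmap(pmap, cfg.min_component_patches)
    rois = select_rois(cleaned, cfg.n_top, cfg.roi_size,
                       rng=rng if rng is not None else _slide_rng(slide.name),
                       order=cfg.roi_order)
    images = extract_roi_images(rescaled.pixels, rois, cfg.roi_size)
    return rois, images, cleaned, rescaled


def predict_line(slide: SlideImage, lm: "LineModels",
                 rng: np.random.Generator | None = None,
                 segmenter=None) -> tuple[float, bool]:
    """One line's full multi-level slide prediction (prob, binary call)."""
    rois, images, cleaned, rescaled = slide_rois(slide, lm.cfg, lm.patch,
                                                 segmenter, rng=rng)
    from .roi import extract_embeddings
    bag = extract_embeddings(lm.roi, images, slide.name, 0, rois)
    prob, call, _ = lm.mil.predict_wsi(bag.matrix)
    return prob, bool(call)


def train_line(slides: dict[str, SlideImage], annotation_table: pd.DataFrame,
               wsi_labels: dict[str, bool], cfg: LineConfig, seed: int,
               segmenter=None, mask_loader=None,
               split: dict[str, str] | None = None,
               prior: LineModels | None = None) -> LineModels:
    """Train one line's patch/ROI/MIL stack.

    ``split`` (wsi_name -> 'train'/'val') imposes an existing split;
    otherwise a fresh random WSI-level split is drawn. ``prior`` warm
    starts all three models from earlier checkpoints and preserves the
    prior validation WSI set for slides it covers.
    """
    ds = build_patch_dataset(slides, annotation_table, cfg, segmenter,
                             mask_loader)
    if split is not None:
        val_wsis = {w for w, s in split.items() if s == "val"}
        apply_split(ds, val_wsis)
    elif prior is not None:
        val_wsis = prior.val_wsis & set(slides)
        apply_split(ds, val_wsis)
    else:
        split_by_wsi(ds, cfg.val_fraction, seed)
        val_wsis = set(ds.meta.loc[ds.meta["split"] == "val", "wsi_name"])

    patch_clf = PatchClassifier(
        backbone=cfg.backbone, epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.warm_lr if prior is not None else cfg.lr,
        random_state=seed)
    if prior is not None:
        patch_clf._init_state = prior.patch.model_.state_dict()
    patch_clf.fit(ds.images, ds.meta["label"].to_numpy(),
                  ds.meta["split"].to_numpy())

    # ROI dataset preserves the patch-level WSI split (no re-split).
    roi_images, roi_labels, roi_splits, bags_meta = [], [], [], []
    for name, slide in slides.items():
        rois, images, cleaned, rescaled = slide_rois(
            slide, cfg, patch_clf, segmenter)
        label = int(bool(wsi_labels.get(name, False)))
        assign_roi_labels(rois, label)
        sp = "val" if name in val_wsis else "train"
        roi_images.append(images)
        roi_labels.extend([label] * len(rois))
        roi_splits.extend([sp] * len(rois))
        bags_meta.append((name, label, sp, len(rois), rois))
    roi_stack = np.concatenate(roi_images) if roi_images else \
        np.zeros((0, cfg.roi_size, cfg.roi_size, 3), dtype=np.uint8)

    roi_clf = RoiClassifier(backbone=cfg.backbone, epochs=cfg.roi_epochs,
                            batch_size=cfg.roi_batch_size, lr=cfg.warm_lr,
                            random_state=seed + 2)
    roi_clf.init_from(prior.roi if prior is not None else patch_clf)
    roi_clf.fit(roi_stack, np.asarray(roi_labels, dtype=float),
                np.asarray(roi_splits))

    bags, bag_labels, bag_splits = [], [], []
    offset = 0
    for name, label, sp, k, rois in bags_meta:
        bag = extract_embeddings(roi_clf, roi_stack[offset:offset + k],
                                 name, label, rois)
        offset += k
        bags.append(bag.matrix)
        bag_labels.append(label)
        bag_splits.append(sp)

    mil = AttentionMILClassifier(lesion_line=cfg.lesion_line,
                                 wsi_threshold=cfg.wsi_threshold,
                                 lr=2e-3 if prior is not None else 5e-3,
                                 random_state=seed + 3)
    if prior is not None:
        mil._init_state = prior.mil.net_.state_dict()
    mil.fit(bags, np.asarray(bag_labels, dtype=float), bag_splits)

    return LineModels(line=cfg.lesion_line, cfg=cfg, patch=patch_clf,
                      roi=roi_clf, mil=mil, val_wsis=val_wsis)


def train_all_lines(slides, annotation_table, wsi_labels_by_line,
                    configs: dict[str, LineConfig], seed: int,
                    segmenter=None, mask_loader=None,
                    split: dict[str, str] | pd.DataFrame | None = None,
                    priors: dict[str, LineModels] | None = None
                    ) -> dict[str, LineModels]:
    """Train every line's stack; ``wsi_labels_by_line[line][wsi] -> bool``."""
    if isinstance(split, pd.DataFrame):
        split = dict(zip(split["wsi_name"], split["split"]))
    out = {}
    for i, line in enumerate(l for l in LESION_LINES if l in configs):
        out[line] = train_line(
            slides, annotation_table, wsi_labels_by_line[line],
            configs[line], seed + 100 * i, segmenter=segmenter,
            mask_loader=mask_loader, split=split,
            prior=(priors or {}).get(line))
    return out
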