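"""Reproducible desk-scale studies on synthetic cohorts.

These functions define the package's standard synthetic experiments:
an end-to-end detection study (train the five per-line stacks on a
mixed 48-slide cohort, evaluate a balanced 60-slide cohort), the
semi-supervised fine-tuning study with its regression contract, a QC
benchmark on 200 defect/clean sections, a controlled margin-status
study, and a subtype benchmark. Problem sizes are chosen so the full
set runs in minutes on one CPU with the tiny backbones; every study is
deterministic given its seed.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from .config import (LESION_LINES, SEVERITY_LADDERS, LineConfig,
                     desk_line_config)
from .margin import margin_map_from_slide, margin_status
from .metrics import compute_metrics, roc_auc
from .pipeline import evaluate_slide
from .qc import HybridQCClassifier, classify_section
from .roi import postprocess_probmap
from .segmentation import extract_sections, segment_tissue
from .slide_io import PatchGrid, load_mask
from .ssl import (assign_ssl_label, apply_review, generate_ssl_masks,
                  merge_datasets, finetune_all)
from .subtype import SubtypeClassifier
from .synthetic import (SectionSpec, SlideSpec, export_annotations,
                        generate_balanced_cohort, generate_slide)
from .training import (LineModels, predict_line, slide_probmap,
                       train_all_lines)


@dataclass
class DetectionStudy:
    models: dict[str, LineModels]
    configs: dict[str, LineConfig]
    metrics: dict[str, dict]
    slides: dict
    annotation_table: pd.DataFrame
    mask_dir: Path
    wsi_labels: dict[str, dict[str, bool]]
    sup_split: dict[str, str]
    test_entries: list = field(default_factory=list)

    def mask_loader(self, fname: str):
        return load_mask(self.mask_dir / fname)


def run_detection_study(seed: int, n_train_per_class: int = 8,
                        n_test_per_class: int = 12,
                        work_dir: str | Path | None = None
                        ) -> DetectionStudy:
    """Train all five lines and evaluate a balanced held-out cohort."""
    work_dir = Path(work_dir) if work_dir else Path(tempfile.mkdtemp())
    train_entries = generate_balanced_cohort(
        n_train_per_class, LESION_LINES + ["none"], seed=seed, ink_band=True)
    tables = [export_annotations(e.truth, work_dir,
                                 csv_name=f"{e.wsi_name}.csv")
              for e in train_entries]
    table = pd.concat([t for t in tables if len(t)], ignore_index=True)
    slides = {e.wsi_name: e.slide for e in train_entries}
    configs = {l: desk_line_config(l) for l in LESION_LINES}
    labels = {l: {e.wsi_name: e.truth.wsi_labels[l] for e in train_entries}
              for l in LESION_LINES}
    # one shared class-stratified WSI split: every line's validation
    # set then contains both classes, keeping per-line val AUCs finite
    # and the pre/post fine-tuning comparison well defined
    split_rng = np.random.default_rng(seed + 7)
    split: dict[str, str] = {}
    by_class: dict[str, list[str]] = {}
    for e in train_entries:
        by_class.setdefault(e.lesion_class, []).append(e.wsi_name)
    for names in by_class.values():
        order = split_rng.permutation(len(names))
        n_val = max(1, int(round(0.2 * len(names))))
        for i, k in enumerate(order):
            split[names[k]] = "val" if i < n_val else "train"
    models = train_all_lines(
        slides, table, labels, configs, seed=seed + 1, split=split,
        mask_loader=lambda f: load_mask(work_dir / f))

    test_entries = generate_balanced_cohort(
        n_test_per_class, LESION_LINES, seed=seed + 1000, ink_band=True)
    calls = {l: [] for l in LESION_LINES}
    truths = {l: [] for l in LESION_LINES}
    for e in test_entries:
        rep = evaluate_slide(e.slide, models,
                             specimen_excision=e.truth.excision,
                             seed=seed + 2)
        for l in LESION_LINES:
            called = rep.final_line == l or l in rep.benign_positives
            calls[l].append(called)
            truths[l].append(e.truth.wsi_labels[l])
    metrics = {l: compute_metrics(calls[l], truths[l]) for l in LESION_LINES}
    sup_split = {w: ("val" if w in models["mel"].val_wsis else "train")
                 for w in slides}
    return DetectionStudy(models=models, configs=configs, metrics=metrics,
                          slides=slides, annotation_table=table,
                          mask_dir=work_dir, wsi_labels=labels,
                          sup_split=sup_split, test_entries=test_entries)


@dataclass
class SSLStudy:
    pre_auc: dict[str, float]
    post_auc: dict[str, float]
    labels_assigned: int
    flagged_fn: int
    post_models: dict[str, LineModels]
    gated_lines: list[str] = field(default_factory=list)


def run_ssl_study(detection: DetectionStudy, seed: int,
                  n_weak_per_class: int = 3) -> SSLStudy:
    """Pseudo-label a weak cohort, merge with the ordered split, and
    fine-tune every line from the supervised checkpoints; compare
    validation AUC of the pre- and post-SSL models on the merged
    validation slides."""
    weak = generate_balanced_cohort(n_weak_per_class,
                                    LESION_LINES + ["none"],
                                    seed=seed, ink_band=True)
    for w in weak:
        w.wsi_name = "weak_" + w.wsi_name
        w.slide.name = w.wsi_name
        w.truth.name = w.wsi_name
    ssl_dir = detection.mask_dir / "ssl_masks"
    ssl_tables, ssl_labels, flagged = [], [], []
    for w in weak:
        for l in LESION_LINES:
            gt = bool(w.truth.wsi_labels[l])
            _, call = predict_line(w.slide, detection.models[l])
            lab = assign_ssl_label(call, gt, l, w.wsi_name)
            ssl_labels.append(lab)
            if lab.outcome == "excluded":
                flagged.append((w.wsi_name, l))
                continue
            pmap, _ = slide_probmap(w.slide, detection.configs[l],
                                    detection.models[l].patch)
            ssl_tables.append(generate_ssl_masks(
                pmap, lab, annotation_scale=detection.configs[l].base_mpp,
                out_dir=ssl_dir, map_mpp=detection.configs[l].base_mpp))
    agreement = pd.DataFrame({"wsi_name": [w.wsi_name for w in weak],
                              "verdict": ["agree"] * len(weak)})
    kept = apply_review(ssl_labels, agreement)
    kept_names = {lab.wsi_name for lab in kept}
    weak_table = pd.concat(ssl_tables, ignore_index=True)
    merged = merge_datasets(
        detection.sup_split,
        [(w.wsi_name, i + 1) for i, w in enumerate(weak)
         if w.wsi_name in kept_names])
    all_slides = dict(detection.slides)
    all_slides.update({w.wsi_name: w.slide for w in weak
                       if w.wsi_name in kept_names})
    full_table = pd.concat([detection.annotation_table, weak_table],
                           ignore_index=True)
    all_labels = {l: {**detection.wsi_labels[l],
                      **{w.wsi_name: bool(w.truth.wsi_labels[l])
                         for w in weak}}
                  for l in LESION_LINES}

    def loader(fname: str):
        p = detection.mask_dir / fname
        return load_mask(p if p.exists() else ssl_dir / fname)

    post, gated = finetune_all(all_slides, full_table, all_labels, merged,
                               detection.models, detection.configs,
                               seed=seed + 2, mask_loader=loader)

    val_names = [w for w in merged.loc[merged["split"] == "val", "wsi_name"]
                 if w in all_slides]
    pre_auc, post_auc = {}, {}
    for l in LESION_LINES:
        y = np.array([all_labels[l][w] for w in val_names], dtype=bool)
        pre_p = np.array([predict_line(all_slides[w],
                                       detection.models[l])[0]
                          for w in val_names])
        post_p = np.array([predict_line(all_slides[w], post[l])[0]
                           for w in val_names])
        _, pre_auc[l] = roc_auc(pre_p, y)
        _, post_auc[l] = roc_auc(post_p, y)
    return SSLStudy(pre_auc=pre_auc, post_auc=post_auc,
                    labels_assigned=len(ssl_labels), flagged_fn=len(flagged),
                    post_models=post, gated_lines=gated)


def run_qc_study(seed: int, n_sections: int = 200,
                 train_fraction: float = 0.8) -> dict:
    """Hybrid QC classifier benchmark on synthetic defect/clean sections."""
    rng = np.random.default_rng(seed)
    kinds = ["ok", "blur", "fold", "artifact", "incomplete"]
    images, labels = [], []
    i = 0
    while len(images) < n_sections:
        kind = kinds[i % 5]
        lesion = SectionSpec("mel", "benign_nevi") if i % 3 == 0 \
            else SectionSpec()
        spec = SlideSpec(n_sections=1, section_size=72,
                         defects=[] if kind == "ok" else [(kind, 0)],
                         seed=int(rng.integers(2 ** 31)),
                         lesion_classes=[lesion])
        slide, _ = generate_slide(spec)
        secs = extract_sections(segment_tissue(slide))
        i += 1
        if not secs:
            continue
        images.append(secs[0].crop(slide.pixels))
        labels.append({"blur": "blurry", "fold": "folding"}.get(kind, kind))
    n_train = int(round(train_fraction * n_sections))
    model = HybridQCClassifier(random_state=seed)
    model.fit(images[:n_train], labels[:n_train])
    pred = [classify_section(im, model) for im in images[n_train:]]
    truth = labels[n_train:]
    acc = float(np.mean([p == t for p, t in zip(pred, truth)]))
    return {"accuracy": acc, "n_test": len(truth), "model": model}


def run_margin_study(mel_models: LineModels, seed: int,
                     n_per_arm: int = 20) -> dict:
    """Controlled lesion-vs-ink geometry: a melanocytic blob touching
    the green band should read margin-positive; a blob at least two
    patches away should read negative."""
    cfg = mel_models.cfg
    rng = np.random.default_rng(seed)
    correct = {"touch": 0, "far": 0}
    for _ in range(n_per_arm):
        for arm in ("touch", "far"):
            off, rad = ((24, 0), 34) if arm == "touch" else ((-18, 0), 14)
            spec = SlideSpec(
                n_sections=1, section_size=96, ink_band=True,
                seed=int(rng.integers(2 ** 31)),
                lesion_classes=[SectionSpec("mel", "severely_atypical",
                                            lesion_radius=rad,
                                            lesion_offset=off)])
            slide, _ = generate_slide(spec)
            pmap, rescaled = slide_probmap(slide, cfg, mel_models.patch)
            cleaned = postprocess_probmap(pmap, cfg.min_component_patches)
            grid = PatchGrid(cfg.patch_size, rescaled.height, rescaled.width)
            mmap = margin_map_from_slide(rescaled.pixels, grid)
            ms = margin_status(cleaned, mmap, "mel", "severely_atypical")
            want = "positive" if arm == "touch" else "negative"
            correct[arm] += ms.status == want
    return {"touch_positive_rate": correct["touch"] / n_per_arm,
            "far_negative_rate": correct["far"] / n_per_arm,
            "accuracy": (correct["touch"] + correct["far"]) / (2 * n_per_arm)}


def make_subtype_dataset(line: str, seed: int, n: int = 90,
                         size: int = 48) -> tuple[np.ndarray, list[str]]:
    """Lesion crops labeled by subtype for one line's ladder.

    Crops are taken at native resolution from the lesion center (not
    resized), preserving the spatial-frequency bands that distinguish
    the severity rungs; a crop larger than the lesion bounding box
    falls back to a resize.
    """
    rng = np.random.default_rng(seed)
    ladder = SEVERITY_LADDERS[line]
    X, y = [], []
    for i in range(n):
        st = ladder[i % len(ladder)]
        spec = SlideSpec(n_sections=1, section_size=64,
                         seed=int(rng.integers(2 ** 31)),
                         lesion_classes=[SectionSpec(line, st)])
        slide, truth = generate_slide(spec)
        reg = truth.regions[0]
        x0, y0 = reg.offset
        h, w = reg.mask.shape
        if h >= size and w >= size:
            cy, cx = y0 + h // 2, x0 + w // 2
            crop = slide.pixels[cy - size // 2:cy + size - size // 2,
                                cx - size // 2:cx + size - size // 2]
        else:
            crop = np.clip(np.round(resize(
                slide.pixels[y0:y0 + h, x0:x0 + w].astype(float),
                (size, size), order=1, anti_aliasing=False,
                preserve_range=True)), 0, 255).astype(np.uint8)
        X.append(crop)
        y.append(st)
    return np.stack(X), y


def run_subtype_study(line: str, seed: int, n: int = 90) -> dict:
    """One-vs-rest subtype classifiers for a line; held-out AUC each.

    The middle severity rung is a non-monotonic frequency-band
    discrimination, the hardest of the three; width 16 and a longer
    schedule keep all rungs separable.
    """
    X, y = make_subtype_dataset(line, seed, n=n)
    n_train = int(round(0.75 * n))
    splits = np.array(["train"] * n_train + ["val"] * (n - n_train))
    aucs, models = {}, {}
    for target in SEVERITY_LADDERS[line]:
        yy = np.array([1.0 if s == target else 0.0 for s in y])
        clf = SubtypeClassifier(backbone="tiny_cnn", width=16, epochs=80,
                                batch_size=8, lr=3e-3, random_state=seed)
        clf.fit(X, yy, splits)
        aucs[target] = float(clf.val_auc_)
        models[target] = clf
    return {"val_auc": aucs, "models": models}
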