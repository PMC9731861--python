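"""Patch-level stage: dataset construction, per-line binary patch
classifiers, test-time-augmented inference, and probability maps.

Each lesion line has its own binary patch classifier. Slides are
rescaled to the line's base MPP, tiled, stripped of non-tissue patches,
and each remaining patch labeled positive iff its pixel overlap with any
annotation mask of the line's label vocabulary reaches the overlap
threshold (default 0.5 of the patch area). Training uses binary
cross-entropy, Adam, and cosine annealing, with augmentation applied to
training batches only; the checkpoint with the best validation AUC is
kept. At inference each patch's probability is the mean sigmoid output
over the 8 dihedral variants of the patch (test-time augmentation), and
the binary probability map marks patches whose probability strictly
exceeds the positivity threshold (default 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize, AffineTransform, warp
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import Adam, CosineAnnealing, Tensor, bce_with_logits, make_backbone
from .config import ALL_KNOWN_LABELS, LINE_LABELS, LineConfig
from .metrics import roc_auc
from .segmentation import filter_tissue_patches, segment_tissue
from .slide_io import PatchGrid, SlideImage, rescale_to_mpp, tile

# -- dataset --------------------------------------------------------------


@dataclass
class PatchDataset:
    """In-memory patch store: image stack plus aligned metadata."""

    images: np.ndarray           # (N, p, p, 3) uint8
    meta: pd.DataFrame           # wsi_name, row, col, label, split
    lesion_line: str
    patch_size: int

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        idx = np.flatnonzero((self.meta["split"] == split).to_numpy())
        return self.images[idx], self.meta["label"].to_numpy()[idx]


def _mask_on_grid(mask: np.ndarray, offset: tuple[int, int], scale: float,
                  base_mpp: float, out_shape: tuple[int, int]) -> np.ndarray:
    """Paint an annotation mask onto a full-slide raster at base MPP."""
    f = scale / base_mpp
    if f != 1.0:
        hh = max(1, int(round(mask.shape[0] * f)))
        ww = max(1, int(round(mask.shape[1] * f)))
        mask = resize(mask.astype(float), (hh, ww), order=0,
                      anti_aliasing=False, preserve_range=True) > 0.5
    x0 = int(round(offset[0] * f))
    y0 = int(round(offset[1] * f))
    out = np.zeros(out_shape, dtype=bool)
    y1 = min(y0 + mask.shape[0], out_shape[0])
    x1 = min(x0 + mask.shape[1], out_shape[1])
    if y1 > y0 and x1 > x0:
        out[y0:y1, x0:x1] = mask[: y1 - y0, : x1 - x0]
    return out


def build_patch_dataset(slides: dict[str, SlideImage],
                        annotation_table: pd.DataFrame,
                        line_cfg: LineConfig,
                        segmenter=None,
                        mask_loader=None) -> PatchDataset:
    """Construct the line's labeled patch dataset from slides + masks.

    ``mask_loader(mask_file) -> bool array`` resolves manifest mask
    files; rows with an empty ``mask_file`` are negative-slide
    sentinels. A manifest label outside the known vocabulary is an
    error; labels of other lines simply do not count as positive here.
    """
    unknown = set(annotation_table["label"].astype(str)) - ALL_KNOWN_LABELS
    unknown -= {"", "nan", "none"}
    if unknown:
        raise ValueError(f"unknown annotation labels {sorted(unknown)}")
    pos_labels = LINE_LABELS[line_cfg.lesion_line]

    images, rows = [], []
    for name, slide in slides.items():
        rescaled = rescale_to_mpp(slide, line_cfg.base_mpp)
        grid = tile(rescaled, line_cfg.patch_size)
        mask = segment_tissue(rescaled, segmenter)
        kept = filter_tissue_patches(grid, mask, line_cfg.min_tissue_fraction)

        lesion = np.zeros(rescaled.pixels.shape[:2], dtype=bool)
        ann = annotation_table[annotation_table["wsi_name"] == name]
        for _, row in ann.iterrows():
            if str(row["label"]) not in pos_labels:
                continue
            if not isinstance(row["mask_file"], str) or not row["mask_file"]:
                continue
            m = mask_loader(row["mask_file"])
            lesion |= _mask_on_grid(m, (int(row["x0"]), int(row["y0"])),
                                    float(row["scale"]), line_cfg.base_mpp,
                                    lesion.shape)

        p = line_cfg.patch_size
        area = float(p * p)
        for r, c in kept:
            x0, y0, x1, y1 = grid.window(r, c)
            ov = lesion[y0:min(y1, lesion.shape[0]),
                        x0:min(x1, lesion.shape[1])].sum() / area
            label = 1.0 if ov >= line_cfg.min_overlap_fraction else 0.0
            images.append(grid.extract(rescaled.pixels, r, c))
            rows.append({"wsi_name": name, "row": r, "col": c,
                         "label": label, "split": "train"})

    meta = pd.DataFrame(rows, columns=["wsi_name", "row", "col", "label",
                                       "split"])
    stack = (np.stack(images) if images
             else np.zeros((0, line_cfg.patch_size, line_cfg.patch_size, 3),
                           dtype=np.uint8))
    return PatchDataset(images=stack, meta=meta,
                        lesion_line=line_cfg.lesion_line,
                        patch_size=line_cfg.patch_size)


def split_by_wsi(dataset: PatchDataset, val_fraction: float,
                 seed: int) -> PatchDataset:
    """Partition WSIs (not patches) into train/validation splits.

    ``|val| = round(val_fraction * n_wsi)``; every patch inherits its
    WSI's split, so no slide contributes to both.
    """
    if not (0.0 < val_fraction < 1.0):
        raise ValueError("val_fraction must be in (0, 1)")
    wsis = sorted(dataset.meta["wsi_name"].unique())
    if len(wsis) < 2:
        raise ValueError("split_by_wsi requires at least 2 WSIs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(wsis))
    n_val = int(round(val_fraction * len(wsis)))
    val_set = {wsis[i] for i in order[:n_val]}
    dataset.meta["split"] = np.where(
        dataset.meta["wsi_name"].isin(val_set), "val", "train")
    return dataset


def apply_split(dataset: PatchDataset, val_wsis: set[str]) -> PatchDataset:
    """Impose an externally fixed validation WSI set (split preservation)."""
    dataset.meta["split"] = np.where(
        dataset.meta["wsi_name"].isin(val_wsis), "val", "train")
    return dataset


# -- augmentation ---------------------------------------------------------

#: Ruifrok-style H&E optical-density stain vectors (rows: H, E).
HE_STAIN_MATRIX = np.array([[0.650, 0.704, 0.286],
                            [0.072, 0.990, 0.105]])
HE_STAIN_MATRIX = HE_STAIN_MATRIX / np.linalg.norm(HE_STAIN_MATRIX, axis=1,
                                                   keepdims=True)


@dataclass
class AugmentConfig:
    p_blur: float = 0.1
    p_noise: float = 0.1
    p_flip: float = 0.5
    p_rot90: float = 0.5
    p_crop: float = 0.0
    p_affine: float = 0.0
    p_hsv: float = 0.1
    p_stain: float = 0.1
    mixup_alpha: float = 0.2

    @classmethod
    def off(cls) -> "AugmentConfig":
        return cls(p_blur=0, p_noise=0, p_flip=0, p_rot90=0, p_crop=0,
                   p_affine=0, p_hsv=0, p_stain=0)


def random_stain_mix(patch: np.ndarray, rng: np.random.Generator
                     ) -> np.ndarray:
    """Jitter the H&E stain channels of a patch in optical-density space."""
    img = np.clip(np.asarray(patch, dtype=np.float64), 0, 255)
    od = -np.log10((img + 1.0) / 256.0).reshape(-1, 3)
    weights, *_ = np.linalg.lstsq(HE_STAIN_MATRIX.T, od.T, rcond=None)
    weights = weights * rng.uniform(0.85, 1.15, size=(2, 1))
    od2 = (HE_STAIN_MATRIX.T @ weights).T.reshape(img.shape)
    out = 256.0 * np.power(10.0, -od2) - 1.0
    return np.clip(out, 0, 255)


def augment(patch: np.ndarray, label: float, rng: np.random.Generator,
            cfg: AugmentConfig | None = None) -> tuple[np.ndarray, float]:
    """Random composition of lossless/semantics-preserving manipulations.

    With all probabilities zero this is the identity. Mixup (the only
    label-changing augmentation) is a batch operation; see ``mixup``.
    """
    cfg = cfg or AugmentConfig()
    from scipy import ndimage
    x = patch
    if cfg.p_flip and rng.random() < cfg.p_flip:
        x = x[:, ::-1] if rng.random() < 0.5 else x[::-1, :]
    if cfg.p_rot90 and rng.random() < cfg.p_rot90:
        x = np.rot90(x, k=int(rng.integers(1, 4)))
    if cfg.p_blur and rng.random() < cfg.p_blur:
        x = ndimage.gaussian_filter(np.asarray(x, dtype=np.float64),
                                    sigma=(rng.uniform(0.4, 1.2),) * 2 + (0,))
    if cfg.p_noise and rng.random() < cfg.p_noise:
        x = np.asarray(x, dtype=np.float64) + \
            rng.normal(0, rng.uniform(2, 8), size=x.shape)
    if cfg.p_crop and rng.random() < cfg.p_crop:
        h, w = x.shape[:2]
        fr = rng.uniform(0.75, 0.95)
        ch, cw = max(4, int(h * fr)), max(4, int(w * fr))
        oy = int(rng.integers(0, h - ch + 1))
        ox = int(rng.integers(0, w - cw + 1))
        x = resize(np.asarray(x, dtype=np.float64)[oy:oy + ch, ox:ox + cw],
                   (h, w), order=1, anti_aliasing=False, preserve_range=True)
    if cfg.p_affine and rng.random() < cfg.p_affine:
        tf = AffineTransform(
            scale=rng.uniform(0.9, 1.1),
            shear=rng.uniform(-0.15, 0.15),
            translation=rng.uniform(-2, 2, size=2))
        x = warp(np.asarray(x, dtype=np.float64), tf.inverse, order=1,
                 mode="edge", preserve_range=True)
    if cfg.p_hsv and rng.random() < cfg.p_hsv:
        from skimage import color as skcolor
        hsv = skcolor.rgb2hsv(
            np.clip(np.asarray(x, dtype=np.float64), 0, 255).astype(np.uint8))
        hsv[:, :, 0] = (hsv[:, :, 0] + rng.uniform(-0.03, 0.03)) % 1.0
        hsv[:, :, 1] = np.clip(hsv[:, :, 1] * rng.uniform(0.9, 1.1), 0, 1)
        hsv[:, :, 2] = np.clip(hsv[:, :, 2] * rng.uniform(0.9, 1.1), 0, 1)
        x = skcolor.hsv2rgb(hsv) * 255.0
    if cfg.p_stain and rng.random() < cfg.p_stain:
        x = random_stain_mix(x, rng)
    if x is not patch:
        x = np.clip(x, 0, 255)
    return x, label


def mixup(x1: np.ndarray, y1: float, x2: np.ndarray, y2: float,
          lam: float) -> tuple[np.ndarray, float]:
    """Linear interpolation of data and labels: x' = lam*x1 + (1-lam)*x2."""
    x = lam * np.asarray(x1, dtype=np.float64) + \
        (1.0 - lam) * np.asarray(x2, dtype=np.float64)
    return x, lam * y1 + (1.0 - lam) * y2


def normalize_pixels(patch: np.ndarray) -> np.ndarray:
    """Scale 0-255 channel values to floats in [0, 1]."""
    return np.asarray(patch, dtype=np.float64) / 255.0


# -- classifier -----------------------------------------------------------


class PatchClassifier(BaseEstimator, ClassifierMixin):
    """Binary patch classifier on a pluggable convolutional backbone.

    The training loop is augment -> normalize -> parameter update, with
    a per-epoch validation pass (normalization only); the parameters
    with the best validation AUC are kept. Fitted attributes:
    ``model_``, ``history_``, ``val_auc_``, ``best_epoch_``.
    """

    def __init__(self, backbone: str = "tiny_cnn", width: int = 8,
                 epochs: int = 10, batch_size: int = 32, lr: float = 3e-3,
                 use_mixup: bool = True, augment_cfg: AugmentConfig | None = None,
                 random_state: int = 0):
        self.backbone = backbone
        self.width = width
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.use_mixup = use_mixup
        self.augment_cfg = augment_cfg
        self.random_state = random_state

    _init_state: dict | None = None  # optional warm start (ROI stage)

    @staticmethod
    def _to_nchw(images: np.ndarray) -> np.ndarray:
        return normalize_pixels(images).transpose(0, 3, 1, 2)

    def fit(self, images: np.ndarray, y: np.ndarray,
            splits: np.ndarray | None = None):
        y = np.asarray(y, dtype=np.float64)
        if splits is None:
            splits = np.full(len(y), "train", dtype=object)
        splits = np.asarray(splits)
        tr = np.flatnonzero(splits == "train")
        va = np.flatnonzero(splits == "val")
        if len(np.unique(np.round(y[tr]))) < 2:
            raise ValueError("training split must contain both classes")
        cfg = self.augment_cfg or AugmentConfig()
        rng = np.random.default_rng(self.random_state)
        self.model_ = make_backbone(self.backbone, rng, width=self.width,
                                    n_out=1)
        if self._init_state is not None:
            self.model_.load_state_dict(self._init_state)
        opt = Adam(self.model_.parameters(), lr=self.lr)
        sched = CosineAnnealing(opt, self.epochs)
        self.history_ = []

        def val_metrics():
            """(AUC, class-balanced BCE) on the validation split.

            The balanced loss weights both classes equally so the
            tie-break rewards confidence on the rare positive patches,
            not just the abundant negatives.
            """
            if not len(va):
                return np.nan, np.nan
            probs = self._forward_probs(images[va])
            yv = np.round(y[va]).astype(int)
            _, auc = roc_auc(probs, yv)
            eps = 1e-12
            losses_v = -(yv * np.log(probs + eps)
                         + (1 - yv) * np.log(1 - probs + eps))
            per_class = [losses_v[yv == c].mean()
                         for c in (0, 1) if (yv == c).any()]
            return auc, float(np.mean(per_class))

        def score_of(val_auc, val_bce, train_loss):
            # lexicographic: finite val AUC first, then val loss breaks
            # ties (confidence-aware); no usable validation -> train loss
            if len(va) and np.isfinite(val_auc):
                return (1, val_auc, -val_bce)
            if len(va) and np.isfinite(val_bce):
                return (0, -val_bce, 0.0)
            return (0, -train_loss, 0.0)

        best = (None, None, -1, np.nan)
        if self._init_state is not None:
            # a warm start competes as checkpoint candidate: fitting can
            # only keep or improve the validation metric, never regress it
            auc0, bce0 = val_metrics()
            best = (score_of(auc0, bce0, np.inf),
                    self.model_.state_dict(), -1, auc0)
        for epoch in range(self.epochs):
            rng.shuffle(tr)
            losses = []
            for start in range(0, len(tr), self.batch_size):
                b = tr[start:start + self.batch_size]
                bx, by = [], []
                for i in b:
                    xi, yi = augment(images[i], float(y[i]), rng, cfg)
                    bx.append(np.asarray(xi, dtype=np.float64))
                    by.append(yi)
                if self.use_mixup and cfg.mixup_alpha > 0 and len(bx) > 1:
                    lam = float(rng.beta(cfg.mixup_alpha, cfg.mixup_alpha))
                    j = rng.permutation(len(bx))
                    bx = [mixup(bx[i], by[i], bx[j[i]], by[j[i]], lam)[0]
                          for i in range(len(bx))]
                    by = [lam * by[i] + (1 - lam) * by[j[i]]
                          for i in range(len(by))]
                xb = np.stack([normalize_pixels(p) for p in bx]
                              ).transpose(0, 3, 1, 2)
                logits = self.model_.logits(Tensor(xb)).reshape(-1)
                loss = bce_with_logits(logits, np.asarray(by))
                self.model_.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            sched.step()
            val_auc, val_bce = val_metrics()
            self.history_.append({"epoch": epoch,
                                  "loss": float(np.mean(losses)),
                                  "val_auc": float(val_auc),
                                  "val_loss": float(val_bce)})
            score = score_of(val_auc, val_bce, float(np.mean(losses)))
            if best[0] is None or score > best[0]:
                best = (score, self.model_.state_dict(), epoch, val_auc)
        self.model_.load_state_dict(best[1])
        self.best_epoch_ = best[2]
        self.val_auc_ = float(best[3])
        return self

    def _forward_probs(self, images: np.ndarray,
                       batch: int = 256) -> np.ndarray:
        out = []
        for start in range(0, len(images), batch):
            x = self._to_nchw(images[start:start + batch])
            logits = self.model_.logits(Tensor(x)).data.reshape(-1)
            out.append(1.0 / (1.0 + np.exp(-logits)))
        return np.concatenate(out) if out else np.zeros(0)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        return self._forward_probs(np.asarray(images))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return (self.predict_proba(images) >= 0.5).astype(int)

    def embed(self, images: np.ndarray, batch: int = 256) -> np.ndarray:
        """Post-GAP, pre-head feature vectors (one row per image)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        out = []
        for start in range(0, len(images), batch):
            x = self._to_nchw(np.asarray(images[start:start + batch]))
            out.append(self.model_.features(Tensor(x)).data)
        return np.vstack(out)


# -- TTA + probability map ------------------------------------------------

def dihedral_variants(patch: np.ndarray) -> list[np.ndarray]:
    """The 8 dihedral transforms: 4 rotations x optional horizontal flip."""
    out = []
    for k in range(4):
        r = np.rot90(patch, k)
        out.append(r)
        out.append(r[:, ::-1])
    return out


def infer_patches_tta(model, patches: np.ndarray) -> np.ndarray:
    """Mean sigmoid prediction over the 8 dihedral variants of each patch.

    The variant set is closed under the dihedral group, and the 8
    predictions are sorted before averaging, so the TTA output of a
    transformed patch equals that of the original exactly.
    """
    patches = np.asarray(patches)
    n = len(patches)
    if n == 0:
        return np.zeros(0)
    variants = [np.stack(dihedral_variants(p)) for p in patches]
    flat = np.concatenate(variants)  # (8n, p, p, 3)
    probs = model.predict_proba(flat).reshape(n, 8)
    probs = np.sort(probs, axis=1)
    return probs.mean(axis=1)


@dataclass
class ProbabilityMap:
    """Per-patch lesion calls on the tiling grid."""

    raw: np.ndarray              # (n_rows, n_cols) float probabilities
    binary: np.ndarray           # raw > threshold, non-tissue forced 0
    tissue: np.ndarray           # bool grid of tissue cells
    lesion_line: str
    patch_size: int
    threshold: float
    slide_shape: tuple[int, int] = (0, 0)


def build_probmap(grid: PatchGrid, raw_probs: np.ndarray,
                  tissue_indices: list[tuple[int, int]],
                  threshold: float = 0.8,
                  lesion_line: str = "mel") -> ProbabilityMap:
    """Reconstruct the probability map; positive iff raw strictly > threshold."""
    raw = np.asarray(raw_probs, dtype=np.float64)
    if raw.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("raw probability raster does not match the grid")
    tissue = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    for r, c in tissue_indices:
        tissue[r, c] = True
    raw = np.where(tissue, raw, 0.0)
    return ProbabilityMap(raw=raw, binary=raw > threshold, tissue=tissue,
                          lesion_line=lesion_line, patch_size=grid.patch_size,
                          threshold=threshold,
                          slide_shape=(grid.slide_height, grid.slide_width))
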