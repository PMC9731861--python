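"""Per-section slide quality control.

Each tissue section receives a handful of tabular quality features
(variance of Laplacian for blur, scan coverage for incomplete scans,
grayscale moments, brightness, luminosity, saturation) and a label from
{ok, blurry, folding, artifact, incomplete} produced by a hybrid of a
random forest on the features and a small CNN on the section image. A
slide is flagged when strictly more than 25% of its sections are bad;
flagged slides are routed to manual review instead of the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from ._nn import (Adam, CosineAnnealing, Tensor, TinyCNN,
                  softmax_cross_entropy)
from .config import QC_FLAG_FRACTION

QC_CLASSES = ["ok", "blurry", "folding", "artifact", "incomplete"]
#: tie-break priority, highest first
_TIE_PRIORITY = {"incomplete": 4, "blurry": 3, "folding": 2, "artifact": 1,
                 "ok": 0}
_LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)


@dataclass
class QCFeatures:
    laplacian_variance: float
    scan_coverage: float
    mean_intensity: float
    std_intensity: float
    brightness: float
    luminosity: float
    saturation: float

    def as_array(self) -> np.ndarray:
        return np.array([self.laplacian_variance, self.scan_coverage,
                         self.mean_intensity, self.std_intensity,
                         self.brightness, self.luminosity, self.saturation])


def qc_features(image: np.ndarray, blank_threshold: int = 243) -> QCFeatures:
    """Quality features of one section image ((h, w, 3), values 0-255).

    ``scan_coverage`` is the fraction of the section bounding box whose
    pixels are non-blank (grayscale below ``blank_threshold``).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty section image")
    gray = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    lap = ndimage.convolve(gray, _LAPLACIAN_KERNEL, mode="nearest")
    hsv = skcolor.rgb2hsv(np.clip(img, 0, 255).astype(np.uint8))
    return QCFeatures(
        laplacian_variance=float(lap.var()),
        scan_coverage=float((gray < blank_threshold).mean()),
        mean_intensity=float(gray.mean()),
        std_intensity=float(gray.std()),
        brightness=float(img.max(axis=-1).mean() / 255.0),
        luminosity=float(gray.mean() / 255.0),
        saturation=float(hsv[:, :, 1].mean()),
    )


class HybridQCClassifier(BaseEstimator, ClassifierMixin):
    """Random forest on QC features + small CNN on the section image.

    The two components' per-class probabilities are fused by an
    unweighted mean; the argmax is the section label, with exact ties
    resolved by the priority incomplete > blurry > folding > artifact >
    ok.
    """

    def __init__(self, n_trees: int = 100, cnn_size: int = 32,
                 epochs: int = 6, batch_size: int = 32, lr: float = 3e-3,
                 random_state: int = 0):
        self.n_trees = n_trees
        self.cnn_size = cnn_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state

    def _cnn_input(self, image: np.ndarray) -> np.ndarray:
        small = resize(np.asarray(image, dtype=np.float64) / 255.0,
                       (self.cnn_size, self.cnn_size), order=1,
                       anti_aliasing=False, preserve_range=True)
        return small.transpose(2, 0, 1)

    def fit(self, images: list[np.ndarray], labels: list[str]):
        labels = list(labels)
        unknown = set(labels) - set(QC_CLASSES)
        if unknown:
            raise ValueError(f"unknown QC labels {unknown}")
        feats = np.stack([qc_features(im).as_array() for im in images])
        self.rf_ = RandomForestClassifier(n_estimators=self.n_trees,
                                          random_state=self.random_state)
        self.rf_.fit(feats, labels)
        y = np.array([QC_CLASSES.index(l) for l in labels])
        onehot = np.eye(len(QC_CLASSES))[y]
        x = np.stack([self._cnn_input(im) for im in images])
        rng = np.random.default_rng(self.random_state)
        self.cnn_ = TinyCNN(rng, width=8, n_out=len(QC_CLASSES))
        opt = Adam(self.cnn_.parameters(), lr=self.lr)
        sched = CosineAnnealing(opt, self.epochs)
        n = len(images)
        idx = np.arange(n)
        for _ in range(self.epochs):
            rng.shuffle(idx)
            for start in range(0, n, self.batch_size):
                b = idx[start:start + self.batch_size]
                logits = self.cnn_.logits(Tensor(x[b]))
                loss = softmax_cross_entropy(logits, onehot[b])
                self.cnn_.zero_grad()
                loss.backward()
                opt.step()
            sched.step()
        self.classes_ = list(QC_CLASSES)
        return self

    def _check_fitted(self):
        if not hasattr(self, "rf_"):
            raise RuntimeError("QC classifier is not fitted")

    def predict_proba_parts(self, image: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
        """(forest probabilities, CNN probabilities), both over QC_CLASSES."""
        self._check_fitted()
        feats = qc_features(image).as_array()[None]
        rf_p = np.zeros(len(QC_CLASSES))
        raw = self.rf_.predict_proba(feats)[0]
        for cls, p in zip(self.rf_.classes_, raw):
            rf_p[QC_CLASSES.index(cls)] = p
        logits = self.cnn_.logits(Tensor(self._cnn_input(image)[None])).data[0]
        z = logits - logits.max()
        cnn_p = np.exp(z) / np.exp(z).sum()
        return rf_p, cnn_p

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        rf_p, cnn_p = self.predict_proba_parts(image)
        return 0.5 * (rf_p + cnn_p)


def fuse_probabilities(tree_probs: dict[str, float],
                       cnn_probs: dict[str, float]) -> dict[str, float]:
    """Unweighted mean of the two components' per-class probabilities."""
    return {c: 0.5 * (tree_probs.get(c, 0.0) + cnn_probs.get(c, 0.0))
            for c in QC_CLASSES}


def argmax_label(probs: dict[str, float]) -> str:
    return max(QC_CLASSES, key=lambda c: (probs.get(c, 0.0), _TIE_PRIORITY[c]))


def classify_section(image: np.ndarray, model: HybridQCClassifier) -> str:
    fused = model.predict_proba(image)
    return argmax_label(dict(zip(QC_CLASSES, fused)))


@dataclass
class QCReport:
    section_labels: list[str]
    bad_fraction: float
    flagged: bool


def qc_slide(section_labels: list[str],
             flag_fraction: float = QC_FLAG_FRACTION) -> QCReport:
    """WSI-level flag rule: flagged iff bad fraction strictly > 25%."""
    if len(section_labels) == 0:
        raise ValueError("qc_slide requires at least one section")
    bad = sum(1 for l in section_labels if l != "ok")
    frac = bad / len(section_labels)
    return QCReport(section_labels=list(section_labels), bad_fraction=frac,
                    flagged=frac > flag_fraction)
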