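"""Tissue/background separation and per-section splitting.

Two segmenters satisfy the same contract (``predict(slide) -> bool
mask``): a deterministic baseline (HSV saturation threshold +
morphological closing + small-object removal) and a small trainable
encoder-decoder fitted on synthetic slide/mask pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage import morphology
from sklearn.base import BaseEstimator

from ._nn import Adam, CosineAnnealing, Tensor, TinyUNet, bce_with_logits
from .slide_io import PatchGrid, SlideImage


class BaselineTissueSegmenter(BaseEstimator):
    """Saturation-threshold segmenter; no fitting required."""

    def __init__(self, saturation_threshold: float = 0.08,
                 closing_radius: int = 2, min_object_px: int = 64):
        self.saturation_threshold = saturation_threshold
        self.closing_radius = closing_radius
        self.min_object_px = min_object_px

    def fit(self, X=None, y=None):
        return self

    def predict(self, slide: SlideImage) -> np.ndarray:
        hsv = skcolor.rgb2hsv(slide.pixels)
        mask = hsv[:, :, 1] >= self.saturation_threshold
        mask = morphology.closing(mask, morphology.disk(self.closing_radius))
        mask = morphology.remove_small_objects(
            mask, max_size=self.min_object_px - 1)
        return mask


class UNetTissueSegmenter(BaseEstimator):
    """Tiny trainable encoder-decoder for pixelwise tissue segmentation."""

    def __init__(self, width: int = 6, epochs: int = 5, lr: float = 5e-3,
                 n_restarts: int = 3, threshold: float = 0.5,
                 random_state: int = 0):
        self.width = width
        self.epochs = epochs
        self.lr = lr
        self.n_restarts = n_restarts
        self.threshold = threshold
        self.random_state = random_state

    @staticmethod
    def _prep(pixels: np.ndarray) -> np.ndarray:
        x = pixels.astype(np.float64) / 255.0
        h, w = x.shape[:2]
        ph, pw = h % 2, w % 2
        if ph or pw:
            x = np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="edge")
        return x.transpose(2, 0, 1)[None]

    def fit(self, slides: list[SlideImage], masks: list[np.ndarray]):
        """Fit with a few random restarts, keeping the lowest final
        training loss: the small net's 5-epoch convergence is
        init-sensitive."""
        best = (np.inf, None, None)
        for r in range(max(1, self.n_restarts)):
            rng = np.random.default_rng(self.random_state + 1000 * r)
            net = TinyUNet(rng, width=self.width)
            opt = Adam(net.parameters(), lr=self.lr)
            sched = CosineAnnealing(opt, self.epochs)
            order = np.arange(len(slides))
            history = []
            for _ in range(self.epochs):
                rng.shuffle(order)
                losses = []
                for i in order:
                    x = Tensor(self._prep(slides[i].pixels))
                    t = np.asarray(masks[i], dtype=np.float64)
                    h, w = t.shape
                    t = np.pad(t, ((0, h % 2), (0, w % 2)), mode="edge")
                    logits = net(x)
                    loss = bce_with_logits(logits.reshape(-1), t.reshape(-1))
                    net.zero_grad()
                    loss.backward()
                    opt.step()
                    losses.append(float(loss.data))
                sched.step()
                history.append(float(np.mean(losses)))
            if history[-1] < best[0]:
                best = (history[-1], net, history)
        self.net_ = best[1]
        self.history_ = best[2]
        # calibrate the decision threshold on the training pairs
        # (the raw sigmoid is biased at the 1-px boundary halo)
        grid = np.arange(0.3, 0.71, 0.05)
        scores = []
        for thr in grid:
            self.threshold_ = float(thr)
            js = []
            for s, m in zip(slides, masks):
                pred = self.predict(s)
                m = np.asarray(m, dtype=bool)
                union = (pred | m).sum()
                js.append((pred & m).sum() / union if union else 1.0)
            scores.append(np.mean(js))
        self.threshold_ = float(grid[int(np.argmax(scores))])
        return self

    def predict(self, slide: SlideImage) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("segmenter is not fitted")
        h, w = slide.pixels.shape[:2]
        logits = self.net_(Tensor(self._prep(slide.pixels))).data[0, 0]
        prob = 1.0 / (1.0 + np.exp(-logits[:h, :w]))
        thr = getattr(self, "threshold_", self.threshold)
        return prob > thr


def segment_tissue(slide: SlideImage, segmenter=None) -> np.ndarray:
    """Tissue mask at the rescaled slide's resolution."""
    if segmenter is None:
        segmenter = BaselineTissueSegmenter()
    mask = segmenter.predict(slide)
    if mask.shape != slide.pixels.shape[:2]:
        raise ValueError("segmenter returned a mask of the wrong shape")
    return mask.astype(bool)


@dataclass
class Section:
    """One connected tissue section."""

    mask: np.ndarray                    # full-slide bool raster
    bbox: tuple[int, int, int, int]     # (x0, y0, x1, y1), half-open
    area: int

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        x0, y0, x1, y1 = self.bbox
        return pixels[y0:y1, x0:x1]


def extract_sections(mask: np.ndarray, min_area: int = 64) -> list[Section]:
    """8-connected components of the tissue mask, one per section.

    Sorted by area descending; ties broken by top-left (row, column)
    lexicographic order of the component's first pixel. Components below
    ``min_area`` pixels are dropped as debris.
    """
    from scipy import ndimage
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sections = []
    for lab in range(1, n + 1):
        comp = labeled == lab
        area = int(comp.sum())
        if area < min_area:
            continue
        ys, xs = np.nonzero(comp)
        top = ys.min()
        left = xs[ys == top].min()
        sections.append((area, int(top), int(left), comp,
                         (int(xs.min()), int(ys.min()),
                          int(xs.max()) + 1, int(ys.max()) + 1)))
    sections.sort(key=lambda s: (-s[0], s[1], s[2]))
    return [Section(mask=comp, bbox=bbox, area=area)
            for area, _, _, comp, bbox in sections]


def filter_tissue_patches(grid: PatchGrid, mask: np.ndarray,
                          min_tissue_fraction: float = 0.1
                          ) -> list[tuple[int, int]]:
    """Grid cells whose tissue fraction is >= ``min_tissue_fraction``.

    The fraction is taken over the full (possibly padded) window area,
    so padded edge tiles are penalized by their out-of-slide part.
    """
    if mask.shape != (grid.slide_height, grid.slide_width):
        raise ValueError("mask and grid are not aligned")
    kept = []
    p = grid.patch_size
    area = float(p * p)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            x0, y0, x1, y1 = grid.window(r, c)
            sub = mask[y0:min(y1, grid.slide_height),
                       x0:min(x1, grid.slide_width)]
            if sub.sum() / area >= min_tissue_fraction:
                kept.append((r, c))
    return kept
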