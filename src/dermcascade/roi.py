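"""ROI stage: probability-map post-processing, top-N ROI selection, the
ROI classifier warm-started from the patch model, and GAP embeddings.

Connected positive components of the cleaned probability map are ranked
by positive-cell count (area) descending -- on a binary map area and
density coincide for solid components; a density ordering (cells per
bounding-box cell) is available behind ``order='density'``. The top N
components each yield one ROI window centered at the component
centroid; a slide with no surviving components falls back to one
uniformly random tissue-located ROI so every slide contributes at least
one instance to its MIL bag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .patches import PatchClassifier, ProbabilityMap

EIGHT_CONN = np.ones((3, 3), dtype=int)


def postprocess_probmap(pmap: ProbabilityMap,
                        min_component_patches: int = 3) -> ProbabilityMap:
    """Drop 8-connected positive components smaller than the minimum.

    Idempotent and anti-extensive: the output is a subset of the input.
    """
    labeled, n = ndimage.label(pmap.binary, structure=EIGHT_CONN)
    keep = np.zeros_like(pmap.binary)
    for lab in range(1, n + 1):
        comp = labeled == lab
        if comp.sum() >= min_component_patches:
            keep |= comp
    return ProbabilityMap(raw=pmap.raw, binary=keep, tissue=pmap.tissue,
                          lesion_line=pmap.lesion_line,
                          patch_size=pmap.patch_size,
                          threshold=pmap.threshold,
                          slide_shape=pmap.slide_shape)


@dataclass
class Roi:
    center: tuple[float, float]          # (x, y) on the rescaled slide
    window: tuple[int, int, int, int]    # (x0, y0, x1, y1), clipped
    source_region_id: int                # -1 for the random fallback
    label: int | None = None


def _component_order_key(comp_cells: np.ndarray, order: str):
    rows, cols = comp_cells
    count = len(rows)
    top = rows.min()
    left = cols[rows == top].min()
    if order == "density":
        bbox = (rows.max() - rows.min() + 1) * (cols.max() - cols.min() + 1)
        return (-count / bbox, int(top), int(left))
    return (-count, int(top), int(left))


def _clip_window(cx: float, cy: float, roi_size: int,
                 slide_shape: tuple[int, int]) -> tuple[int, int, int, int]:
    h, w = slide_shape
    x0 = int(round(cx - roi_size / 2))
    y0 = int(round(cy - roi_size / 2))
    x0 = max(0, min(x0, max(0, w - roi_size)))
    y0 = max(0, min(y0, max(0, h - roi_size)))
    return (x0, y0, min(x0 + roi_size, w), min(y0 + roi_size, h))


def select_rois(pmap: ProbabilityMap, n_top: int, roi_size: int,
                rng: np.random.Generator | None = None,
                order: str = "area") -> list[Roi]:
    """Top-N ROI windows from the cleaned probability map.

    Components are sorted by positive-cell count descending (ties by
    top-left lexicographic order); each contributes one ROI centered at
    its centroid, converted to pixel coordinates and clipped to the
    slide. An empty map yields exactly one random tissue-located ROI
    drawn from the run's seeded RNG.
    """
    p = pmap.patch_size
    labeled, n = ndimage.label(pmap.binary, structure=EIGHT_CONN)
    comps = []
    for lab in range(1, n + 1):
        cells = np.nonzero(labeled == lab)
        comps.append((lab, cells, _component_order_key(cells, order)))
    comps.sort(key=lambda t: t[2])

    rois: list[Roi] = []
    for lab, (rows, cols), _ in comps[:n_top]:
        cr, cc = rows.mean(), cols.mean()
        cx, cy = (cc + 0.5) * p, (cr + 0.5) * p
        rois.append(Roi(center=(float(cx), float(cy)),
                        window=_clip_window(cx, cy, roi_size,
                                            pmap.slide_shape),
                        source_region_id=int(lab)))
    if not rois:
        rng = rng or np.random.default_rng(0)
        tissue_cells = np.argwhere(pmap.tissue)
        if len(tissue_cells):
            r, c = tissue_cells[int(rng.integers(len(tissue_cells)))]
        else:
            r, c = pmap.binary.shape[0] // 2, pmap.binary.shape[1] // 2
        cx, cy = (c + 0.5) * p, (r + 0.5) * p
        rois.append(Roi(center=(float(cx), float(cy)),
                        window=_clip_window(cx, cy, roi_size,
                                            pmap.slide_shape),
                        source_region_id=-1))
    return rois


def assign_roi_labels(rois: list[Roi], wsi_label: int) -> list[Roi]:
    """Every ROI of a slide inherits the slide's binary line label."""
    for roi in rois:
        roi.label = int(wsi_label)
    return rois


def extract_roi_images(pixels: np.ndarray, rois: list[Roi],
                       roi_size: int) -> np.ndarray:
    """Pixel windows of the ROIs, white-padded to a uniform roi_size."""
    out = np.full((len(rois), roi_size, roi_size, 3), 255, dtype=pixels.dtype)
    for i, roi in enumerate(rois):
        x0, y0, x1, y1 = roi.window
        out[i, : y1 - y0, : x1 - x0] = pixels[y0:y1, x0:x1]
    return out


class RoiClassifier(PatchClassifier):
    """ROI-level binary classifier initialized from the patch model.

    The backbone's fully convolutional body + global pooling makes the
    input-size change from patch to ROI windows legal; all weights
    (body and head) start bitwise equal to the patch model's.
    """

    def init_from(self, patch_model: PatchClassifier) -> "RoiClassifier":
        if patch_model.backbone != self.backbone or \
                patch_model.width != self.width:
            raise ValueError("incompatible backbone for warm start")
        self._init_state = patch_model.model_.state_dict()
        return self


@dataclass
class EmbeddingBag:
    """One bag of ROI feature vectors per WSI."""

    wsi_name: str
    matrix: np.ndarray        # (n_rois, embedding_dim)
    wsi_label: int
    roi_centers: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValueError("an embedding bag needs at least one row")


def extract_embeddings(roi_model: PatchClassifier, roi_images: np.ndarray,
                       wsi_name: str, wsi_label: int,
                       rois: list[Roi] | None = None) -> EmbeddingBag:
    """Post-GAP, pre-head activations of the ROI model, one row per ROI."""
    emb = roi_model.embed(np.asarray(roi_images))
    centers = [r.center for r in rois] if rois else []
    return EmbeddingBag(wsi_name=wsi_name, matrix=emb,
                        wsi_label=int(wsi_label), roi_centers=centers)
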