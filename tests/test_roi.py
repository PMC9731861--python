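"""Probability-map post-processing, ROI selection, warm start, embeddings."""

import numpy as np
import pytest
from scipy import ndimage

from dermcascade.patches import PatchClassifier, ProbabilityMap
from dermcascade.roi import (EmbeddingBag, RoiClassifier, assign_roi_labels,
                             extract_embeddings, extract_roi_images,
                             postprocess_probmap, select_rois)


def pmap_from(binary, patch=16, tissue=None):
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape[0] * patch, binary.shape[1] * patch
    return ProbabilityMap(raw=binary.astype(float), binary=binary,
                          tissue=(np.ones_like(binary) if tissue is None
                                  else np.asarray(tissue, dtype=bool)),
                          lesion_line="mel", patch_size=patch, threshold=0.8,
                          slide_shape=(h, w))


def test_postprocess_empty_map_stays_empty():
    pmap = pmap_from(np.zeros((5, 5)))
    assert not postprocess_probmap(pmap).binary.any()


def test_postprocess_removes_small_and_keeps_large_components():
    binary = np.zeros((6, 6), dtype=bool)
    binary[0, 0] = True                        # isolated cell: removed
    binary[3, 1:6] = True                      # 5-cell blob: survives
    out = postprocess_probmap(pmap_from(binary), min_component_patches=3)
    assert not out.binary[0, 0]
    assert out.binary[3, 1:6].all()


def test_postprocess_idempotent_and_anti_extensive(rng):
    for _ in range(20):
        pmap = pmap_from(rng.random((12, 12)) < 0.3)
        once = postprocess_probmap(pmap)
        twice = postprocess_probmap(once)
        assert np.array_equal(once.binary, twice.binary)
        assert not (once.binary & ~pmap.binary).any()


def test_select_rois_takes_largest_components_first():
    binary = np.zeros((8, 8), dtype=bool)
    binary[0, 0:2] = True                      # 2 cells
    binary[3, 0:4] = True                      # 4 cells
    binary[6, 0:3] = True                      # 3 cells
    rois = select_rois(pmap_from(binary), n_top=2, roi_size=32)
    assert len(rois) == 2
    assert rois[0].center[1] == pytest.approx((3 + 0.5) * 16)
    assert rois[1].center[1] == pytest.approx((6 + 0.5) * 16)


def test_empty_map_falls_back_to_one_random_tissue_roi(rng):
    tissue = np.zeros((6, 6), dtype=bool)
    tissue[2, 3] = True
    pmap = pmap_from(np.zeros((6, 6)), tissue=tissue)
    rois = select_rois(pmap, n_top=5, roi_size=32, rng=rng)
    assert len(rois) == 1
    assert rois[0].source_region_id == -1
    assert rois[0].center == ((3 + 0.5) * 16, (2 + 0.5) * 16)


def test_roi_center_is_component_centroid_in_pixels():
    binary = np.zeros((8, 8), dtype=bool)
    binary[2, 2] = binary[2, 3] = binary[3, 2] = binary[3, 3] = True
    rois = select_rois(pmap_from(binary), n_top=1, roi_size=32)
    assert rois[0].center == ((2.5 + 0.5) * 16, (2.5 + 0.5) * 16)
    x0, y0, x1, y1 = rois[0].window
    assert (x1 - x0, y1 - y0) == (32, 32)


def test_roi_window_clipped_inside_slide():
    binary = np.zeros((4, 4), dtype=bool)
    binary[0, 0] = binary[0, 1] = binary[1, 0] = True
    rois = select_rois(pmap_from(binary), n_top=1, roi_size=48)
    x0, y0, x1, y1 = rois[0].window
    assert x0 >= 0 and y0 >= 0 and x1 <= 64 and y1 <= 64


def test_n_top_is_a_prefix_ordering(rng):
    for _ in range(10):
        pmap = pmap_from(rng.random((10, 10)) < 0.25)
        seed = int(rng.integers(1 << 30))
        rois = {n: select_rois(pmap, n, 32,
                               rng=np.random.default_rng(seed))
                for n in (1, 2, 3, 4)}
        for n in (1, 2, 3):
            prefix = [r.center for r in rois[n]]
            longer = [r.center for r in rois[n + 1]][:len(prefix)]
            assert prefix == longer


def test_component_ordering_matches_brute_force_oracle(rng):
    """Area-descending, ties top-left: agrees with a flood-fill oracle."""
    for _ in range(30):
        binary = rng.random((20, 20)) < 0.2
        pmap = pmap_from(binary)
        rois = select_rois(pmap, n_top=100, roi_size=16)
        labeled, n = ndimage.label(binary, np.ones((3, 3), int))
        comps = []
        for lab in range(1, n + 1):
            rows, cols = np.nonzero(labeled == lab)
            top = rows.min()
            left = cols[rows == top].min()
            comps.append((-len(rows), top, left,
                          ((cols.mean() + 0.5) * 16, (rows.mean() + 0.5) * 16)))
        comps.sort()
        if n == 0:
            assert len(rois) == 1 and rois[0].source_region_id == -1
        else:
            assert [r.center for r in rois] == [c[3] for c in comps]


def test_assign_roi_labels_propagates_wsi_label():
    rois = select_rois(pmap_from(np.ones((3, 3))), 1, 16)
    assert all(r.label == 1 for r in assign_roi_labels(rois, 1))
    assert all(r.label == 0 for r in assign_roi_labels(rois, 0))


def test_roi_images_are_padded_to_uniform_size(rng):
    pixels = rng.integers(0, 255, size=(48, 48, 3)).astype(np.uint8)
    binary = np.zeros((3, 3), dtype=bool)
    binary[2, 2] = True
    rois = select_rois(pmap_from(binary, patch=16), 1, 32)
    imgs = extract_roi_images(pixels, rois, 32)
    assert imgs.shape == (1, 32, 32, 3)
    x0, y0, x1, y1 = rois[0].window
    assert np.array_equal(imgs[0], pixels[y0:y1, x0:x1])


def fitted_patch_classifier(rng, n=60):
    X = np.zeros((n, 16, 16, 3), dtype=np.uint8)
    y = np.tile([0.0, 1.0], n // 2)
    for i in range(n):
        base = [170, 60, 60] if y[i] else [80, 80, 170]
        X[i] = np.clip(np.array(base) + rng.normal(0, 15, (16, 16, 3)),
                       0, 255).astype(np.uint8)
    clf = PatchClassifier(epochs=4, random_state=0)
    clf.fit(X, y)
    return clf, X, y


def test_warm_start_copies_body_weights_bitwise(rng):
    patch_clf, X, y = fitted_patch_classifier(rng)
    roi_clf = RoiClassifier(epochs=1, random_state=7).init_from(patch_clf)
    # instantiate the backbone without any update steps
    from dermcascade._nn import make_backbone
    probe = make_backbone(roi_clf.backbone, np.random.default_rng(0),
                          width=roi_clf.width, n_out=1)
    probe.load_state_dict(roi_clf._init_state)
    for k, v in patch_clf.model_.body_state().items():
        assert np.array_equal(probe.state_dict()[k], v)


def test_warm_start_rejects_incompatible_backbones(rng):
    patch_clf, _, _ = fitted_patch_classifier(rng)
    with pytest.raises(ValueError):
        RoiClassifier(backbone="se_cnn").init_from(patch_clf)


def test_roi_classifier_learns_from_warm_start(rng):
    patch_clf, _, _ = fitted_patch_classifier(rng)
    n = 40
    X = np.zeros((n, 48, 48, 3), dtype=np.uint8)
    y = np.tile([0.0, 1.0], n // 2)
    for i in range(n):
        base = [170, 60, 60] if y[i] else [80, 80, 170]
        X[i] = np.clip(np.array(base) + rng.normal(0, 15, (48, 48, 3)),
                       0, 255).astype(np.uint8)
    splits = np.array(["train"] * 30 + ["val"] * 10)
    roi_clf = RoiClassifier(epochs=6, random_state=1).init_from(patch_clf)
    roi_clf.fit(X, y, splits)
    assert roi_clf.val_auc_ >= 0.9


def test_embedding_bags_shape_and_determinism(rng):
    patch_clf, X, y = fitted_patch_classifier(rng)
    imgs = np.stack([X[0], X[1], X[0]])
    bag = extract_embeddings(patch_clf, imgs, "w1", 1)
    assert bag.matrix.shape == (3, patch_clf.model_.feature_dim)
    assert np.array_equal(bag.matrix[0], bag.matrix[2])  # duplicate rows
    with pytest.raises(ValueError):
        EmbeddingBag("w", np.zeros((0, 4)), 0)
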