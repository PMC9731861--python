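"""Patch dataset construction, augmentation, training, TTA, probmaps."""

import numpy as np
import pandas as pd
import pytest

from dermcascade import patches as P
from dermcascade.config import desk_line_config
from dermcascade.slide_io import SlideImage, tile
from dermcascade.metrics import roc_auc


def make_slide(h=64, w=64, value=200):
    px = np.full((h, w, 3), value, dtype=np.uint8)
    px[:, :, 0] = 230  # slightly pink so the tissue segmenter keeps it
    return SlideImage(px, mpp=1.0, name="w1")


class FullTissueSegmenter:
    def predict(self, slide):
        return np.ones(slide.pixels.shape[:2], dtype=bool)


def build_ds(mask_map, table_rows, cfg=None, slide=None):
    cfg = cfg or desk_line_config("mel")
    slide = slide or make_slide()
    table = pd.DataFrame(table_rows, columns=["wsi_name", "mask_file",
                                              "label", "x0", "y0", "scale"])
    return P.build_patch_dataset({"w1": slide}, table, cfg,
                                 segmenter=FullTissueSegmenter(),
                                 mask_loader=lambda f: mask_map[f])


def test_slide_without_masks_is_all_negative():
    ds = build_ds({}, [])
    assert len(ds.meta) == 16
    assert (ds.meta["label"] == 0.0).all()


def test_mask_covering_one_patch_marks_exactly_that_patch():
    mask = np.ones((16, 16), dtype=bool)
    rows = [{"wsi_name": "w1", "mask_file": "m.png", "label": "mel",
             "x0": 16, "y0": 32, "scale": 1.0}]
    ds = build_ds({"m.png": mask}, rows)
    pos = ds.meta[ds.meta["label"] == 1.0]
    assert [(r, c) for r, c in zip(pos["row"], pos["col"])] == [(2, 1)]


def test_overlap_fraction_against_threshold():
    mask = np.ones((16, 7), dtype=bool)       # covers ~44% of patch (0,0)
    rows = [{"wsi_name": "w1", "mask_file": "m.png", "label": "mel",
             "x0": 0, "y0": 0, "scale": 1.0}]
    ds = build_ds({"m.png": mask}, rows)
    assert ds.meta.iloc[0]["label"] == 0.0    # 44% < default 50%
    cfg = desk_line_config("mel")
    cfg.min_overlap_fraction = 0.25
    ds = build_ds({"m.png": mask}, rows, cfg=cfg)
    assert ds.meta.iloc[0]["label"] == 1.0


def test_other_line_labels_count_negative_but_unknown_labels_error():
    mask = np.ones((16, 16), dtype=bool)
    rows = [{"wsi_name": "w1", "mask_file": "m.png", "label": "bcc",
             "x0": 0, "y0": 0, "scale": 1.0}]
    ds = build_ds({"m.png": mask}, rows)      # bcc mask in a mel dataset
    assert (ds.meta["label"] == 0.0).all()
    rows[0]["label"] = "weird"
    with pytest.raises(ValueError):
        build_ds({"m.png": mask}, rows)


def make_meta_ds(n_wsi=100, per=3):
    meta = pd.DataFrame({
        "wsi_name": [f"w{i}" for i in range(n_wsi) for _ in range(per)],
        "row": 0, "col": 0, "label": 0.0, "split": "train"})
    return P.PatchDataset(images=np.zeros((n_wsi * per, 8, 8, 3),
                                          dtype=np.uint8),
                          meta=meta, lesion_line="mel", patch_size=8)


def test_split_by_wsi_counts_and_leakage():
    ds = P.split_by_wsi(make_meta_ds(), 0.2, seed=3)
    val_wsis = set(ds.meta.loc[ds.meta["split"] == "val", "wsi_name"])
    assert len(val_wsis) == 20
    by_wsi = ds.meta.groupby("wsi_name")["split"].nunique()
    assert (by_wsi == 1).all()


def test_split_by_wsi_is_deterministic_and_validated():
    a = P.split_by_wsi(make_meta_ds(), 0.2, seed=5).meta["split"].tolist()
    b = P.split_by_wsi(make_meta_ds(), 0.2, seed=5).meta["split"].tolist()
    assert a == b
    with pytest.raises(ValueError):
        P.split_by_wsi(make_meta_ds(), 1.5, seed=0)
    with pytest.raises(ValueError):
        P.split_by_wsi(make_meta_ds(n_wsi=1), 0.2, seed=0)


def test_augment_all_probabilities_zero_is_identity(rng):
    patch = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
    out, label = P.augment(patch, 1.0, rng, P.AugmentConfig.off())
    assert out is patch
    assert label == 1.0


def test_augment_keeps_pixels_in_valid_range(rng):
    cfg = P.AugmentConfig(p_blur=1, p_noise=1, p_flip=1, p_rot90=1,
                          p_crop=1, p_affine=1, p_hsv=1, p_stain=1)
    patch = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
    for _ in range(10):
        out, _ = P.augment(patch, 0.0, rng, cfg)
        assert out.min() >= 0 and out.max() <= 255


def test_mixup_interpolates_data_and_labels():
    x1 = np.full((4, 4, 3), 100.0)
    x2 = np.zeros((4, 4, 3))
    x, y = P.mixup(x1, 1.0, x2, 0.0, lam=0.7)
    assert y == pytest.approx(0.7)
    assert x[0, 0, 0] == pytest.approx(70.0)


def test_stain_mix_preserves_shape_and_range(rng):
    patch = rng.integers(0, 256, size=(12, 12, 3)).astype(np.uint8)
    out = P.random_stain_mix(patch, rng)
    assert out.shape == patch.shape
    assert out.min() >= 0 and out.max() <= 255


@pytest.mark.parametrize("value,expected",
                         [(255, 1.0), (0, 0.0), (128, 128 / 255)])
def test_normalize_pixels(value, expected):
    out = P.normalize_pixels(np.full((2, 2, 3), value, dtype=np.uint8))
    assert out[0, 0, 0] == pytest.approx(expected)


def separable_patches(rng, n=160, size=16):
    """Two color/texture families a tiny CNN separates quickly."""
    X = np.zeros((n, size, size, 3), dtype=np.uint8)
    y = np.zeros(n)
    for i in range(n):
        if i % 2:
            base = np.array([170, 60, 60])
            y[i] = 1.0
        else:
            base = np.array([80, 80, 170])
        X[i] = np.clip(base + rng.normal(0, 20, size=(size, size, 3)),
                       0, 255).astype(np.uint8)
    return X, y


def test_patch_classifier_learns_separable_textures(rng):
    X, y = separable_patches(rng)
    splits = np.array(["train"] * 120 + ["val"] * 40)
    clf = P.PatchClassifier(epochs=10, random_state=0)
    clf.fit(X, y, splits)
    assert clf.val_auc_ >= 0.95


def test_training_requires_both_classes(rng):
    X, y = separable_patches(rng, n=20)
    with pytest.raises(ValueError):
        P.PatchClassifier(epochs=1).fit(X, np.zeros(20))


def test_validation_pass_applies_normalization_only(rng, monkeypatch):
    """Augmentation must never touch validation samples."""
    X, y = separable_patches(rng, n=40)
    splits = np.array(["train"] * 30 + ["val"] * 10)
    seen = []
    original = P.augment

    def spy(patch, label, rng_, cfg=None):
        seen.append(patch.tobytes())
        return original(patch, label, rng_, cfg)

    monkeypatch.setattr(P, "augment", spy)
    P.PatchClassifier(epochs=2, random_state=0).fit(X, y, splits)
    val_bytes = {X[i].tobytes() for i in range(30, 40)}
    assert val_bytes.isdisjoint(seen)


def test_bce_loss_near_zero_on_confident_correct_predictions():
    from dermcascade._nn import Tensor, bce_with_logits
    logits = Tensor(np.array([20.0, -20.0]))
    assert float(bce_with_logits(logits, np.array([1.0, 0.0])).data) < 1e-6


class StubModel:
    """Records inputs; emits a fixed or content-dependent probability."""

    def __init__(self, prob=0.3):
        self.prob = prob
        self.calls = 0

    def predict_proba(self, images):
        self.calls += 1
        return np.full(len(images), self.prob)


def test_tta_constant_model_passes_through(rng):
    patches_in = rng.integers(0, 256, size=(3, 8, 8, 3)).astype(np.uint8)
    out = P.infer_patches_tta(StubModel(0.3), patches_in)
    assert np.allclose(out, 0.3)


def test_tta_on_symmetric_patch_equals_single_prediction(rng):
    sym = np.full((8, 8, 3), 120, dtype=np.uint8)

    class ContentModel:
        def predict_proba(self, images):
            return np.array([im.astype(float).mean() / 255 for im in images])

    out = P.infer_patches_tta(ContentModel(), sym[None])
    assert out[0] == pytest.approx(120 / 255)


def test_tta_exactly_invariant_under_dihedral_transforms(rng):
    class ContentModel:
        def predict_proba(self, images):
            # deliberately orientation-sensitive scoring
            return np.array([im[:4, :4].astype(float).sum() % 97 / 97
                             for im in images])

    model = ContentModel()
    patch = rng.integers(0, 256, size=(8, 8, 3)).astype(np.uint8)
    base = P.infer_patches_tta(model, patch[None])[0]
    for variant in P.dihedral_variants(patch):
        assert P.infer_patches_tta(model, variant[None])[0] == base


def test_probmap_strict_threshold_boundary():
    slide = make_slide(32, 32)
    grid = tile(slide, 16)
    tissue = [(0, 0), (0, 1), (1, 0), (1, 1)]
    raw = np.array([[0.80, 0.81], [0.0, 0.9]])
    pmap = P.build_probmap(grid, raw, tissue, threshold=0.8)
    assert not pmap.binary[0, 0]              # 0.80 is NOT > 0.8
    assert pmap.binary[0, 1]
    assert pmap.binary[1, 1]


def test_probmap_forces_non_tissue_to_zero_and_checks_shape():
    slide = make_slide(32, 32)
    grid = tile(slide, 16)
    raw = np.full((2, 2), 0.99)
    pmap = P.build_probmap(grid, raw, [(0, 0)], threshold=0.8)
    assert pmap.binary.sum() == 1 and pmap.raw[1, 1] == 0.0
    with pytest.raises(ValueError):
        P.build_probmap(grid, np.zeros((3, 3)), [], threshold=0.8)


def test_probmap_binarization_matches_elementwise_oracle(rng):
    slide = make_slide(128, 128)
    grid = tile(slide, 16)
    cells = [(r, c) for r in range(8) for c in range(8)]
    for _ in range(25):
        raw = rng.random((8, 8))
        keep = [rc for rc in cells if rng.random() < 0.8]
        pmap = P.build_probmap(grid, raw, keep, threshold=0.8)
        oracle = np.zeros((8, 8), dtype=bool)
        for r, c in keep:
            oracle[r, c] = raw[r, c] > 0.8
        assert np.array_equal(pmap.binary, oracle)
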