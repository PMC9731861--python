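"""Pseudo-label assignment, mask auto-generation, merging, review."""

import numpy as np
import pandas as pd
import pytest

from dermcascade.patches import ProbabilityMap
from dermcascade.slide_io import read_annotation_table
from dermcascade.ssl import (SSLLabel, apply_review, assign_ssl_label,
                             generate_ssl_masks, merge_datasets)


@pytest.mark.parametrize("pred,gt,outcome,provenance", [
    (True, True, "positive", "TP"),
    (False, False, "negative", "TN"),
    (True, False, "negative", "FP"),
    (False, True, "excluded", "FN"),
])
def test_ssl_label_truth_table(pred, gt, outcome, provenance):
    lab = assign_ssl_label(pred, gt, "bcc", "w1")
    assert (lab.outcome, lab.provenance) == (outcome, provenance)
    assert lab.flagged_for_review == (provenance == "FN")


def make_pmap(binary, raw=None, patch=16):
    binary = np.asarray(binary, dtype=bool)
    raw = binary.astype(float) * 0.95 if raw is None else np.asarray(raw)
    return ProbabilityMap(raw=raw, binary=binary,
                          tissue=np.ones_like(binary), lesion_line="bcc",
                          patch_size=patch, threshold=0.8,
                          slide_shape=(binary.shape[0] * patch,
                                       binary.shape[1] * patch))


def test_negative_label_yields_empty_mask_sentinel(tmp_path):
    lab = SSLLabel("w1", "bcc", "negative", "TN")
    df = generate_ssl_masks(make_pmap(np.zeros((4, 4))), lab, 1.0,
                            tmp_path, map_mpp=1.0)
    assert len(df) == 1
    assert df.iloc[0]["mask_file"] == ""
    assert list(tmp_path.glob("*.png")) == []


def test_two_surviving_components_give_two_files_and_rows(tmp_path):
    binary = np.zeros((8, 8), dtype=bool)
    binary[0, 0:3] = True
    binary[5, 2:6] = True
    lab = SSLLabel("w1", "bcc", "positive", "TP")
    df = generate_ssl_masks(make_pmap(binary), lab, 1.0, tmp_path,
                            map_mpp=1.0)
    assert len(df) == 2
    assert len(list(tmp_path.glob("*.png"))) == 2
    assert (df["label"] == "bcc").all()
    assert df.iloc[0]["x0"] == 0 and df.iloc[0]["y0"] == 0
    assert df.iloc[1]["x0"] == 2 * 16 and df.iloc[1]["y0"] == 5 * 16


def test_low_confidence_and_small_components_are_dropped(tmp_path):
    binary = np.zeros((8, 8), dtype=bool)
    binary[0, 0:4] = True                       # large but low confidence
    binary[4, 0] = True                         # too small
    raw = binary.astype(float) * 0.85
    lab = SSLLabel("w1", "bcc", "positive", "TP")
    df = generate_ssl_masks(make_pmap(binary, raw), lab, 1.0, tmp_path,
                            map_mpp=1.0)
    assert len(df) == 1 and df.iloc[0]["mask_file"] == ""  # sentinel


def test_excluded_label_is_an_error(tmp_path):
    lab = SSLLabel("w1", "bcc", "excluded", "FN")
    with pytest.raises(ValueError):
        generate_ssl_masks(make_pmap(np.zeros((2, 2))), lab, 1.0, tmp_path,
                           map_mpp=1.0)


def test_generated_masks_feed_back_into_patch_training(tmp_path):
    """Format closure: SSL annotations are readable by the patch stage."""
    from dermcascade.config import desk_line_config
    from dermcascade.patches import build_patch_dataset
    from dermcascade.slide_io import SlideImage, load_mask, \
        write_annotation_table

    binary = np.zeros((4, 4), dtype=bool)
    binary[1, 0:3] = True
    lab = SSLLabel("w1", "bcc", "positive", "TP")
    df = generate_ssl_masks(make_pmap(binary), lab, 1.0, tmp_path,
                            map_mpp=1.0)
    write_annotation_table(df, tmp_path / "ssl.csv")
    table = read_annotation_table(tmp_path / "ssl.csv")
    pixels = np.full((64, 64, 3), 200, dtype=np.uint8)
    pixels[:, :, 0] = 230

    class FullSegmenter:
        def predict(self, slide):
            return np.ones(slide.pixels.shape[:2], dtype=bool)

    ds = build_patch_dataset({"w1": SlideImage(pixels, 1.0, "w1")}, table,
                             desk_line_config("bcc"),
                             segmenter=FullSegmenter(),
                             mask_loader=lambda f: load_mask(tmp_path / f))
    pos = {(r, c) for r, c in zip(ds.meta.loc[ds.meta.label == 1, "row"],
                                  ds.meta.loc[ds.meta.label == 1, "col"])}
    assert pos == {(1, 0), (1, 1), (1, 2)}


def test_mask_generation_idempotent_on_its_own_output(tmp_path):
    """Re-running on a map equal to the cleaned output changes nothing."""
    binary = np.zeros((6, 6), dtype=bool)
    binary[2, 1:5] = True
    lab = SSLLabel("w1", "bcc", "positive", "TP")
    df1 = generate_ssl_masks(make_pmap(binary), lab, 1.0, tmp_path / "a",
                             map_mpp=1.0)
    df2 = generate_ssl_masks(make_pmap(binary), lab, 1.0, tmp_path / "b",
                             map_mpp=1.0)
    assert df1.drop(columns=["mask_file"]).equals(
        df2.drop(columns=["mask_file"]))


def test_review_keeps_agree_drops_disagree_warns_pending(caplog):
    labels = [SSLLabel(w, "mel", "positive", "TP") for w in "abc"]
    table = pd.DataFrame({"wsi_name": ["a", "b"],
                          "verdict": ["agree", "disagree"]})
    import logging
    with caplog.at_level(logging.WARNING, logger="dermcascade.ssl"):
        kept = apply_review(labels, table)
    assert [l.wsi_name for l in kept] == ["a"]
    assert labels[1].reviewer_agreement == "disagree"
    assert any("no reviewer verdict" in m for m in caplog.messages)


def test_merge_ordered_split_of_weak_cases():
    sup = {"s1": "train", "s2": "val"}
    weak = [(f"w{i}", i) for i in range(1, 11)]
    merged = merge_datasets(sup, weak)
    weak_rows = merged[merged["source"] == "weak"].set_index("wsi_name")
    assert (weak_rows.loc[[f"w{i}" for i in range(1, 9)],
                          "split"] == "train").all()
    assert (weak_rows.loc[["w9", "w10"], "split"] == "val").all()
    sup_rows = merged[merged["source"] == "supervised"].set_index("wsi_name")
    assert sup_rows.loc["s2", "split"] == "val"      # supervised preserved


def test_merge_split_order_independent_of_input_order():
    sup = {}
    weak = [("w3", 3), ("w1", 1), ("w5", 5), ("w2", 2), ("w4", 4)]
    merged = merge_datasets(sup, weak).set_index("wsi_name")
    assert merged.loc["w5", "split"] == "val"        # last by case_id
    assert (merged.loc[["w1", "w2", "w3", "w4"], "split"] == "train").all()


def test_merge_rejects_duplicates_and_has_no_leakage():
    with pytest.raises(ValueError):
        merge_datasets({"x": "train"}, [("x", 1)])
    merged = merge_datasets({"a": "train", "b": "val"},
                            [(f"w{i}", i) for i in range(5)])
    assert merged["wsi_name"].is_unique
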