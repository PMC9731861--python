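"""Severity ladders, ROI expansion, the subtype cascade."""

import numpy as np
import pandas as pd
import pytest

from dermcascade.patches import ProbabilityMap
from dermcascade.roi import Roi
from dermcascade.study import run_subtype_study
from dermcascade.subtype import (SeverityLadder, build_subtype_dataset,
                                 expand_roi_to_lesion, subtype_cascade)


def pmap_from(binary, patch=16):
    binary = np.asarray(binary, dtype=bool)
    return ProbabilityMap(raw=binary.astype(float), binary=binary,
                          tissue=np.ones_like(binary), lesion_line="asl",
                          patch_size=patch, threshold=0.8,
                          slide_shape=(binary.shape[0] * patch,
                                       binary.shape[1] * patch))


def roi_at(r, c, patch=16, size=32):
    cx, cy = (c + 0.5) * patch, (r + 0.5) * patch
    return Roi(center=(cx, cy), window=(int(cx - size / 2),
                                        int(cy - size / 2),
                                        int(cx + size / 2),
                                        int(cy + size / 2)),
               source_region_id=1)


def test_ladder_orders_and_validates():
    lad = SeverityLadder("asl")
    assert lad.subtypes == ["scc_invasive", "sccis", "ak"]
    assert lad.severity_index("scc_invasive") == 0
    with pytest.raises(ValueError):
        SeverityLadder("mel", ["benign_nevi", "benign_nevi"])


def test_expand_single_cell_component_pads_one_patch():
    binary = np.zeros((8, 8), dtype=bool)
    binary[3, 3] = True
    win = expand_roi_to_lesion(roi_at(3, 3), pmap_from(binary))
    # cell (48..64) padded by one 16-px patch per side
    assert win == (32, 32, 80, 80)


def test_expand_component_spanning_whole_map_gives_whole_slide():
    binary = np.ones((4, 4), dtype=bool)
    win = expand_roi_to_lesion(roi_at(0, 0), pmap_from(binary))
    assert win == (0, 0, 64, 64)


def test_expand_off_component_returns_original_window():
    binary = np.zeros((8, 8), dtype=bool)
    binary[0, 0] = True
    roi = roi_at(5, 5)
    assert expand_roi_to_lesion(roi, pmap_from(binary)) == roi.window


def test_supervised_subtype_labels_and_conflict_rule(caplog):
    lad = SeverityLadder("asl")
    records = [
        {"roi_id": "r1", "wsi_name": "w1", "supervised": True,
         "mask_subtypes": ["sccis"]},
        {"roi_id": "r2", "wsi_name": "w1", "supervised": True,
         "mask_subtypes": ["ak", "scc_invasive"]},   # conflict
        {"roi_id": "r3", "wsi_name": "w2", "supervised": True,
         "mask_subtypes": []},                       # no mask: excluded
    ]
    import logging
    with caplog.at_level(logging.INFO, logger="dermcascade.subtype"):
        df = build_subtype_dataset(records, lad)
    assert dict(zip(df["roi_id"], df["subtype"])) == {
        "r1": "sccis", "r2": "scc_invasive"}         # most severe wins
    assert any("conflicting" in m for m in caplog.messages)


def test_weak_rois_labeled_from_reviewer_table(caplog):
    lad = SeverityLadder("bcc")
    records = [
        {"roi_id": "r1", "wsi_name": "w1", "supervised": False},
        {"roi_id": "r2", "wsi_name": "w1", "supervised": False},
    ]
    review = pd.DataFrame({"roi_id": ["r1"], "subtype": ["nodular"]})
    import logging
    with caplog.at_level(logging.INFO, logger="dermcascade.subtype"):
        df = build_subtype_dataset(records, lad, review)
    assert list(df["roi_id"]) == ["r1"]              # r2 excluded, logged
    assert any("lacks a reviewer label" in m for m in caplog.messages)


class Stub:
    def __init__(self, score):
        self.score = score
        self.calls = 0

    def __call__(self, images):
        self.calls += 1
        return np.full(len(images), self.score)


def test_cascade_stops_at_most_severe_hit_for_asl():
    lad = SeverityLadder("asl")
    stubs = {"scc_invasive": Stub(0.9), "sccis": Stub(0.9), "ak": Stub(0.9)}
    result = subtype_cascade(np.zeros((2, 8, 8, 3)), lad, stubs)
    assert result.label == "scc_invasive"
    assert stubs["scc_invasive"].calls == 1
    assert stubs["sccis"].calls == 0                 # never consulted
    assert stubs["ak"].calls == 0


def test_cascade_all_below_threshold_is_inconclusive():
    lad = SeverityLadder("mel")
    stubs = {s: Stub(0.0) for s in lad.subtypes}
    result = subtype_cascade(np.zeros((1, 8, 8, 3)), lad, stubs)
    assert result.label == "inconclusive"
    assert all(s.calls == 1 for s in stubs.values())


def test_bcc_reports_mixed_when_two_rungs_fire():
    lad = SeverityLadder("bcc")
    stubs = {"infiltrative": Stub(0.8), "nodular": Stub(0.7),
             "superficial": Stub(0.1)}
    result = subtype_cascade(np.zeros((1, 8, 8, 3)), lad, stubs)
    assert result.label == "mixed"
    assert all(s.calls == 1 for s in stubs.values())  # bcc tests all rungs


def test_bcc_single_rung_is_plain_subtype():
    lad = SeverityLadder("bcc")
    stubs = {"infiltrative": Stub(0.2), "nodular": Stub(0.9),
             "superficial": Stub(0.3)}
    assert subtype_cascade(np.zeros((1, 8, 8, 3)), lad, stubs).label == \
        "nodular"


def test_cascade_threshold_is_strict_and_needs_rois():
    lad = SeverityLadder("mel")
    stubs = {s: Stub(0.5) for s in lad.subtypes}
    result = subtype_cascade(np.zeros((1, 8, 8, 3)), lad, stubs,
                             roi_threshold=0.5)
    assert result.label == "inconclusive"            # 0.5 is not > 0.5
    with pytest.raises(ValueError):
        subtype_cascade(np.zeros((0, 8, 8, 3)), lad, stubs)


def test_cascade_is_deterministic_given_fixed_scores():
    lad = SeverityLadder("asl")
    scores = {"scc_invasive": 0.2, "sccis": 0.9, "ak": 0.95}
    out = [subtype_cascade(np.zeros((3, 8, 8, 3)), lad,
                           {k: Stub(v) for k, v in scores.items()}).label
           for _ in range(3)]
    assert out == ["sccis"] * 3


@pytest.mark.parametrize("line", ["asl", "bcc"])
def test_subtype_classifiers_separate_the_ladder(line):
    """One-vs-rest tiny classifiers reach val AUC >= 0.9 per rung."""
    result = run_subtype_study(line, seed=21)
    for subtype, auc in result["val_auc"].items():
        assert auc >= 0.9, (line, subtype)
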