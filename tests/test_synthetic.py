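"""The slide generator: determinism, truth consistency, export format."""

import numpy as np
import pandas as pd
import pytest

from dermcascade.config import LESION_LINES
from dermcascade.slide_io import load_mask, read_annotation_table
from dermcascade.synthetic import (SectionSpec, SlideSpec, class_motif,
                                   export_annotations, generate_balanced_cohort,
                                   generate_cohort, generate_slide,
                                   render_texture)


def test_zero_sections_yields_background_only():
    slide, truth = generate_slide(SlideSpec(n_sections=0, seed=1))
    assert not truth.tissue_mask.any()
    assert truth.regions == []
    assert (slide.pixels > 230).all()


def test_same_spec_same_seed_is_bitwise_identical():
    spec = dict(n_sections=2, ink_band=True, defects=[("blur", 0)], seed=42,
                lesion_classes=[SectionSpec("bcc", "nodular"), SectionSpec()])
    s1, t1 = generate_slide(SlideSpec(**spec))
    s2, t2 = generate_slide(SlideSpec(**spec))
    assert np.array_equal(s1.pixels, s2.pixels)
    assert np.array_equal(t1.tissue_mask, t2.tissue_mask)
    assert np.array_equal(t1.ink_mask, t2.ink_mask)


def test_lesion_mask_area_matches_disk_area():
    r = 20
    spec = SlideSpec(n_sections=1, section_size=96, seed=3,
                     lesion_classes=[SectionSpec(
                         "bcc", "nodular", lesion_radius=r,
                         lesion_offset=(0, 0))])
    _, truth = generate_slide(spec)
    area = truth.regions[0].mask.sum()
    assert abs(area - np.pi * r * r) / (np.pi * r * r) < 0.05


def test_invalid_specs_are_rejected():
    with pytest.raises(ValueError):
        SlideSpec(n_sections=-1)
    with pytest.raises(ValueError):
        SlideSpec(n_sections=1, mpp=0.0)
    with pytest.raises(ValueError):
        SlideSpec(n_sections=1, defects=[("blur", 5)])
    with pytest.raises(ValueError):
        SectionSpec("mel", "nodular")  # subtype of another line


def test_lesions_stay_inside_their_section():
    for seed in range(5):
        spec = SlideSpec(n_sections=2, seed=seed,
                         lesion_classes=[SectionSpec("mel", "benign_nevi"),
                                         SectionSpec("vv")])
        _, truth = generate_slide(spec)
        for reg in truth.regions:
            x0, y0 = reg.offset
            sec = truth.section_masks[reg.section_index]
            sub = sec[y0:y0 + reg.mask.shape[0], x0:x0 + reg.mask.shape[1]]
            assert (sub | ~reg.mask).all()


def test_wsi_labels_follow_the_positivity_rule():
    spec = SlideSpec(n_sections=3, seed=9,
                     lesion_classes=[SectionSpec("asl", "ak"), SectionSpec(),
                                     SectionSpec("asl", "sccis")])
    _, truth = generate_slide(spec)
    assert truth.wsi_labels == {"mel": False, "bcc": False, "asl": True,
                                "sk": False, "vv": False}


def test_export_writes_one_mask_and_row_per_region(tmp_path):
    spec = SlideSpec(n_sections=3, seed=5, name="wsi_a",
                     lesion_classes=[SectionSpec("mel", "benign_nevi"),
                                     SectionSpec("mel", "severely_atypical"),
                                     SectionSpec("sk")])
    _, truth = generate_slide(spec)
    df = export_annotations(truth, tmp_path)
    assert len(df) == 3
    assert len(list(tmp_path.glob("*.png"))) == 3
    reread = read_annotation_table(tmp_path / "annotations.csv")
    assert list(reread["label"]) == ["benign_nevi", "severely_atypical", "sk"]


def test_export_round_trip_reproduces_masks_and_offsets(tmp_path):
    spec = SlideSpec(n_sections=1, seed=6, name="wsi_b",
                     lesion_classes=[SectionSpec("vv", lesion_offset=(4, -3))])
    _, truth = generate_slide(spec)
    df = export_annotations(truth, tmp_path)
    reg = truth.regions[0]
    row = df.iloc[0]
    assert (int(row["x0"]), int(row["y0"])) == reg.offset
    assert np.array_equal(load_mask(tmp_path / row["mask_file"]), reg.mask)


def test_cohort_mixture_and_case_ids():
    entries = generate_cohort(10, {"mel": 1.0}, seed=2)
    assert all(e.lesion_class == "mel" for e in entries)
    assert all(e.truth.wsi_labels["mel"] for e in entries)
    ids = [e.case_id for e in entries]
    assert ids == sorted(ids) and len(set(ids)) == len(ids)
    with pytest.raises(ValueError):
        generate_cohort(5, {"mel": 0.7}, seed=0)


def test_cohort_class_counts_within_binomial_interval():
    from scipy import stats
    entries = generate_cohort(100, {"mel": 0.5, "none": 0.5}, seed=8,
                              section_size=48)
    k = sum(e.lesion_class == "mel" for e in entries)
    lo, hi = stats.binom.ppf([0.005, 0.995], 100, 0.5)
    assert lo <= k <= hi


def test_balanced_cohort_has_exact_counts():
    entries = generate_balanced_cohort(3, LESION_LINES, seed=4,
                                       section_size=48)
    counts = {l: sum(e.lesion_class == l for e in entries)
              for l in LESION_LINES}
    assert counts == {l: 3 for l in LESION_LINES}
    assert [e.case_id for e in entries] == list(range(1, 16))


def test_difficulty_knob_shrinks_texture_separation():
    """Mean pairwise histogram distance decreases as difficulty rises."""
    rng_seed = 12
    def mean_pairwise_distance(difficulty):
        rng = np.random.default_rng(rng_seed)
        hists = []
        for cls in LESION_LINES:
            color, sigma, amp = class_motif(cls, difficulty=difficulty)
            tex = np.clip(render_texture((48, 48), color, sigma, amp, rng),
                          0, 255)
            h = np.concatenate([np.histogram(tex[:, :, c], bins=16,
                                             range=(0, 255))[0]
                                for c in range(3)]).astype(float)
            hists.append(h / h.sum())
        dists = [np.abs(hists[i] - hists[j]).sum()
                 for i in range(5) for j in range(i + 1, 5)]
        return np.mean(dists)

    d = [mean_pairwise_distance(x) for x in (0.0, 0.5, 1.0)]
    assert d[0] > d[1] > d[2]


def test_ink_band_is_green_and_below_section_center():
    spec = SlideSpec(n_sections=1, section_size=96, ink_band=True, seed=13)
    slide, truth = generate_slide(spec)
    assert truth.ink_mask.sum() > 0
    from skimage import color as skcolor
    hsv = skcolor.rgb2hsv(slide.pixels)
    hues = hsv[:, :, 0][truth.ink_mask] * 360
    assert (hues >= 90).all() and (hues <= 165).all()
    ys = np.nonzero(truth.ink_mask)[0]
    cy = np.nonzero(truth.section_masks[0])[0].mean()
    assert (ys > cy).all()


def test_defect_labels_recorded_per_section():
    spec = SlideSpec(n_sections=2, seed=14,
                     defects=[("fold", 0), ("incomplete", 1)])
    _, truth = generate_slide(spec)
    assert truth.defect_labels == ["folding", "incomplete"]
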