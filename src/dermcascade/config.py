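"""Lesion-line vocabulary, severity ladders, and per-line hyperparameters.

Five lesion lines are detected, each by its own binary cascade:

* ``mel`` -- melanocytic lesions
* ``bcc`` -- basal cell carcinoma
* ``asl`` -- atypical squamous lesions (invasive SCC, SCC in-situ, AK)
* ``sk``  -- seborrheic keratosis
* ``vv``  -- verruca vulgaris

Production defaults follow the published patch-level hyperparameters
(250 epochs, batch 64, 20% WSI-level validation split, 128 px patches at
0.547619 MPP for mel/bcc/asl and 256 px at 2.1905 MPP for sk/vv; ROI
windows of 1024 px and 512 px respectively). ``desk_line_config``
returns a scaled-down configuration used for the synthetic end-to-end
study and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

LESION_LINES = ["mel", "bcc", "asl", "sk", "vv"]

#: Severity ladders, most severe first. BCC additionally derives the
#: label ``mixed`` when at least two subtype rungs fire.
SEVERITY_LADDERS: dict[str, list[str]] = {
    "mel": ["severely_atypical", "mildly_atypical", "benign_nevi"],
    "asl": ["scc_invasive", "sccis", "ak"],
    "bcc": ["infiltrative", "nodular", "superficial"],
}

#: Mask-label vocabulary per line: the line name itself or any of its
#: subtype labels counts toward that line.
LINE_LABELS: dict[str, set[str]] = {
    line: {line} | set(SEVERITY_LADDERS.get(line, []))
    for line in LESION_LINES
}

ALL_KNOWN_LABELS = set().union(*LINE_LABELS.values()) | {"other"}

#: (line, subtype) pairs for which margin status is reported. Margin
#: status applies to all melanocytic and all BCC subtypes, and to ASL
#: subtypes invasive SCC and SCCIS; never to AK, SK, or VV.
def margin_applicable(line: str, subtype: str | None) -> bool:
    if line in ("mel", "bcc"):
        return True
    if line == "asl":
        return subtype in ("scc_invasive", "sccis", "mixed")
    return False


@dataclass
class LineConfig:
    """Hyperparameters of one lesion line's patch/ROI/WSI cascade."""

    lesion_line: str
    patch_size: int = 128
    base_mpp: float = 0.547619
    epochs: int = 250
    batch_size: int = 64
    val_fraction: float = 0.2
    positive_threshold: float = 0.8
    min_overlap_fraction: float = 0.5
    roi_size: int = 1024
    roi_epochs: int = 250
    roi_batch_size: int = 2
    n_top: int = 10
    min_component_patches: int = 3
    roi_order: str = "area"          # or "density"
    wsi_threshold: float = 0.5
    backbone: str = "se_cnn"
    min_tissue_fraction: float = 0.1
    lr: float = 8e-3
    #: reduced rate for warm-started training (ROI stage, fine-tuning);
    #: full-rate updates collapse an already-converged small ReLU net
    warm_lr: float = 2e-3

    def __post_init__(self):
        if self.lesion_line not in LESION_LINES:
            raise ValueError(f"unknown lesion line {self.lesion_line!r}")
        if not (0.0 < self.positive_threshold < 1.0):
            raise ValueError("positive_threshold must be in (0, 1)")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")


def default_line_config(line: str) -> LineConfig:
    """Published per-line defaults (Mel/BCC/ASL vs SK/VV scale split)."""
    if line in ("mel", "bcc", "asl"):
        return LineConfig(lesion_line=line, patch_size=128, base_mpp=0.547619,
                          roi_size=1024)
    return LineConfig(lesion_line=line, patch_size=256, base_mpp=2.1905,
                      roi_size=512)


def desk_line_config(line: str, *, patch_size: int = 16, base_mpp: float = 1.0,
                     epochs: int = 30, roi_epochs: int = 8,
                     roi_size: int = 48, n_top: int = 4,
                     backbone: str = "tiny_cnn") -> LineConfig:
    """Scaled-down configuration for synthetic desk-scale experiments."""
    return LineConfig(
        lesion_line=line, patch_size=patch_size, base_mpp=base_mpp,
        epochs=epochs, batch_size=32, roi_epochs=roi_epochs,
        roi_batch_size=4, roi_size=roi_size, n_top=n_top, backbone=backbone,
        # desk-scale lesions span only ~10 grid cells, so the speck
        # cleanup scales down with them (production default stays 3)
        min_component_patches=2,
    )


def save_line_configs(configs: dict[str, LineConfig], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: asdict(v) for k, v in configs.items()}, fh)


def load_line_configs(path: str | Path) -> dict[str, LineConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: LineConfig(**v) for k, v in raw.items()}


#: Fraction of bad sections above which a slide is QC-flagged (strict >).
QC_FLAG_FRACTION = 0.25
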