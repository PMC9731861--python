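"""Seeded generator of toy multi-section H&E-like slides with ground truth.

Every downstream stage of the cascade is testable without clinical data:
slides are pale-background rasters carrying elliptical tissue sections;
each lesion class renders a visually distinct color/spatial-frequency
texture motif; an optional saturated-green band along each section's
non-epidermal edge emulates the tissue marking dye used for margin
detection; and four QC defect kinds (blur, fold, artifact, incomplete
scan) can be stamped onto individual sections.

The generator is deterministic given its seed (bitwise), and the
slide-level ground-truth label for a lesion line is positive iff some
section carries a lesion of that line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import LESION_LINES, SEVERITY_LADDERS
from .slide_io import SlideImage, save_mask, write_annotation_table

DEFECT_KINDS = ("blur", "fold", "artifact", "incomplete")
#: defect kind -> QC section label
DEFECT_TO_QC_LABEL = {"blur": "blurry", "fold": "folding",
                      "artifact": "artifact", "incomplete": "incomplete"}

#: Base texture motifs: class -> (RGB color, noise correlation sigma).
#: Each class pairs a distinct hue with a spatial-frequency band so that
#: small CNNs can separate them quickly.
_MOTIFS: dict[str, tuple[tuple[int, int, int], float]] = {
    "tissue": ((232, 193, 205), 1.2),
    "mel": ((115, 78, 52), 2.5),
    "bcc": ((95, 85, 170), 1.5),
    "asl": ((205, 62, 95), 0.8),
    "sk": ((180, 140, 45), 0.5),
    "vv": ((150, 70, 155), 2.2),
    "other": ((130, 130, 130), 1.0),
}
_TEXTURE_AMP = 25.0
_TISSUE_AMP = 12.0
#: Saturated green matching a green tissue marking dye (hue ~ 120 deg).
INK_COLOR = (30, 200, 60)


def class_motif(lesion_class: str, subtype: str | None = None,
                difficulty: float = 0.0) -> tuple[np.ndarray, float, float]:
    """(color, sigma, amplitude) of a class texture.

    ``difficulty`` in [0, 1] blends every motif toward the common tissue
    motif, monotonically shrinking inter-class texture distance.
    """
    color, sigma = _MOTIFS[lesion_class]
    color = np.asarray(color, dtype=float)
    amp = _TEXTURE_AMP if lesion_class != "tissue" else _TISSUE_AMP
    if subtype is not None:
        ladder = SEVERITY_LADDERS.get(lesion_class, [])
        if subtype not in ladder:
            raise ValueError(f"unknown subtype {subtype!r} for {lesion_class}")
        i = ladder.index(subtype)
        # mild color shift keeps subtype motifs inside the line's hue
        # family; the frequency band separates the rungs more strongly
        # but stays bounded so no rung degenerates to a flat color at
        # patch scale
        color = color + (i - 1) * np.array([15.0, -10.0, 12.0])
        sigma = sigma * (0.5, 1.0, 2.0)[i]
    d = float(np.clip(difficulty, 0.0, 1.0))
    tissue_color = np.asarray(_MOTIFS["tissue"][0], dtype=float)
    color = (1 - d) * color + d * tissue_color
    sigma = (1 - d) * sigma + d * _MOTIFS["tissue"][1]
    amp = (1 - d) * amp + d * _TISSUE_AMP
    return np.clip(color, 0, 255), sigma, amp


def render_texture(shape: tuple[int, int], color: np.ndarray, sigma: float,
                   amp: float, rng: np.random.Generator) -> np.ndarray:
    """Filtered-noise texture patch of the given motif, float (H,W,3)."""
    noise = rng.normal(size=shape)
    noise = ndimage.gaussian_filter(noise, sigma)
    s = noise.std()
    if s > 0:
        noise = noise / s
    return color[None, None, :] + amp * noise[:, :, None]


@dataclass
class SectionSpec:
    """One tissue section: its lesion class ('none' for lesion-free)."""

    lesion_class: str = "none"
    subtype: str | None = None
    lesion_radius: int | None = None
    #: (dy, dx) displacement of the lesion from the section center;
    #: when given, placement jitter is disabled (controlled geometry).
    lesion_offset: tuple[int, int] | None = None

    def __post_init__(self):
        valid = set(LESION_LINES) | {"other", "none"}
        if self.lesion_class not in valid:
            raise ValueError(f"unknown lesion class {self.lesion_class!r}")
        if self.subtype is not None:
            ladder = SEVERITY_LADDERS.get(self.lesion_class, [])
            if self.subtype not in ladder:
                raise ValueError(
                    f"subtype {self.subtype!r} invalid for {self.lesion_class}")


@dataclass
class SlideSpec:
    """Recipe for one synthetic slide."""

    n_sections: int
    section_size: int = 96
    lesion_classes: list[SectionSpec] | None = None
    ink_band: bool = False
    defects: list[tuple[str, int]] = field(default_factory=list)
    mpp: float = 1.0
    seed: int = 0
    difficulty: float = 0.0
    excision: bool = False
    name: str = "synthetic"

    def __post_init__(self):
        if self.n_sections < 0:
            raise ValueError("n_sections must be >= 0")
        if not (self.mpp > 0):
            raise ValueError("mpp must be positive")
        if self.lesion_classes is None:
            self.lesion_classes = [SectionSpec() for _ in range(self.n_sections)]
        if len(self.lesion_classes) != self.n_sections:
            raise ValueError("lesion_classes must have one entry per section")
        for kind, idx in self.defects:
            if kind not in DEFECT_KINDS:
                raise ValueError(f"unknown defect kind {kind!r}")
            if not (0 <= idx < self.n_sections):
                raise ValueError("defect section index out of range")


@dataclass
class LesionRegion:
    """A single lesion blob with its placement record."""

    section_index: int
    lesion_class: str
    subtype: str | None
    mask: np.ndarray            # local bool raster
    offset: tuple[int, int]     # (x0, y0) of the local raster on the slide


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated slide."""

    tissue_mask: np.ndarray
    section_masks: list[np.ndarray]
    regions: list[LesionRegion]
    ink_mask: np.ndarray
    defect_labels: list[str]
    wsi_labels: dict[str, bool]
    excision: bool
    mpp: float
    name: str


def _ellipse_mask(shape, cy, cx, ry, rx) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _section_mask(shape, cy, cx, ry, rx, rng) -> np.ndarray:
    """Elliptical tissue section (smooth boundary)."""
    del rng
    return _ellipse_mask(shape, cy, cx, ry, rx)


def generate_slide(spec: SlideSpec) -> tuple[SlideImage, SyntheticTruth]:
    """Render a slide and its ground truth; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    margin = 16
    size = spec.section_size
    n = spec.n_sections
    if n == 0:
        h = w = 4 * margin
    else:
        cols = int(np.ceil(np.sqrt(n)))
        rows = int(np.ceil(n / cols))
        cell = size + 2 * margin
        w = cols * cell
        h = rows * cell
    # pale background
    img = 246.0 + rng.normal(0, 2.0, size=(h, w, 3))

    tissue_mask = np.zeros((h, w), dtype=bool)
    section_masks: list[np.ndarray] = []
    regions: list[LesionRegion] = []
    ink_mask = np.zeros((h, w), dtype=bool)
    defect_labels = ["ok"] * n

    t_color, t_sigma, t_amp = class_motif("tissue", difficulty=spec.difficulty)

    for i in range(n):
        cols = int(np.ceil(np.sqrt(n)))
        cell = size + 2 * margin
        r, c = divmod(i, cols)
        cy = r * cell + cell // 2
        cx = c * cell + cell // 2
        ry = size / 2 * rng.uniform(0.80, 0.95)
        rx = size / 2 * rng.uniform(0.88, 1.0)
        smask = _section_mask((h, w), cy, cx, ry, rx, rng)
        section_masks.append(smask)
        tissue_mask |= smask
        tex = render_texture((h, w), t_color, t_sigma, t_amp, rng)
        img[smask] = tex[smask]

        sec = spec.lesion_classes[i]
        if sec.lesion_class != "none":
            # default blob spans ~10 patch-grid cells at desk scale,
            # matching how many cells a real lesion would cover
            rad = sec.lesion_radius or max(6, int(round(0.3 * size)))
            if sec.lesion_offset is not None:
                ly = cy + int(sec.lesion_offset[0])
                lx = cx + int(sec.lesion_offset[1])
            else:
                # placement varies enough that some lesions reach the
                # section edge (margin-positive specimens exist)
                jit = size // 8
                ly = cy + int(rng.integers(-jit, jit + 1))
                lx = cx + int(rng.integers(-jit, jit + 1))
            lmask = _ellipse_mask((h, w), ly, lx, rad, rad) & smask
            color, sigma, amp = class_motif(sec.lesion_class, sec.subtype,
                                            spec.difficulty)
            ltex = render_texture((h, w), color, sigma, amp, rng)
            img[lmask] = ltex[lmask]
            ys, xs = np.nonzero(lmask)
            y0, y1 = ys.min(), ys.max() + 1
            x0, x1 = xs.min(), xs.max() + 1
            regions.append(LesionRegion(
                section_index=i, lesion_class=sec.lesion_class,
                subtype=sec.subtype, mask=lmask[y0:y1, x0:x1].copy(),
                offset=(int(x0), int(y0))))

        if spec.ink_band:
            band = max(3, size // 8)
            dist = ndimage.distance_transform_edt(smask)
            yy = np.arange(h)[:, None]
            strip = smask & (dist <= band) & (yy > cy)
            ink_mask |= strip
            # dye tints rather than replaces the tissue: green blend
            # keeps the underlying texture partly visible at the edge
            alpha = 0.5
            img[strip] = (alpha * np.asarray(INK_COLOR, dtype=float)[None, :]
                          + (1 - alpha) * img[strip]
                          + rng.normal(0, 4.0, size=(int(strip.sum()), 3)))

    # QC defects: one label per section (first defect wins)
    for kind, idx in spec.defects:
        smask = section_masks[idx]
        ys, xs = np.nonzero(smask)
        y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
        if kind == "blur":
            img[y0:y1, x0:x1] = ndimage.gaussian_filter(
                img[y0:y1, x0:x1], sigma=(3.0, 3.0, 0))
        elif kind == "fold":
            cy_ = (y0 + y1) // 2
            half = max(3, (y1 - y0) // 8)
            strip = np.zeros((h, w), dtype=bool)
            strip[cy_ - half:cy_ + half, x0:x1] = True
            strip &= smask
            img[strip] *= 0.45
        elif kind == "artifact":
            cy_, cx_ = (y0 + y1) // 2, (x0 + x1) // 2
            rad = max(4, (y1 - y0) // 5)
            blotch = _ellipse_mask((h, w), cy_, cx_, rad, rad)
            img[blotch] = (250.0, 20.0, 230.0)  # saturated magenta blotch
        elif kind == "incomplete":
            # blank scan stripe kept interior so the section stays one
            # component and its bounding-box coverage drops
            xa = x0 + int(0.50 * (x1 - x0))
            xb = x0 + int(0.92 * (x1 - x0))
            ya = y0 + int(0.18 * (y1 - y0))
            yb = y0 + int(0.82 * (y1 - y0))
            img[ya:yb, xa:xb] = 255.0
        if defect_labels[idx] == "ok":
            defect_labels[idx] = DEFECT_TO_QC_LABEL[kind]

    wsi_labels = {line: any(reg.lesion_class == line for reg in regions)
                  for line in LESION_LINES}
    slide = SlideImage(np.clip(np.round(img), 0, 255).astype(np.uint8),
                       mpp=spec.mpp, name=spec.name)
    truth = SyntheticTruth(
        tissue_mask=tissue_mask, section_masks=section_masks, regions=regions,
        ink_mask=ink_mask, defect_labels=defect_labels, wsi_labels=wsi_labels,
        excision=spec.excision, mpp=spec.mpp, name=spec.name)
    return slide, truth


def export_annotations(truth: SyntheticTruth, out_dir: str | Path,
                       csv_name: str = "annotations.csv") -> pd.DataFrame:
    """Write one binary mask PNG per lesion region plus a CSV manifest.

    The manifest row schema matches the supervised annotation convention:
    ``wsi_name, mask_file, label, x0, y0, scale`` with 0-based offsets.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, reg in enumerate(truth.regions):
        fname = f"{truth.name}_region{k}.png"
        save_mask(reg.mask, out_dir / fname)
        rows.append({
            "wsi_name": truth.name,
            "mask_file": fname,
            "label": reg.subtype if reg.subtype is not None else reg.lesion_class,
            "x0": reg.offset[0],
            "y0": reg.offset[1],
            "scale": truth.mpp,
        })
    df = pd.DataFrame(rows, columns=["wsi_name", "mask_file", "label",
                                     "x0", "y0", "scale"])
    write_annotation_table(df, out_dir / csv_name)
    return df


def generate_balanced_cohort(n_per_class: int, classes: list[str], seed: int,
                             **kwargs) -> list["CohortEntry"]:
    """Exactly ``n_per_class`` slides of each class, in shuffled order.

    Accepts the same slide-level keyword arguments as
    ``generate_cohort``; case_ids remain strictly increasing in
    generation order.
    """
    rng = np.random.default_rng(seed)
    schedule = [c for c in classes for _ in range(n_per_class)]
    rng.shuffle(schedule)
    entries: list[CohortEntry] = []
    for case_id, cls in enumerate(schedule, start=1):
        sub = generate_cohort(1, {cls: 1.0}, int(rng.integers(2 ** 31)),
                              **kwargs)[0]
        sub.case_id = case_id
        name = f"case_{case_id:04d}"
        sub.wsi_name = name
        sub.spec.name = name
        sub.slide.name = name
        sub.truth.name = name
        entries.append(sub)
    return entries


@dataclass
class CohortEntry:
    case_id: int
    wsi_name: str
    lesion_class: str            # line, 'other', or 'none'
    subtype: str | None
    spec: SlideSpec
    slide: SlideImage
    truth: SyntheticTruth


def generate_cohort(n_slides: int, class_mix: dict[str, float], seed: int,
                    *, n_sections: int = 2, section_size: int = 96,
                    ink_band: bool = False, difficulty: float = 0.0,
                    excision_fraction: float = 0.0,
                    mpp: float = 1.0) -> list[CohortEntry]:
    """Generate a manifest of slides with case_id in generation order.

    ``class_mix`` maps each class (a lesion line, 'other', or 'none') to
    its mixture proportion; proportions must sum to 1. Positive slides
    carry one lesion section with a subtype drawn uniformly from the
    line's severity ladder (where the line has one).
    """
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("class mixture proportions must sum to 1")
    rng = np.random.default_rng(seed)
    classes = sorted(class_mix)
    probs = np.array([class_mix[c] for c in classes])
    entries: list[CohortEntry] = []
    for case_id in range(1, n_slides + 1):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        subtype = None
        sections = [SectionSpec() for _ in range(n_sections)]
        if cls not in ("none",):
            ladder = SEVERITY_LADDERS.get(cls, [])
            if ladder:
                subtype = ladder[int(rng.integers(len(ladder)))]
            lesion_at = int(rng.integers(n_sections)) if n_sections else 0
            sections[lesion_at] = SectionSpec(lesion_class=cls, subtype=subtype)
        name = f"case_{case_id:04d}"
        spec = SlideSpec(
            n_sections=n_sections, section_size=section_size,
            lesion_classes=sections, ink_band=ink_band,
            mpp=mpp, seed=int(rng.integers(2 ** 31)), difficulty=difficulty,
            excision=bool(rng.random() < excision_fraction), name=name)
        slide, truth = generate_slide(spec)
        entries.append(CohortEntry(case_id=case_id, wsi_name=name,
                                   lesion_class=cls, subtype=subtype,
                                   spec=spec, slide=slide, truth=truth))
    return entries
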