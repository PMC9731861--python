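"""Ink-based surgical margin detection.

Specimens are grossed with a green tissue marking dye on all but the
epidermal surfaces, so the non-epidermal margin appears as a saturated
green band. Patches are flagged as margin patches in HSV space (hue in
[90, 165] degrees, saturation >= 0.25, value >= 0.15, with at least 5%
of pixels inked); flags are reassembled into a margin map on the same
grid as the lesion probability map, and margin status is positive iff
the detected lesion and margin maps overlap in at least one cell.
Margin status applies to all melanocytic and BCC subtypes and to ASL
subtypes invasive SCC and SCCIS; AK, SK, and VV get ``not_applicable``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor

from .config import margin_applicable
from .patches import ProbabilityMap
from .slide_io import PatchGrid


@dataclass
class InkThresholds:
    hue_min_deg: float = 90.0
    hue_max_deg: float = 165.0
    saturation_min: float = 0.25
    value_min: float = 0.15
    ink_fraction_min: float = 0.05


def is_margin_patch(patch: np.ndarray,
                    thresholds: InkThresholds | None = None) -> bool:
    """True iff the patch carries enough green-ink pixels.

    Hue is measured in degrees [0, 360); saturation and value in [0, 1].
    """
    t = thresholds or InkThresholds()
    hsv = skcolor.rgb2hsv(np.asarray(patch, dtype=np.uint8))
    hue = hsv[:, :, 0] * 360.0
    ink = ((hue >= t.hue_min_deg) & (hue <= t.hue_max_deg)
           & (hsv[:, :, 1] >= t.saturation_min)
           & (hsv[:, :, 2] >= t.value_min))
    return bool(ink.mean() >= t.ink_fraction_min)


@dataclass
class MarginMap:
    """Grid-shaped binary raster of margin patches."""

    flags: np.ndarray            # (n_rows, n_cols) bool
    patch_size: int


def build_margin_map(grid: PatchGrid,
                     margin_flags: list[tuple[int, int]]) -> MarginMap:
    """Place per-patch margin flags at their grid coordinates."""
    flags = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    for r, c in margin_flags:
        flags[r, c] = True
    return MarginMap(flags=flags, patch_size=grid.patch_size)


def margin_map_from_slide(pixels: np.ndarray, grid: PatchGrid,
                          thresholds: InkThresholds | None = None
                          ) -> MarginMap:
    """Run the margin patch check over every grid cell of a slide."""
    flags = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            if is_margin_patch(grid.extract(pixels, r, c), thresholds):
                flags.append((r, c))
    return build_margin_map(grid, flags)


@dataclass
class MarginStatus:
    status: str                                   # positive/negative/not_applicable
    overlap_patches: list[tuple[int, int]] = field(default_factory=list)


def margin_status(pmap: ProbabilityMap, mmap: MarginMap, line: str,
                  subtype: str | None) -> MarginStatus:
    """Lesion/margin overlap rule with the applicability gate."""
    if not margin_applicable(line, subtype):
        return MarginStatus(status="not_applicable")
    if pmap.binary.shape != mmap.flags.shape:
        raise ValueError("lesion and margin maps must share a grid")
    overlap = pmap.binary & mmap.flags
    cells = [tuple(map(int, rc)) for rc in np.argwhere(overlap)]
    return MarginStatus(status="positive" if cells else "negative",
                        overlap_patches=cells)
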