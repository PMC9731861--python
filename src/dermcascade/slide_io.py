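"""Slide, mask, and manifest I/O plus the shared tiling geometry.

Slides are plain tiled TIFFs carrying a microns-per-pixel (MPP) value;
annotation masks are binary PNGs referenced from a CSV manifest with
columns ``wsi_name, mask_file, label, x0, y0, scale`` (the QuPath-export
convention). All coordinates are 0-based, half-open pixel windows with
x = column and y = row.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from skimage.transform import resize

ANNOTATION_COLUMNS = ["wsi_name", "mask_file", "label", "x0", "y0", "scale"]


@dataclass
class SlideImage:
    """A raster slide: (H, W, 3) uint8 pixels plus physical resolution."""

    pixels: np.ndarray
    mpp: float
    name: str = "slide"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("slide must be at least 1x1 pixels")
        if not (self.mpp > 0):
            raise ValueError("mpp must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class AnnotationMask:
    """A labeled binary mask placed at ``offset`` on the rescaled slide."""

    label: str
    mask: np.ndarray
    offset: tuple[int, int]  # (x0, y0)
    scale: float             # mpp at which the mask raster lives

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.size == 0 or not self.mask.any():
            raise ValueError("annotation mask must be nonempty")


@dataclass
class PatchGrid:
    """Row-major half-open square windows covering a slide.

    A trailing partial row/column is padded (with white) to full patch
    size and flagged ``padded`` rather than dropped, so probability maps
    align with the slide extent.
    """

    patch_size: int
    slide_height: int
    slide_width: int
    n_rows: int = field(init=False)
    n_cols: int = field(init=False)

    def __post_init__(self):
        if self.patch_size < 8:
            raise ValueError("patch_size must be >= 8")
        self.n_rows = math.ceil(self.slide_height / self.patch_size)
        self.n_cols = math.ceil(self.slide_width / self.patch_size)

    def __len__(self) -> int:
        return self.n_rows * self.n_cols

    def window(self, r: int, c: int) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) of the grid cell, half-open, unclipped."""
        p = self.patch_size
        return (c * p, r * p, (c + 1) * p, (r + 1) * p)

    def is_padded(self, r: int, c: int) -> bool:
        x0, y0, x1, y1 = self.window(r, c)
        return x1 > self.slide_width or y1 > self.slide_height

    def iter_windows(self):
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield r, c, self.window(r, c), self.is_padded(r, c)

    def extract(self, pixels: np.ndarray, r: int, c: int) -> np.ndarray:
        """Patch pixels; out-of-slide area padded with white (255)."""
        p = self.patch_size
        x0, y0, x1, y1 = self.window(r, c)
        out = np.full((p, p) + pixels.shape[2:], 255, dtype=pixels.dtype)
        xi, yi = min(x1, self.slide_width), min(y1, self.slide_height)
        out[: yi - y0, : xi - x0] = pixels[y0:yi, x0:xi]
        return out


# -- slide files ----------------------------------------------------------

def save_slide(slide: SlideImage, path: str | Path) -> None:
    """Write a tiled TIFF with an MPP record (lossless round trip)."""
    path = Path(path)
    desc = json.dumps({"mpp": slide.mpp, "name": slide.name})
    ppcm = 10000.0 / slide.mpp  # pixels per centimeter
    tifffile.imwrite(
        path, slide.pixels.astype(np.uint8), tile=(128, 128),
        description=desc, resolution=(ppcm, ppcm), resolutionunit="CENTIMETER",
        photometric="rgb",
    )


def load_slide(path: str | Path, mpp: float | None = None) -> SlideImage:
    """Read a slide image; level 0 of a multi-page file.

    The MPP is taken from the file's description record, then from TIFF
    resolution tags, then from the ``mpp`` override; if none is
    available an error is raised.
    """
    path = Path(path)
    name = path.stem
    file_mpp: float | None = None
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]  # level 0 = largest level
            pixels = page.asarray()
            desc = page.description
            if desc:
                try:
                    meta = json.loads(desc)
                    file_mpp = float(meta["mpp"])
                    name = meta.get("name", name)
                except (ValueError, KeyError, TypeError):
                    pass
            if file_mpp is None:
                try:
                    xres = page.tags["XResolution"].value
                    unit = page.tags["ResolutionUnit"].value
                    per_cm = xres[0] / xres[1]
                    if int(unit) == 3:  # centimeter
                        file_mpp = 10000.0 / per_cm
                    elif int(unit) == 2:  # inch
                        file_mpp = 25400.0 / per_cm
                except (KeyError, ZeroDivisionError):
                    file_mpp = None
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    final_mpp = file_mpp if file_mpp is not None else mpp
    if final_mpp is None:
        raise ValueError(
            f"{path} carries no MPP record and no override was supplied")
    return SlideImage(pixels=pixels.astype(np.uint8), mpp=float(final_mpp),
                      name=name)


def rescale_to_mpp(slide: SlideImage, target_mpp: float) -> SlideImage:
    """Bilinear resampling to a standardized resolution.

    The scale factor is ``slide.mpp / target_mpp`` on both axes.
    """
    if not (target_mpp > 0):
        raise ValueError("target_mpp must be positive")
    f = slide.mpp / target_mpp
    if f == 1.0:
        return SlideImage(slide.pixels.copy(), target_mpp, slide.name)
    h = int(round(slide.height * f))
    w = int(round(slide.width * f))
    if h < 1 or w < 1:
        raise ValueError("rescaling would produce a degenerate (<1 px) image")
    out = resize(slide.pixels, (h, w), order=1, anti_aliasing=False,
                 preserve_range=True)
    return SlideImage(np.clip(np.round(out), 0, 255).astype(np.uint8),
                      target_mpp, slide.name)


def tile(slide: SlideImage, patch_size: int) -> PatchGrid:
    """Tiling geometry shared by all cascade stages."""
    return PatchGrid(patch_size=patch_size, slide_height=slide.height,
                     slide_width=slide.width)


# -- masks and manifests --------------------------------------------------

def save_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask).astype(bool) * 255).astype(np.uint8),
                    mode="L").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) > 127


def write_annotation_table(rows: list[dict] | pd.DataFrame,
                           csv_path: str | Path) -> None:
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df.to_csv(csv_path, index=False)


def read_annotation_table(csv_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(csv_path, dtype={"wsi_name": str, "mask_file": str,
                                      "label": str})
    if list(df.columns) != ANNOTATION_COLUMNS:
        raise ValueError(
            f"annotation table must have columns {ANNOTATION_COLUMNS}, "
            f"got {list(df.columns)}")
    return df
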