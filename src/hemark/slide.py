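"""Raster input, background removal and stain separation.

An H&E slide raster is reduced to three single-channel views before any
texture analysis: the haematoxylin concentration map (nuclei), the eosin
concentration map (cytoplasm/stroma) and plain luminance.  Stain separation
follows the classical color-deconvolution model: each pixel's optical
density vector is a non-negative mixture of per-stain unit OD vectors, so
multiplying by the inverted stain matrix unmixes the channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage.color import rgb2gray
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import remove_small_objects

log = logging.getLogger(__name__)

#: Ruifrok & Johnston unit optical-density vectors for haematoxylin and
#: eosin; the third row is the normalized residual (H x E cross product)
#: so the matrix is invertible even for two-stain images.
RUIFROK_HE: np.ndarray = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.072, 0.990, 0.105],
    ]
)


def default_stain_matrix() -> np.ndarray:
    """3x3 H&E stain OD matrix (rows: haematoxylin, eosin, residual)."""
    h = RUIFROK_HE[0] / np.linalg.norm(RUIFROK_HE[0])
    e = RUIFROK_HE[1] / np.linalg.norm(RUIFROK_HE[1])
    r = np.cross(h, e)
    r /= np.linalg.norm(r)
    return np.stack([h, e, r])


#: Maximum optical density representable by an 8-bit pixel under the
#: OD = -log10((I+1)/255) convention; used to rescale channels to [0, 1].
OD_SCALE: float = float(np.log10(255.0))


@dataclass
class SlideImage:
    """An RGB histology raster plus optional scan metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    microns_per_pixel: float | None = None
    level_downsamples: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an RGB raster, got shape {px.shape}")
        if px.shape[0] < 31 or px.shape[1] < 31:
            raise ValueError("image smaller than one 31x31 tile")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class TissueMask:
    """Boolean raster aligned to a SlideImage; True marks tissue."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class StainChannels:
    """Unmixed haematoxylin/eosin concentrations plus luminance, in [0, 1].

    ``haematoxylin`` and ``eosin`` are optical-density concentrations
    divided by :data:`OD_SCALE`; multiply back to recover raw OD.
    """

    haematoxylin: np.ndarray
    eosin: np.ndarray
    gray: np.ndarray
    od_scale: float = OD_SCALE

    def __post_init__(self) -> None:
        shapes = {self.haematoxylin.shape, self.eosin.shape, self.gray.shape}
        if len(shapes) != 1:
            raise ValueError("stain channels are not shape-aligned")


def read_image(path: str | Path, level: int = 0) -> SlideImage:
    """Read a TIFF/PNG raster, optionally selecting a pyramid level.

    For pyramidal TIFFs (sub-IFD levels), ``level`` indexes the pyramid and
    ``level_downsamples`` records the downsample factor of every level
    relative to level 0.  PNG and flat TIFF input only has level 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() in {".tif", ".tiff", ".svs"}:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            levels = list(getattr(series, "levels", None) or [series])
            if not 0 <= level < len(levels):
                raise ValueError(f"level {level} out of range (0..{len(levels) - 1})")
            arr = levels[level].asarray()
            base_h = levels[0].shape[0]
            downs = [base_h / float(lv.shape[0]) for lv in levels]
    else:
        if level != 0:
            raise ValueError("non-TIFF input has a single pyramid level")
        arr = np.asarray(Image.open(path))
        downs = [1.0]
    if arr.ndim == 3 and arr.shape[2] == 4:  # tolerate RGBA, drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path.name}: expected RGB input, got shape {arr.shape}")
    return SlideImage(pixels=arr, level_downsamples=downs)


def tissue_mask(
    img: SlideImage, min_object_px: int = 64, degenerate_span: float = 1e-3
) -> TissueMask:
    """Separate tissue from the white slide background by Otsu thresholding.

    The threshold is computed on luminance; pixels darker than it count as
    tissue, then objects smaller than ``min_object_px`` are dropped.
    Because an H&E luminance histogram is typically trimodal (background /
    stroma / nuclei), the threshold is the upper cut of a three-class Otsu
    split, which isolates the bright background mode regardless of how the
    stain partitions the tissue modes; for a genuinely bimodal histogram it
    coincides with the classic two-class threshold.  A near-constant image
    has no split at all: it is called all-background when bright and
    all-tissue when dark, with a warning.
    """
    lum = rgb2gray(img.pixels)  # [0, 1]
    if float(lum.max() - lum.min()) < degenerate_span:
        warnings.warn("degenerate luminance histogram; thresholding by brightness")
        full = bool(lum.mean() < 0.5)
        return TissueMask(np.full(img.shape, full, dtype=bool))
    try:
        thr = float(threshold_multiotsu(lum, classes=3)[-1])
    except ValueError:  # fewer than 3 distinct gray levels
        thr = float(threshold_otsu(lum))
    mask = lum < thr
    if min_object_px > 1:
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return TissueMask(mask)


def separate_stains(
    img: SlideImage, stain_matrix: np.ndarray | None = None
) -> StainChannels:
    """Unmix an RGB raster into haematoxylin/eosin/luminance channels.

    Per-pixel optical density OD = -log10((I + 1) / 255) (the +1 avoids
    log(0) for saturated black) is projected through the inverse of the
    3x3 stain matrix; negative concentrations are clipped and the result is
    rescaled by :data:`OD_SCALE` into [0, 1].
    """
    m = default_stain_matrix() if stain_matrix is None else np.asarray(stain_matrix, float)
    if m.shape != (3, 3):
        raise ValueError("stain matrix must be 3x3")
    norms = np.linalg.norm(m, axis=1)
    if np.any(norms < 1e-12) or np.linalg.cond(m / norms[:, None]) > 1e8:
        raise ValueError("singular or near-singular stain matrix")
    m = m / norms[:, None]
    od = -np.log10((img.pixels.astype(np.float64) + 1.0) / 255.0)
    conc = od.reshape(-1, 3) @ np.linalg.inv(m)
    conc = np.clip(conc, 0.0, None).reshape(img.pixels.shape)
    chans = np.clip(conc / OD_SCALE, 0.0, 1.0)
    return StainChannels(
        haematoxylin=chans[:, :, 0],
        eosin=chans[:, :, 1],
        gray=rgb2gray(img.pixels),
    )


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)).save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a 0/255 single-channel PNG back into a boolean mask."""
    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 127
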