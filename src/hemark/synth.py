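"""Synthetic H&E-like slides with exact nuclei-level ground truth.

Real training material for tumor/non-tumor tile classification is a
pathologist-annotated slide archive; this module emulates its essential
structure so the whole pipeline is testable without any slide:

* a bright background frame around an eosin-pink tissue block,
* tumor regions populated with dense, round, strongly haematoxylin-stained
  nuclei,
* stroma populated with sparser, elongated nuclei,
* rendering through the same optical-density stain model that
  :func:`hemark.slide.separate_stains` inverts, so stain unmixing recovers
  the generating concentrations up to 8-bit quantization.

Nuclei never overlap (rejection sampling against an occupancy raster) and
each is recorded with center, equivalent radius and class, so the true
percent tumor nuclei is an exact count ratio, playing the role of a
hand-counted benchmark.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .slide import default_stain_matrix

#: Background optical density giving ~245 gray on the white frame.
BACKGROUND_OD: float = float(np.log10(255.0 / 246.0))

_MAX_ATTEMPTS = 1000  # rejection-sampling cap per nucleus


@dataclass
class SynthSpec:
    """Parameters of one synthetic slide.

    Densities are nuclei per 1000 px²; radii are the mean/sd of the
    equivalent (area-preserving) circle radius in pixels.  Stroma nuclei
    are elongated (``stroma_axis_ratio``: major/minor ≈ 3), tumor nuclei
    near-round and slightly larger — the morphological contrast a tile
    classifier must pick up.  ``seed`` makes the output byte-reproducible.
    """

    width: int = 512
    height: int = 512
    tumor_regions: list[tuple[int, int, int, int]] = field(default_factory=list)
    tissue_margin_px: int = 32
    tumor_nucleus_density: float = 8.0
    stroma_nucleus_density: float = 2.0
    tumor_nucleus_radius_px: tuple[float, float] = (3.5, 0.4)
    stroma_nucleus_radius_px: tuple[float, float] = (3.3, 0.4)
    tumor_axis_ratio: float = 1.2
    stroma_axis_ratio: float = 3.0
    hematoxylin_intensity: float = 0.9
    eosin_intensity: float = 0.35  # strong enough that Otsu's best split is background vs tissue
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_nucleus_density < 0 or self.stroma_nucleus_density < 0:
            raise ValueError("nucleus densities must be >= 0")
        for mean, sd in (self.tumor_nucleus_radius_px, self.stroma_nucleus_radius_px):
            if mean <= 0 or sd < 0:
                raise ValueError("nucleus radii must be positive")
        if self.width < 31 or self.height < 31:
            raise ValueError("slide must be at least 31x31")


@dataclass
class Nucleus:
    row: float
    col: float
    radius: float
    is_tumor: bool


@dataclass
class SynthGroundTruth:
    """Exact per-slide truth: masks, nuclei list, percent tumor nuclei.

    ``nucleus_mask`` is the exact rendered footprint of every nucleus;
    ``tumor_nucleus_mask`` the footprint of the tumor-class nuclei only.
    """

    tumor_mask: np.ndarray
    tissue_mask: np.ndarray
    nuclei: list[Nucleus]
    true_percent_tumor: float
    nucleus_mask: np.ndarray | None = None
    tumor_nucleus_mask: np.ndarray | None = None

    @property
    def n_tumor(self) -> int:
        return sum(n.is_tumor for n in self.nuclei)

    @property
    def n_nontumor(self) -> int:
        return sum(not n.is_tumor for n in self.nuclei)

    def to_json(self) -> str:
        return json.dumps(
            {
                "nuclei": [
                    {
                        "x": n.col,
                        "y": n.row,
                        "r": n.radius,
                        "class": "tumor" if n.is_tumor else "non-tumor",
                    }
                    for n in self.nuclei
                ],
                "percent_tumor": self.true_percent_tumor,
            }
        )


def centered_square(side: int, spec_width: int, spec_height: int) -> tuple[int, int, int, int]:
    """A (r0, c0, r1, c1) square region centered in the slide."""
    r0 = (spec_height - side) // 2
    c0 = (spec_width - side) // 2
    return (r0, c0, r0 + side, c0 + side)


def _region_masks(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    h, w, m = spec.height, spec.width, spec.tissue_margin_px
    tissue = np.zeros((h, w), dtype=bool)
    tissue[m : h - m, m : w - m] = True
    tumor = np.zeros((h, w), dtype=bool)
    for r0, c0, r1, c1 in spec.tumor_regions:
        r0c, c0c = max(r0, 0), max(c0, 0)
        r1c, c1c = min(r1, h), min(c1, w)
        clipped = np.zeros((h, w), dtype=bool)
        if r1c > r0c and c1c > c0c:
            clipped[r0c:r1c, c0c:c1c] = True
        clipped &= tissue
        if not clipped.any() and spec.tumor_nucleus_density > 0:
            raise ValueError(
                f"tumor region {(r0, c0, r1, c1)} has zero area inside the "
                "tissue but tumor nucleus density is nonzero"
            )
        tumor |= clipped
    return tissue, tumor


def _scatter_nuclei(
    rng: np.random.Generator,
    region: np.ndarray,
    occupied: np.ndarray,
    density: float,
    radius: tuple[float, float],
    axis_ratio: float,
    is_tumor: bool,
) -> list[Nucleus]:
    """Rejection-sample non-overlapping ellipses fully inside ``region``."""
    area = int(region.sum())
    n_target = int(round(density * area / 1000.0))
    if n_target == 0 or area == 0:
        return []
    rows, cols = np.nonzero(region)
    mean_r, sd_r = radius
    out: list[Nucleus] = []
    for _ in range(n_target):
        for _attempt in range(_MAX_ATTEMPTS):
            k = int(rng.integers(len(rows)))
            r = float(np.clip(rng.normal(mean_r, sd_r), 0.4 * mean_r, 2.5 * mean_r))
            theta = float(rng.uniform(0.0, np.pi))
            a = r * np.sqrt(axis_ratio)
            b = r / np.sqrt(axis_ratio)
            rr, cc = draw_ellipse(
                rows[k], cols[k], a, b, shape=region.shape, rotation=theta
            )
            if rr.size == 0:
                continue
            if region[rr, cc].all() and not occupied[rr, cc].any():
                occupied[rr, cc] = True
                out.append(Nucleus(float(rows[k]), float(cols[k]), r, is_tumor))
                break
    return out


def generate_slide(spec: SynthSpec) -> tuple[np.ndarray, SynthGroundTruth]:
    """Render a synthetic slide and its exact ground truth.

    Returns the (H, W, 3) uint8 RGB raster and a :class:`SynthGroundTruth`
    whose ``true_percent_tumor`` is 100·N_tumor/(N_tumor+N_nontumor) over
    the nuclei actually placed (0.0 for a slide with no nuclei).
    """
    rng = np.random.default_rng(spec.seed)
    tissue, tumor = _region_masks(spec)
    stroma = tissue & ~tumor

    occ_tumor = np.zeros_like(tissue)
    occ_stroma = np.zeros_like(tissue)
    nuclei = _scatter_nuclei(
        rng, tumor, occ_tumor, spec.tumor_nucleus_density,
        spec.tumor_nucleus_radius_px, spec.tumor_axis_ratio, True,
    )
    nuclei += _scatter_nuclei(
        rng, stroma, occ_stroma, spec.stroma_nucleus_density,
        spec.stroma_nucleus_radius_px, spec.stroma_axis_ratio, False,
    )

    od_h = np.zeros(tissue.shape, dtype=np.float64)
    od_e = np.zeros(tissue.shape, dtype=np.float64)
    od_e[tissue] = spec.eosin_intensity
    nuc = occ_tumor | occ_stroma
    od_h[nuc] = spec.hematoxylin_intensity
    if spec.noise_sd > 0:
        od_h = np.clip(od_h + rng.normal(0.0, spec.noise_sd, od_h.shape), 0.0, None)
        od_e = np.clip(od_e + rng.normal(0.0, spec.noise_sd, od_e.shape), 0.0, None)

    rgb = render_od(od_h, od_e)

    n_t = sum(n.is_tumor for n in nuclei)
    n_all = len(nuclei)
    pct = 100.0 * n_t / n_all if n_all else 0.0
    return rgb, SynthGroundTruth(
        tumor, tissue, nuclei, pct,
        nucleus_mask=nuc, tumor_nucleus_mask=occ_tumor,
    )


def render_od(od_h: np.ndarray, od_e: np.ndarray, background: bool = True) -> np.ndarray:
    """Forward stain model: per-stain OD maps -> 8-bit RGB transmission.

    Uses the same unit stain vectors as the deconvolution default plus
    (optionally) the constant background density, with
    pixel = round(255·10^(-OD)) − 1 so that -log10((pixel+1)/255) inverts
    it up to quantization.
    """
    m = default_stain_matrix()
    od = od_h[..., None] * m[0] + od_e[..., None] * m[1]
    if background:
        od = od + BACKGROUND_OD
    px = np.rint(255.0 * np.power(10.0, -od)) - 1.0
    return np.clip(px, 0, 255).astype(np.uint8)


def _full_window_origins(mask: np.ndarray, t: int) -> np.ndarray:
    """Top-left corners of t×t windows entirely inside ``mask`` (True)."""
    h, w = mask.shape
    if h < t or w < t:
        return np.empty((0, 2), dtype=int)
    c = np.zeros((h + 1, w + 1), dtype=np.int64)
    c[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), 0), 1)
    s = c[t:, t:] - c[:-t, t:] - c[t:, :-t] + c[:-t, :-t]
    return np.argwhere(s == t * t)


def generate_tile_set(
    spec_pair: tuple[SynthSpec, SynthSpec],
    n_per_class: int,
    tile: int = 31,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample labeled 31×31 RGB training tiles from a pair of slides.

    Tumor tiles are windows lying entirely inside the first slide's tumor
    mask; non-tumor tiles lie entirely in the second slide's tumor-free
    tissue.  Returns ``(tiles, labels)`` with tiles shaped
    (2·n_per_class, tile, tile, 3) and labels 1 = tumor first.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    spec_t, spec_s = spec_pair
    img_t, gt_t = generate_slide(spec_t)
    img_s, gt_s = generate_slide(spec_s)

    rng = np.random.default_rng(
        seed if seed is not None else [spec_t.seed, spec_s.seed, 2718]
    )
    picks = []
    for img, mask, label in (
        (img_t, gt_t.tumor_mask, 1),
        (img_s, gt_s.tissue_mask & ~gt_s.tumor_mask, 0),
    ):
        origins = _full_window_origins(mask, tile)
        if len(origins) < n_per_class:
            raise ValueError(
                f"region too small: {len(origins)} candidate {tile}x{tile} "
                f"windows for label {label}, need {n_per_class}"
            )
        idx = rng.choice(len(origins), size=n_per_class, replace=False)
        for r, col in origins[idx]:
            picks.append((img[r : r + tile, col : col + tile], label))

    tiles = np.stack([p[0] for p in picks])
    labels = np.array([p[1] for p in picks], dtype=int)
    return tiles, labels


def write_slide(
    out_dir: str | Path, rgb: np.ndarray, gt: SynthGroundTruth, stem: str = "slide"
) -> dict[str, Path]:
    """Write image PNG, tumor-mask PNG and ground-truth JSON; return paths."""
    from .slide import write_mask_png

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from PIL import Image

    paths = {
        "image": out / f"{stem}.png",
        "mask": out / f"{stem}_tumor_mask.png",
        "truth": out / f"{stem}_truth.json",
    }
    Image.fromarray(rgb).save(paths["image"])
    write_mask_png(gt.tumor_mask, paths["mask"])
    paths["truth"].write_text(gt.to_json())
    return paths
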