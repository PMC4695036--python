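"""From tile classifications to a macrodissection boundary.

The classified tile grid becomes a three-state spatial map (background /
tumor / non-tumor).  The binary tumor layer is cleaned by morphological
opening, closing, hole filling and small-component removal; each remaining
component's contour is traced, resampled, and low-pass filtered in the
Fourier-descriptor domain, yielding a smooth closed polygon a technician
can scrape along.  A per-tile tumor-posterior heatmap (blue → red) supports
visual review.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_fill_holes
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient
from skimage.draw import polygon2mask
from skimage.measure import find_contours
from skimage.morphology import closing, opening, remove_small_objects

from .classifier import LABEL_TUMOR, TileClassification, TrainedModel, classify_tiles
from .config import RunConfig
from .features import Tile, extract_features_batch, tile_grid
from .slide import SlideImage, StainChannels, TissueMask, separate_stains, tissue_mask

BG, NONTUMOR, TUMOR = 0, 1, 2


@dataclass
class TileLabelMap:
    """Grid of background/non-tumor/tumor calls plus tumor posteriors.

    ``scale`` is the working-pixel edge length of one grid cell
    (tile_size × resolution), so cell (i, j) covers pixels
    [i·scale, (i+1)·scale) × [j·scale, (j+1)·scale).  Background cells
    carry NaN posterior.
    """

    labels: np.ndarray  # (gh, gw) int8
    posterior: np.ndarray  # (gh, gw) float, NaN on background
    tile_size: int = 31
    scale: float = 31.0

    def __post_init__(self) -> None:
        if self.labels.shape != self.posterior.shape:
            raise ValueError("label and posterior grids differ in shape")

    @property
    def tumor(self) -> np.ndarray:
        return self.labels == TUMOR


@dataclass
class TumorBoundary:
    """Smoothed closed tumor polygons in level-0 pixel coordinates.

    Polygons are (n, 2) float arrays of (x, y) = (col, row) vertices,
    oriented counter-clockwise.  An empty polygon list is the legal
    "non-tumor slide" outcome.
    """

    polygons: list[np.ndarray] = field(default_factory=list)
    area_px: float = 0.0

    @property
    def is_empty(self) -> bool:
        return len(self.polygons) == 0

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the union of polygons on an image of ``shape``."""
        out = np.zeros(shape, dtype=bool)
        for poly in self.polygons:
            out |= polygon2mask(shape, poly[:, ::-1])  # (x,y) -> (row,col)
        return out

    def to_geojson(self) -> str:
        feats = []
        for poly in self.polygons:
            ring = poly.tolist()
            ring.append(ring[0])
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {"area_px": float(Polygon(poly).area)},
                }
            )
        return json.dumps(
            {
                "type": "FeatureCollection",
                "crs": {"type": "name", "properties": {"name": "image-pixel"}},
                "features": feats,
            }
        )

    @classmethod
    def from_geojson(cls, text: str) -> "TumorBoundary":
        d = json.loads(text)
        polys = []
        for feat in d.get("features", []):
            coords = feat["geometry"]["coordinates"][0]
            arr = np.asarray(coords, float)
            if np.allclose(arr[0], arr[-1]):
                arr = arr[:-1]
            polys.append(arr)
        area = float(sum(Polygon(p).area for p in polys))
        return cls(polygons=polys, area_px=area)


def build_label_map(
    tiles: list[Tile],
    classifications: list[TileClassification],
    grid_shape: tuple[int, int],
    tile_size: int = 31,
    resolution: float = 1.0,
) -> TileLabelMap:
    """Assemble the spatial map from per-tile classifications.

    ``grid_shape`` is the full tile grid of the image at this resolution;
    cells without a tissue tile stay background.
    """
    if len(tiles) != len(classifications):
        raise ValueError(
            f"{len(tiles)} tiles but {len(classifications)} classifications"
        )
    labels = np.full(grid_shape, BG, dtype=np.int8)
    post = np.full(grid_shape, np.nan)
    for t, c in zip(tiles, classifications):
        gi, gj = t.origin[0] // tile_size, t.origin[1] // tile_size
        labels[gi, gj] = TUMOR if c.label == LABEL_TUMOR else NONTUMOR
        post[gi, gj] = c.posterior
    return TileLabelMap(labels, post, tile_size, tile_size * resolution)


def clean_map(
    m: TileLabelMap,
    open_size: int = 2,
    close_size: int = 5,
    min_region_tiles: int = 4,
    max_iter: int = 8,
) -> TileLabelMap:
    """Remove isolated regions and fill holes in the tumor layer.

    One pass applies opening (square footprint of ``open_size`` cells),
    closing (``close_size`` cells), hole filling, and removal of components
    smaller than ``min_region_tiles``; passes repeat until the layer stops
    changing, so the operation is idempotent.  The opening footprint is
    deliberately small (2×2 by default): it removes isolated
    false-positive cells and one-cell-wide debris before the closing can
    absorb them, while preserving any genuine focus with a coherent 2×2
    core — on a coarse tile grid a larger element would erase small but
    real tumor regions a few tiles across.  Square (8-connected)
    footprints are used because a diamond clips the corners of every
    rectangular region at this resolution.  Tumor cells may only exist on
    tissue.
    """
    tissue = m.labels != BG
    pad = max(open_size, close_size) + 1  # false border so edge regions erode properly
    t = np.pad(m.tumor, pad)
    tis = np.pad(tissue, pad)
    for _ in range(max_iter):
        prev = t
        t = opening(t, np.ones((open_size, open_size), bool))
        t = closing(t, np.ones((close_size, close_size), bool))
        t = binary_fill_holes(t)
        if min_region_tiles > 1:
            t = remove_small_objects(t, max_size=min_region_tiles - 1)
        t &= tis
        if np.array_equal(t, prev):
            break
    t = t[pad:-pad, pad:-pad]
    labels = np.where(~tissue, BG, np.where(t, TUMOR, NONTUMOR)).astype(np.int8)
    return TileLabelMap(labels, m.posterior.copy(), m.tile_size, m.scale)


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points equally spaced in arc length."""
    pts = points
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.diff(pts, axis=0)
    d = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(d)])
    t = np.linspace(0.0, s[-1], n, endpoint=False)
    return np.column_stack(
        [np.interp(t, s, pts[:, 0]), np.interp(t, s, pts[:, 1])]
    )


def smooth_contour(points: np.ndarray, keep_coeffs: int, n_samples: int = 1024) -> np.ndarray:
    """Low-pass filter a closed contour via Fourier descriptors.

    The contour is resampled to ``n_samples`` points, encoded as the
    complex sequence x + iy, and all harmonics with |k| > keep_coeffs are
    zeroed; ``keep_coeffs >= n_samples // 2`` is the identity.
    """
    rs = _resample_closed(points, n_samples)
    z = rs[:, 0] + 1j * rs[:, 1]
    Z = np.fft.fft(z)
    idx = np.arange(n_samples)
    harmonic = np.minimum(idx, n_samples - idx)
    Z[harmonic > keep_coeffs] = 0.0
    sm = np.fft.ifft(Z)
    return np.column_stack([sm.real, sm.imag])


def smooth_boundary(
    m: TileLabelMap,
    keep_coeffs: int = 32,
    n_samples: int = 1024,
    min_region_area: float = 0.0,
) -> TumorBoundary:
    """Trace and smooth every tumor component into level-0 polygons.

    A map without tumor cells yields an empty boundary (the non-tumor
    slide call).  Contours nested inside another contour (holes) are
    dropped; ``clean_map`` fills holes beforehand in the normal pipeline.
    """
    t = m.tumor
    if not t.any():
        return TumorBoundary()
    padded = np.pad(t, 1).astype(float)
    contours = find_contours(padded, 0.5)
    polys: list[Polygon] = []
    for c in contours:
        c = c - 1.0  # undo padding
        sm = smooth_contour(c[:, ::-1], keep_coeffs, n_samples)  # to (x=col, y=row)
        px = (sm + 0.5) * m.scale  # cell coords -> level-0 pixel centers
        p = Polygon(px)
        if not p.is_valid:
            p = p.buffer(0)
        if p.is_empty or p.area <= min_region_area:
            continue
        if p.geom_type == "MultiPolygon":
            p = max(p.geoms, key=lambda g: g.area)
        polys.append(orient(p, sign=1.0))
    # drop contours contained in a larger one (interior hole traces)
    polys.sort(key=lambda p: p.area, reverse=True)
    kept: list[Polygon] = []
    for p in polys:
        if not any(q.contains(p.representative_point()) for q in kept):
            kept.append(p)
    rings = [np.asarray(p.exterior.coords)[:-1] for p in kept]
    return TumorBoundary(polygons=rings, area_px=float(sum(p.area for p in kept)))


def render_tumormap(m: TileLabelMap, upscale: int = 1) -> np.ndarray:
    """RGB heatmap of tumor posteriors: blue (0) → red (1), background black.

    The colormap is the straight line (1−p)·blue + p·red, so posterior 1
    renders pure red, 0 pure blue and 0.5 the (128, 0, 128) midpoint.
    """
    p = m.posterior
    valid = np.isfinite(p)
    out = np.zeros(p.shape + (3,), dtype=np.uint8)
    pv = np.clip(np.where(valid, p, 0.0), 0.0, 1.0)
    out[:, :, 0] = np.where(valid, np.rint(255.0 * pv), 0).astype(np.uint8)
    out[:, :, 2] = np.where(valid, np.rint(255.0 * (1.0 - pv)), 0).astype(np.uint8)
    if upscale > 1:
        out = np.repeat(np.repeat(out, upscale, axis=0), upscale, axis=1)
    return out


@dataclass
class SlideAnnotation:
    """Everything the end-to-end annotation of one slide produced."""

    label_map: TileLabelMap
    cleaned_map: TileLabelMap
    boundary: TumorBoundary
    heatmap: np.ndarray
    tissue: TissueMask
    stains: StainChannels
    tiles: list[Tile]
    classifications: list[TileClassification]

    @property
    def is_tumor_slide(self) -> bool:
        return not self.boundary.is_empty


def classify_slide(
    model: TrainedModel, img: SlideImage, cfg: RunConfig | None = None
) -> SlideAnnotation:
    """Run the full annotation pipeline on one slide raster.

    tissue mask → stain separation → tiling → features → SVM → map
    cleaning → Fourier-descriptor boundary → heatmap.  With several
    configured resolutions the per-resolution posteriors are averaged on
    the finest grid before thresholding.
    """
    cfg = cfg or RunConfig()
    mask = tissue_mask(img, min_object_px=cfg.otsu_min_object_px)
    stains = separate_stains(img, cfg.stain_matrix_array)
    base_res = cfg.resolutions[0]
    gh = int(img.shape[0] // base_res) // cfg.tile_size
    gw = int(img.shape[1] // base_res) // cfg.tile_size
    post_acc = np.zeros((gh, gw))
    post_n = np.zeros((gh, gw))
    base_tiles: list[Tile] = []
    base_cls: list[TileClassification] = []
    for res in cfg.resolutions:
        tiles = tile_grid(
            img, mask, stains,
            resolutions=(res,), tile=cfg.tile_size,
            min_tissue_frac=cfg.min_tissue_frac,
        )
        if not tiles:
            continue
        X = extract_features_batch(tiles)
        cls = classify_tiles(model, X)
        if res == base_res:
            base_tiles, base_cls = tiles, cls
        for t, c in zip(tiles, cls):
            # map this tile's footprint onto the base grid
            f = res / base_res
            gi0 = int(t.origin[0] // cfg.tile_size * f)
            gj0 = int(t.origin[1] // cfg.tile_size * f)
            gi1 = max(gi0 + 1, int(np.ceil((t.origin[0] // cfg.tile_size + 1) * f)))
            gj1 = max(gj0 + 1, int(np.ceil((t.origin[1] // cfg.tile_size + 1) * f)))
            post_acc[gi0 : min(gi1, gh), gj0 : min(gj1, gw)] += c.posterior
            post_n[gi0 : min(gi1, gh), gj0 : min(gj1, gw)] += 1.0

    labels = np.full((gh, gw), BG, dtype=np.int8)
    post = np.full((gh, gw), np.nan)
    covered = post_n > 0
    post[covered] = post_acc[covered] / post_n[covered]
    labels[covered] = np.where(
        post[covered] >= cfg.decision_threshold, TUMOR, NONTUMOR
    )
    lmap = TileLabelMap(labels, post, cfg.tile_size, cfg.tile_size * base_res)
    if len(cfg.resolutions) == 1:
        lmap = build_label_map(
            base_tiles, base_cls, (gh, gw), cfg.tile_size, base_res
        )
    cleaned = clean_map(
        lmap, cfg.open_size, cfg.close_size, cfg.min_region_tiles
    )
    bnd = smooth_boundary(cleaned, cfg.keep_coeffs, cfg.n_boundary_samples)
    heat = render_tumormap(cleaned)
    return SlideAnnotation(
        label_map=lmap,
        cleaned_map=cleaned,
        boundary=bnd,
        heatmap=heat,
        tissue=mask,
        stains=stains,
        tiles=base_tiles,
        classifications=base_cls,
    )


def write_boundary(b: TumorBoundary, path: str | Path) -> None:
    Path(path).write_text(b.to_geojson())


def read_boundary(path: str | Path) -> TumorBoundary:
    return TumorBoundary.from_geojson(Path(path).read_text())
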