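"""Run configuration shared by the pipeline stages and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class RunConfig:
    """Every tunable of the annotation pipeline, with working defaults.

    ``tile_size`` must be odd and >= 15.  ``resolutions`` are downsample
    factors relative to the working raster; with more than one entry the
    per-resolution tile posteriors are averaged on the finest grid.
    ``min_region_tiles`` sizes the smallest tumor focus kept after
    morphological cleaning, expressed in grid cells so it scales with the
    working resolution.
    """

    tile_size: int = 31
    resolutions: tuple[float, ...] = (1.0,)
    min_tissue_frac: float = 0.5
    otsu_min_object_px: int = 64
    stain_matrix: list[list[float]] | None = None
    # morphology / boundary
    open_size: int = 2  # square footprint edge, in grid cells
    close_size: int = 5
    min_region_tiles: int = 4
    n_boundary_samples: int = 1024
    keep_coeffs: int = 32
    # nuclei segmentation / size model
    nuclei_block_size: int = 51
    nuclei_offset: float = 0.02
    min_speck_px: int = 8
    nucleus_area_range: tuple[float, float] = (20.0, 400.0)
    # classification / evaluation
    decision_threshold: float = 0.5
    fdr_weights: tuple[float, float] = (2.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile_size < 15 or self.tile_size % 2 == 0:
            raise ValueError("tile_size must be odd and >= 15")

    @property
    def stain_matrix_array(self) -> np.ndarray | None:
        if self.stain_matrix is None:
            return None
        return np.asarray(self.stain_matrix, float)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["resolutions"] = list(self.resolutions)
        d["nucleus_area_range"] = list(self.nucleus_area_range)
        d["fdr_weights"] = list(self.fdr_weights)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for key in ("resolutions", "nucleus_area_range", "fdr_weights"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        return cls(**kw)
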