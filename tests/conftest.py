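"""Shared fixtures: the synthetic study conditions and a trained model.

The "study" conditions mirror the default recovery experiment: tumor
nuclei at 8 per 1000 px² (round, r ≈ 3.5 px), stroma nuclei at 4 per
1000 px² (3:1 elongated, r ≈ 3.3 px), 512×512 slides with a 32 px white
frame.  Training them once per session keeps the suite fast.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from hemark.classifier import train
from hemark.features import features_from_rgb_tiles
from hemark.slide import SlideImage
from hemark.synth import SynthSpec, centered_square, generate_slide, generate_tile_set

TUMOR_DENSITY = 8.0
STROMA_DENSITY = 4.0


def study_spec(seed: int, tumor_side: int = 0, size: int = 512, **kw) -> SynthSpec:
    regions = [centered_square(tumor_side, size, size)] if tumor_side > 0 else []
    params = dict(
        width=size,
        height=size,
        seed=seed,
        tumor_nucleus_density=TUMOR_DENSITY,
        stroma_nucleus_density=STROMA_DENSITY,
        tumor_regions=regions,
    )
    params.update(kw)
    return SynthSpec(**params)


def spec_for_percent(p: float, seed: int, size: int = 512, margin: int = 32) -> SynthSpec:
    """Tumor-square spec whose expected percent tumor nuclei is ~100·p."""
    f = p * STROMA_DENSITY / (TUMOR_DENSITY * (1 - p) + p * STROMA_DENSITY)
    side = int(round(math.sqrt(f) * (size - 2 * margin)))
    return study_spec(seed, tumor_side=side, size=size)


@pytest.fixture(scope="session")
def training_tiles():
    spec_t = study_spec(101, tumor_side=360)
    spec_s = study_spec(102)
    tiles, labels = generate_tile_set((spec_t, spec_s), n_per_class=150)
    return tiles, labels


@pytest.fixture(scope="session")
def training_features(training_tiles):
    tiles, labels = training_tiles
    return features_from_rgb_tiles(tiles), labels


@pytest.fixture(scope="session")
def study_model(training_features):
    X, y = training_features
    model, report = train(X, y, seed=0)
    model.meta["cv_report"] = report
    return model


@pytest.fixture(scope="session")
def quarter_tumor_slide():
    """Slide whose tumor square covers 25% of the tissue area."""
    side = int(round(math.sqrt(0.25) * 448))
    spec = study_spec(7, tumor_side=side)
    rgb, gt = generate_slide(spec)
    return SlideImage(pixels=rgb), gt


@pytest.fixture(scope="session")
def stroma_slide():
    rgb, gt = generate_slide(study_spec(8))
    return SlideImage(pixels=rgb), gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
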