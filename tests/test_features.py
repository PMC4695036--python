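"""Texture-descriptor oracles: each family against an independent
brute-force implementation, plus the frozen 135-feature layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemark.features import (
    FAMILY_SIZES,
    GLCM_LEVELS,
    N_FEATURES,
    N_PER_CHANNEL,
    Tile,
    extract_features,
    feature_names,
    glcm_features,
    histogram_features,
    moment_features,
    spectral_features,
    tile_grid,
)
from hemark.slide import SlideImage, TissueMask, separate_stains
from hemark.synth import SynthSpec, centered_square, generate_slide


def _random_tile(seed):
    return np.random.default_rng(seed).random((31, 31))


# ---------------------------------------------------------------- tiling


class TestTileGrid:
    def _tiles(self, h, w, mask=None):
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 200, (h, w, 3), dtype=np.uint8)
        img = SlideImage(pixels=rgb)
        m = TissueMask(np.ones((h, w), bool) if mask is None else mask)
        return tile_grid(img, m)

    def test_62x62_full_tissue_gives_4_tiles(self):
        assert len(self._tiles(62, 62)) == 4

    def test_100x100_floor_division_gives_9_tiles(self):
        assert len(self._tiles(100, 100)) == 9

    def test_tissue_fraction_filter_matches_brute_force(self):
        rng = np.random.default_rng(3)
        mask = rng.random((124, 124)) > 0.5
        tiles = self._tiles(124, 124, mask)
        expected = sum(
            mask[r : r + 31, c : c + 31].mean() >= 0.5
            for r in range(0, 124 - 30, 31)
            for c in range(0, 124 - 30, 31)
        )
        assert len(tiles) == expected

    def test_image_smaller_than_tile_warns_and_returns_empty(self):
        rgb = np.zeros((40, 40, 3), dtype=np.uint8)
        img = SlideImage(pixels=rgb)
        with pytest.warns(UserWarning, match="smaller"):
            tiles = tile_grid(img, TissueMask(np.ones((40, 40), bool)),
                              resolutions=(2.0,))
        assert tiles == []


# ---------------------------------------------------------------- histogram


class TestHistogramFeatures:
    def test_constant_tile(self):
        f = histogram_features(np.full((31, 31), 0.5))
        mean, sd, smooth, skew, kurt, energy, entropy = f
        assert mean == pytest.approx(0.5, abs=0.005)
        assert sd == 0 and smooth == 0 and skew == 0 and kurt == 0
        assert energy == 1.0 and entropy == 0.0

    def test_two_valued_tile(self):
        x = np.zeros((31, 31))
        x.ravel()[: x.size // 2] = 1.0
        f = histogram_features(x)
        # half the pixels at 0, (almost) half at 1: ~1 bit of entropy
        assert f[6] == pytest.approx(1.0, abs=0.01)
        assert f[5] == pytest.approx(0.5, abs=0.01)

    def test_matches_direct_formula_on_random_tile(self):
        x = _random_tile(11)
        q = np.clip(np.rint(x * 255.0), 0, 255).astype(int) / 255.0
        mean = q.mean()
        var = ((q - mean) ** 2).mean()
        sd = np.sqrt(var)
        skew = ((q - mean) ** 3).mean() / sd**3
        kurt = ((q - mean) ** 4).mean() / sd**4 - 3.0
        counts = np.bincount((q * 255).round().astype(int).ravel(), minlength=256)
        p = counts / counts.sum()
        energy = (p**2).sum()
        entropy = -(p[p > 0] * np.log2(p[p > 0])).sum()
        expected = [mean, sd, 1 - 1 / (1 + var), skew, kurt, energy, entropy]
        assert np.allclose(histogram_features(x), expected, rtol=1e-9)


# ---------------------------------------------------------------- GLCM


def brute_force_glcm_stats(x, levels=GLCM_LEVELS):
    """Naive double-loop co-occurrence + independently written statistics."""
    q = np.clip((x * levels).astype(int), 0, levels - 1)
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]
    mats = []
    h, w = q.shape
    for dr, dc in offsets:
        m = np.zeros((levels, levels))
        for i in range(h):
            for j in range(w):
                i2, j2 = i + dr, j + dc
                if 0 <= i2 < h and 0 <= j2 < w:
                    m[q[i, j], q[i2, j2]] += 1
                    m[q[i2, j2], q[i, j]] += 1
        mats.append(m / m.sum())
    P = np.mean(mats, axis=0)

    G = levels
    stats = {}
    con = dis = hom = asm = mp = 0.0
    for i in range(G):
        for j in range(G):
            p = P[i, j]
            con += (i - j) ** 2 * p
            dis += abs(i - j) * p
            hom += p / (1 + (i - j) ** 2)
            asm += p * p
            mp = max(mp, p)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(G))
    mu_y = sum(j * py[j] for j in range(G))
    vx = sum((i - mu_x) ** 2 * px[i] for i in range(G))
    vy = sum((j - mu_y) ** 2 * py[j] for j in range(G))
    corr = (
        sum((i - mu_x) * (j - mu_y) * P[i, j] for i in range(G) for j in range(G))
        / np.sqrt(vx * vy)
        if vx > 0 and vy > 0
        else 1.0
    )
    ent = -sum(p * np.log(p) for p in P.ravel() if p > 0)
    var = sum((i - mu_x) ** 2 * P[i, j] for i in range(G) for j in range(G))
    psum = np.zeros(2 * G - 1)
    pdiff = np.zeros(G)
    for i in range(G):
        for j in range(G):
            psum[i + j] += P[i, j]
            pdiff[abs(i - j)] += P[i, j]
    sa = sum(k * psum[k] for k in range(2 * G - 1))
    sv = sum((k - sa) ** 2 * psum[k] for k in range(2 * G - 1))
    se = -sum(p * np.log(p) for p in psum if p > 0)
    da = sum(k * pdiff[k] for k in range(G))
    dv = sum((k - da) ** 2 * pdiff[k] for k in range(G))
    de = -sum(p * np.log(p) for p in pdiff if p > 0)
    hx = -sum(p * np.log(p) for p in px if p > 0)
    hy = -sum(p * np.log(p) for p in py if p > 0)
    hxy1 = -sum(
        P[i, j] * np.log(px[i] * py[j])
        for i in range(G)
        for j in range(G)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log(px[i] * py[j])
        for i in range(G)
        for j in range(G)
        if px[i] * py[j] > 0
    )
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent))))
    return np.array(
        [con, dis, hom, asm, np.sqrt(asm), corr, ent, var, sa, sv, se, dv, de,
         imc1, imc2, mp]
    )


class TestGLCMFeatures:
    def test_constant_tile(self):
        f = glcm_features(np.full((31, 31), 0.3))
        contrast, _, _, asm, _, corr = f[:6]
        assert contrast == 0.0
        assert asm == pytest.approx(1.0)
        assert corr == 1.0
        assert f[15] == pytest.approx(1.0)  # max probability

    def test_checkerboard_contrast_by_hand(self):
        # alternating levels 0/1: every horizontal neighbor pair differs by 1
        x = np.indices((4, 4)).sum(axis=0) % 2 / GLCM_LEVELS
        q = np.clip((x * GLCM_LEVELS).astype(int), 0, GLCM_LEVELS - 1)
        assert set(q.ravel()) == {0, 1}
        # hand enumeration at 0°, distance 1: all 24 directed pairs are (0,1)
        # or (1,0) -> normalized GLCM puts all mass off-diagonal -> contrast 1
        m = np.zeros((2, 2))
        for i in range(4):
            for j in range(3):
                m[q[i, j], q[i, j + 1]] += 1
                m[q[i, j + 1], q[i, j]] += 1
        m /= m.sum()
        contrast0 = sum((a - b) ** 2 * m[a, b] for a in range(2) for b in range(2))
        assert contrast0 == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        x = _random_tile(seed)
        assert np.allclose(
            glcm_features(x), brute_force_glcm_stats(x), rtol=1e-9, atol=1e-12
        )

    def test_matches_brute_force_on_structured_tile(self):
        x = np.sin(np.linspace(0, 6 * np.pi, 31))[:, None] * 0.4 + 0.5
        x = np.repeat(x, 31, axis=1)
        assert np.allclose(
            glcm_features(x), brute_force_glcm_stats(x), rtol=1e-9, atol=1e-12
        )


# ---------------------------------------------------------------- spectral


class TestSpectralFeatures:
    def test_constant_tile_is_all_zero(self):
        assert np.all(spectral_features(np.full((31, 31), 0.7)) == 0)

    def test_ring_and_wedge_fractions_each_sum_to_one(self):
        f = spectral_features(_random_tile(5))
        assert f[:8].sum() == pytest.approx(1.0, abs=1e-9)
        assert f[8:].sum() == pytest.approx(1.0, abs=1e-9)

    def test_horizontal_sinusoid_concentrates_in_one_wedge(self):
        cols = np.arange(31)
        x = 0.5 + 0.4 * np.cos(2 * np.pi * 6 * cols / 32)  # aligned to FFT bin 6
        x = np.tile(x, (31, 1))
        f = spectral_features(x)
        # oracle: locate the spectral peak directly and compute its wedge
        F = np.fft.fftshift(np.fft.fft2(x, s=(32, 32)))
        P = np.abs(F) ** 2
        P[16, 16] = 0
        py, px = np.unravel_index(np.argmax(P), P.shape)
        theta = np.mod(np.arctan2(py - 16, px - 16), np.pi)
        wedge = min(int(theta / np.pi * 7), 6)
        assert f[8 + wedge] > 0.85

    def test_wedge_matches_direct_spectrum_fraction(self):
        x = _random_tile(9)
        f = spectral_features(x)
        F = np.fft.fftshift(np.fft.fft2(x - x.mean(), s=(32, 32)))
        P = np.abs(F) ** 2
        P[16, 16] = 0
        yy, xx = np.mgrid[0:32, 0:32]
        theta = np.mod(np.arctan2(yy - 16, xx - 16), np.pi)
        w0 = P[(theta >= 0) & (theta < np.pi / 7)].sum() / P.sum()
        assert f[8] == pytest.approx(w0, rel=1e-6)


# ---------------------------------------------------------------- moments


class TestMomentFeatures:
    def test_all_zero_tile(self):
        assert np.all(moment_features(np.zeros((31, 31))) == 0)

    def test_centered_disc_higher_invariants_vanish(self):
        yy, xx = np.mgrid[0:31, 0:31]
        disc = ((yy - 15) ** 2 + (xx - 15) ** 2 <= 100).astype(float)
        f = moment_features(disc)
        # phi2..phi7 of a rotationally symmetric mass are (near) zero: the
        # signed-log compression maps exact zero to -0.0 and tiny values to
        # a large negative magnitude
        assert np.all((f[1:] == 0.0) | (f[1:] < -4))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_rotation_invariance(self, seed):
        x = _random_tile(seed)
        assert np.allclose(moment_features(x), moment_features(np.rot90(x)), atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_mirror_invariance(self, seed):
        x = _random_tile(seed)
        assert np.allclose(moment_features(x), moment_features(x[:, ::-1]), atol=1e-6)


# ---------------------------------------------------------------- assembly


class TestExtractFeatures:
    def test_vector_length_and_family_split(self):
        assert N_FEATURES == 135
        assert N_PER_CHANNEL == 45
        assert tuple(FAMILY_SIZES.values()) == (7, 16, 15, 7)
        names = feature_names()
        assert len(names) == 135
        assert len([n for n in names if n.startswith("h_")]) == 45
        assert names[0] == "h_hist_mean" and names[45] == "e_hist_mean"

    def test_synthetic_tile_vector_is_finite_135(self):
        rgb, _ = generate_slide(
            SynthSpec(seed=3, width=128, height=128, tissue_margin_px=16,
                      tumor_regions=[centered_square(64, 128, 128)])
        )
        st = separate_stains(SlideImage(pixels=rgb))
        t = Tile(origin=(40, 40), h=st.haematoxylin[40:71, 40:71],
                 e=st.eosin[40:71, 40:71], gray=st.gray[40:71, 40:71])
        v = extract_features(t)
        assert v.shape == (135,)
        assert np.all(np.isfinite(v))

    def test_constant_white_tile_has_empty_stain_blocks(self):
        white = np.zeros((31, 31))
        t = Tile(origin=(0, 0), h=white, e=white, gray=np.ones((31, 31)))
        v = extract_features(t)
        names = feature_names()
        assert v[names.index("h_hist_mean")] == pytest.approx(0.0, abs=1e-6)
        assert v[names.index("e_hist_mean")] == pytest.approx(0.0, abs=1e-6)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_property_glcm_oracle_equivalence(seed):
    """Direction-averaged GLCM statistics equal the naive enumeration."""
    x = np.random.default_rng(seed).random((12, 12))  # small for the O(n^2) oracle
    assert np.allclose(
        glcm_features(x), brute_force_glcm_stats(x), rtol=1e-9, atol=1e-12
    )
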