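"""Texture features versus brute-force per-pixel oracles and their
equivariance/positivity properties."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import scaffdeg as sd
from scaffdeg.texture import EntropyParams, StructureTensorParams


def brute_force_tensor_eigen(channel, sigma):
    """Independent oracle: dense 2x2 eigendecomposition at every pixel."""
    f = np.asarray(channel, float)
    fy, fx = np.gradient(f)
    jxx = gaussian_filter(fx * fx, sigma, mode="reflect")
    jxy = gaussian_filter(fx * fy, sigma, mode="reflect")
    jyy = gaussian_filter(fy * fy, sigma, mode="reflect")
    lmax = np.empty_like(f)
    lmin = np.empty_like(f)
    for y in range(f.shape[0]):
        for x in range(f.shape[1]):
            w = np.linalg.eigvalsh(np.array([[jxx[y, x], jxy[y, x]],
                                             [jxy[y, x], jyy[y, x]]]))
            lmin[y, x], lmax[y, x] = w
    return lmax, lmin


def brute_force_entropy(channel, radius, n_bins):
    """Independent oracle: explicit histogram-and-sum per pixel with the
    circular neighbourhood cropped at image borders."""
    f = np.asarray(channel, float)
    binned = np.clip(np.floor(f * n_bins / 256.0), 0, n_bins - 1).astype(int)
    h, w = f.shape
    offsets = [(dy, dx) for dy in range(-radius, radius + 1)
               for dx in range(-radius, radius + 1)
               if dy * dy + dx * dx <= radius * radius]
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            vals = [binned[y + dy, x + dx] for dy, dx in offsets
                    if 0 <= y + dy < h and 0 <= x + dx < w]
            counts = np.bincount(vals)
            p = counts[counts > 0] / len(vals)
            out[y, x] = -(p * np.log2(p)).sum()
    return out


class TestStructureTensor:
    def test_constant_channel_gives_zero_eigenvalues(self):
        lmax, lmin = sd.structure_tensor_eigen(np.full((16, 16), 9.0))
        assert np.all(lmax == 0) and np.all(lmin == 0)

    def test_linear_ramp_has_unit_major_eigenvalue_in_interior(self):
        x = np.tile(np.arange(32, dtype=float), (32, 1))
        lmax, lmin = sd.structure_tensor_eigen(x)
        interior = (slice(8, -8), slice(8, -8))
        np.testing.assert_allclose(lmax[interior], 1.0, atol=1e-9)
        np.testing.assert_allclose(lmin[interior], 0.0, atol=1e-9)

    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(0)
        patch = rng.uniform(0, 255, (9, 9))
        lmax, lmin = sd.structure_tensor_eigen(
            patch, StructureTensorParams(sigma=1.5))
        bmax, bmin = brute_force_tensor_eigen(patch, 1.5)
        np.testing.assert_allclose(lmax, bmax, atol=1e-10)
        np.testing.assert_allclose(lmin, bmin, atol=1e-10)

    def test_non_finite_input_rejected(self):
        bad = np.ones((8, 8))
        bad[3, 3] = np.nan
        with pytest.raises(sd.ValidationError):
            sd.structure_tensor_eigen(bad)


class TestLocalEntropy:
    def test_constant_patch_has_zero_entropy(self):
        ent = sd.local_entropy(np.full((16, 16), 120.0))
        assert np.all(ent == 0)

    def test_two_balanced_values_give_one_bit(self):
        # columns alternate between two intensities: every interior
        # neighbourhood holds them in (near-)equal counts; check the exact
        # 1-bit value where counts balance exactly
        img = np.zeros((17, 17))
        img[:, 1::2] = 128.0
        ent = sd.local_entropy(img, EntropyParams(radius=2))
        oracle = brute_force_entropy(img, 2, 256)
        np.testing.assert_allclose(ent, oracle, atol=1e-10)
        assert np.any(np.isclose(ent, 1.0))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (14, 14)).astype(float)
        for n_bins in (256, 16):
            ent = sd.local_entropy(img, EntropyParams(radius=3, n_bins=n_bins))
            oracle = brute_force_entropy(img, 3, n_bins)
            np.testing.assert_allclose(ent, oracle, atol=1e-10)

    def test_bounded_by_log2_bins(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (20, 20)).astype(float)
        ent = sd.local_entropy(img, EntropyParams(radius=4, n_bins=16))
        assert ent.max() <= np.log2(16) + 1e-12

    def test_oversized_radius_rejected(self):
        with pytest.raises(sd.ValidationError):
            sd.local_entropy(np.zeros((16, 16)), EntropyParams(radius=9))


class TestFeatureStack:
    def test_shape_and_names(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)
        stack = sd.build_feature_stack(img)
        assert stack.shape == (64, 64, 24)
        assert stack.feature_names[0] == "R_intensity"
        assert stack.feature_names[3] == "R_entropy"
        assert stack.feature_names[-1] == "V_entropy"

    def test_grayscale_input_rejected(self):
        with pytest.raises(sd.ValidationError):
            sd.build_feature_stack(np.zeros((64, 64)))

    def test_rgb_eigenvalues_invariant_to_constant_offset(self):
        rng = np.random.default_rng(4)
        img = rng.integers(40, 200, (64, 64, 3)).astype(float)
        s1 = sd.build_feature_stack(img)
        s2 = sd.build_feature_stack(img + 30.0)
        names = s1.feature_names
        rgb_eigen = [i for i, n in enumerate(names)
                     if n[0] in "RGB" and "lambda" in n and len(n.split("_")[0]) == 1]
        np.testing.assert_allclose(s1.data[..., rgb_eigen],
                                   s2.data[..., rgb_eigen], atol=1e-4)

    def test_eigenvalue_maps_rotation_equivariant(self):
        rng = np.random.default_rng(5)
        ch = gaussian_filter(rng.uniform(0, 255, (48, 48)), 2.0)
        lmax, _ = sd.structure_tensor_eigen(ch)
        lmax_rot, _ = sd.structure_tensor_eigen(np.rot90(ch))
        interior = (slice(8, -8), slice(8, -8))
        np.testing.assert_allclose(np.rot90(lmax)[interior],
                                   lmax_rot[interior], atol=1e-9)

    def test_translation_equivariance_in_interior(self):
        rng = np.random.default_rng(6)
        ch = rng.uniform(0, 255, (40, 40))
        lmax, _ = sd.structure_tensor_eigen(ch)
        lmax_sh, _ = sd.structure_tensor_eigen(np.roll(ch, 5, axis=1))
        np.testing.assert_allclose(lmax[10:-10, 10:25],
                                   lmax_sh[10:-10, 15:30], atol=1e-9)

    def test_eigenvalues_nonnegative_psd(self, standard_stack):
        names = standard_stack.feature_names
        lam_idx = [i for i, n in enumerate(names) if "lambda" in n]
        assert standard_stack.data[..., lam_idx].min() >= -1e-9
        ent_idx = [i for i, n in enumerate(names) if "entropy" in n]
        assert standard_stack.data[..., ent_idx].min() >= 0
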