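"""Conventional texture features against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from echotex.features import (
    FEATURE_NAMES,
    GLCMConfig,
    GLCMTensor,
    LBPConfig,
    autocorrelation_index,
    compute_glcm,
    edge_statistics,
    extract_feature_vector,
    haralick_features,
    hurst_index,
    laws_features,
    laws_kernels,
    lbp_codes,
    lbp_histogram,
    median_prefilter,
    order2_displacements,
    order3_displacements,
    quantize,
    shannon_entropy,
    wavelet_entropies,
)

# ---------------------------------------------------------------------------
# oracles


def glcm_oracle(pixels, config):
    """Enumerate every pixel tuple literally, one tensor per displacement."""
    q = quantize(pixels, config.gray_levels)
    h, w = q.shape
    g = config.gray_levels
    tensors = []
    for disp in config.displacements:
        counts = np.zeros((g,) * config.order, dtype=np.int64)
        for y in range(h):
            for x in range(w):
                coords = [(x, y)] + [(x + dx, y + dy) for dx, dy in disp]
                if all(0 <= cx < w and 0 <= cy < h for cx, cy in coords):
                    counts[tuple(q[cy, cx] for cx, cy in coords)] += 1
        tensors.append(counts)
    return tensors


def haralick_oracle(p):
    """Straight-sum textbook formulas on one normalized distribution."""
    order = p.ndim
    g = p.shape[0]
    cells = list(itertools.product(range(g), repeat=order))
    pairs = [(i, j) for i in range(order) for j in range(i + 1, order)]
    energy = sum(p[c] ** 2 for c in cells)
    entropy = -sum(p[c] * math.log2(p[c]) for c in cells if p[c] > 0)
    contrast = sum(
        p[c] * np.mean([(c[i] - c[j]) ** 2 for i, j in pairs]) for c in cells
    )
    homog = sum(
        p[c] / (1 + np.mean([(c[i] - c[j]) ** 2 for i, j in pairs])) for c in cells
    )
    mus = [sum(p[c] * c[i] for c in cells) for i in range(order)]
    sigs = [math.sqrt(sum(p[c] * (c[i] - mus[i]) ** 2 for c in cells)) for i in range(order)]
    variance = np.mean(
        [sum(p[c] * (c[i] - mus[i]) ** 2 for c in cells) for i in range(order)]
    )
    corrs = []
    for i, j in pairs:
        if sigs[i] == 0 or sigs[j] == 0:
            corrs.append(0.0)
        else:
            cov = sum(p[c] * (c[i] - mus[i]) * (c[j] - mus[j]) for c in cells)
            corrs.append(cov / (sigs[i] * sigs[j]))
    return {
        "homogeneity": homog,
        "energy": energy,
        "entropy": entropy,
        "correlation": float(np.mean(corrs)),
        "contrast": contrast,
        "variance": float(variance),
    }


def fbm_surface(h_exponent, size, seed):
    """Spectral-synthesis fractional Brownian surface (independent oracle)."""
    rng = np.random.default_rng(seed)
    freqs = np.fft.fftfreq(size)
    fx, fy = np.meshgrid(freqs, freqs)
    f = np.hypot(fx, fy)
    f[0, 0] = np.inf  # kill the DC term
    amplitude = f ** (-(h_exponent + 1.0))
    phase = rng.uniform(0, 2 * np.pi, (size, size))
    spectrum = amplitude * np.exp(1j * phase)
    surf = np.real(np.fft.ifft2(spectrum))
    surf = (surf - surf.min()) / (surf.max() - surf.min())
    return (surf * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# tests


class TestMedianFilter:
    def test_constant_unchanged(self, constant_patch):
        assert np.array_equal(median_prefilter(constant_patch), constant_patch)

    def test_impulse_removed(self):
        patch = np.zeros((9, 9), np.uint8)
        patch[4, 4] = 255
        assert median_prefilter(patch)[4, 4] == 0

    def test_matches_sorted_window_oracle(self, rng):
        patch = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        got = median_prefilter(patch)
        padded = np.pad(patch, 1, mode="symmetric")  # edge-inclusive reflection
        for y in range(8):
            for x in range(8):
                window = np.sort(padded[y : y + 3, x : x + 3].ravel())
                assert got[y, x] == window[4]

    def test_even_kernel_rejected(self, constant_patch):
        with pytest.raises(ValueError):
            median_prefilter(constant_patch, kernel=4)


class TestGLCM:
    def test_hand_example_two_by_two(self):
        patch = np.array([[0, 0], [128, 128]], dtype=np.uint8)
        config = GLCMConfig(order=2, gray_levels=2, displacements=(((1, 0),),))
        (tensor,) = compute_glcm(patch, config)
        expected = np.zeros((2, 2), dtype=np.int64)
        expected[0, 0] = 1  # the two pixels of the top row
        expected[1, 1] = 1  # the two pixels of the bottom row
        assert np.array_equal(tensor.counts, expected)

    def test_constant_patch_all_mass_on_diagonal(self, constant_patch):
        for order in (2, 3):
            for t in compute_glcm(constant_patch, GLCMConfig(order=order, gray_levels=8)):
                level = quantize(constant_patch, 8)[0, 0]
                assert t.counts.sum() == t.counts[(level,) * order]

    @pytest.mark.parametrize("order,levels", [(2, 8), (3, 4)])
    def test_matches_enumeration_oracle(self, rng, order, levels):
        patch = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        config = GLCMConfig(order=order, gray_levels=levels)
        got = compute_glcm(patch, config)
        want = glcm_oracle(patch, config)
        for g, w in zip(got, want):
            assert np.array_equal(g.counts, w)

    def test_order2_matches_skimage(self, rng):
        """Independent cross-check against the scikit-image implementation
        for one unit displacement (right neighbor)."""
        from skimage.feature import graycomatrix

        patch = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        config = GLCMConfig(order=2, gray_levels=16, displacements=(((1, 0),),))
        (tensor,) = compute_glcm(patch, config)
        ref = graycomatrix(quantize(patch, 16).astype(np.uint8), [1], [0], levels=16)
        assert np.array_equal(tensor.counts, ref[:, :, 0, 0])

    def test_displacement_inventories(self):
        assert len(order2_displacements()) == 8
        assert len(order3_displacements()) == 12
        assert all(
            max(abs(c) for v in disp for c in v) == 2 for disp in order3_displacements()
        )

    def test_too_small_patch_raises(self):
        with pytest.raises(ValueError):
            compute_glcm(np.zeros((2, 2), np.uint8), GLCMConfig(order=3))


class TestHaralick:
    def test_closed_form_two_point_distribution(self):
        counts = np.zeros((2, 2), dtype=np.int64)
        counts[0, 0] = counts[1, 1] = 5
        t = GLCMTensor(counts=counts, config=GLCMConfig(order=2, gray_levels=2))
        f = haralick_features([t])
        assert f["energy"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(1.0)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["correlation"] == pytest.approx(1.0)

    def test_constant_patch_degenerate_statistics(self, constant_patch):
        f = haralick_features(compute_glcm(constant_patch, GLCMConfig(order=2)))
        assert f["entropy"] == pytest.approx(0.0)
        assert f["energy"] == pytest.approx(1.0)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["correlation"] == 0.0  # zero-variance convention

    @pytest.mark.parametrize("order,levels", [(2, 8), (3, 4)])
    def test_matches_straight_sum_oracle(self, rng, order, levels):
        patch = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        tensors = compute_glcm(patch, GLCMConfig(order=order, gray_levels=levels))
        got = haralick_features(tensors)
        per = [haralick_oracle(t.normalized()) for t in tensors]
        for name in got:
            want = float(np.mean([d[name] for d in per]))
            assert got[name] == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_empty_tensor_rejected(self):
        t = GLCMTensor(counts=np.zeros((2, 2), np.int64), config=GLCMConfig(order=2, gray_levels=2))
        with pytest.raises(ValueError):
            haralick_features([t])


class TestAutocorrelation:
    def test_constant_nonzero_patch(self, constant_patch):
        assert autocorrelation_index(constant_patch) == pytest.approx(1.0)

    def test_checkerboard_diagonal_lag(self):
        patch = np.indices((8, 8)).sum(axis=0) % 2 * 255
        assert autocorrelation_index(patch) == pytest.approx(1.0)

    def test_all_zero_defined_as_zero(self):
        assert autocorrelation_index(np.zeros((8, 8))) == 0.0

    def test_matches_double_sum(self, rng):
        patch = rng.integers(0, 256, (10, 10)).astype(float)
        num = sum(patch[y, x] * patch[y + 1, x + 1] for y in range(9) for x in range(9))
        den = sum(patch[y, x] ** 2 for y in range(9) for x in range(9))
        assert autocorrelation_index(patch) == pytest.approx(num / den, rel=1e-9)


class TestHurst:
    @pytest.mark.parametrize("h_true", [0.3, 0.5, 0.7])
    def test_recovers_fbm_exponent(self, h_true):
        estimates = [hurst_index(fbm_surface(h_true, 64, seed)) for seed in range(10)]
        assert abs(float(np.mean(estimates)) - h_true) <= 0.15

    def test_iid_noise_is_rough(self):
        ests = [
            hurst_index(np.random.default_rng(s).integers(0, 256, (56, 56)))
            for s in range(10)
        ]
        assert float(np.mean(ests)) < 0.3

    def test_constant_patch_maximally_smooth(self, constant_patch):
        assert hurst_index(constant_patch) == 1.0

    def test_range(self, rng):
        for _ in range(5):
            v = hurst_index(rng.integers(0, 256, (32, 32)))
            assert 0.0 <= v <= 1.0


class TestEdgeStatistics:
    def test_constant_patch_all_zero(self, constant_patch):
        f = edge_statistics(constant_patch)
        assert f == {"edge_frequency": 0.0, "edge_contrast": 0.0, "edge_orientation": 0.0}

    def test_vertical_step_edge(self):
        patch = np.zeros((20, 20), np.uint8)
        patch[:, 10:] = 255
        f = edge_statistics(patch)
        assert f["edge_frequency"] > 0
        # gradient along +x: orientation folds to ~0 (mod pi)
        assert min(f["edge_orientation"], math.pi - f["edge_orientation"]) < 1e-6

    def test_frequency_bounded(self, rng):
        f = edge_statistics(rng.integers(0, 256, (16, 16)))
        assert 0.0 <= f["edge_frequency"] <= 1.0


class TestLaws:
    def test_kernel_construction(self):
        ks = laws_kernels()
        assert set(ks) == {"L5", "E5", "S5", "W5", "R5"}
        for name in ("E5", "S5", "W5", "R5"):
            assert ks[name].sum() == pytest.approx(0.0)
        assert np.array_equal(ks["L5"], np.outer([1, 4, 6, 4, 1], [1, 4, 6, 4, 1]))

    def test_zero_sum_kernels_annihilate_constants(self, constant_patch):
        f = laws_features(constant_patch)
        for name in ("E5", "S5", "W5", "R5"):
            assert f[f"laws_{name}_density"] == 0.0
            assert f[f"laws_{name}_frequency"] == 0.0

    def test_matches_direct_convolution(self, rng):
        from scipy.ndimage import convolve

        patch = rng.integers(0, 256, (8, 8)).astype(float)
        f = laws_features(patch)
        for name, kernel in laws_kernels().items():
            resp = np.abs(convolve(patch, kernel, mode="reflect"))
            assert f[f"laws_{name}_density"] == pytest.approx(resp.mean(), rel=1e-9)
            assert f[f"laws_{name}_frequency"] == pytest.approx(
                (resp > resp.mean()).mean(), rel=1e-9
            )


class TestWaveletEntropies:
    def test_all_zero_patch(self):
        f = wavelet_entropies(np.zeros((8, 8)))
        assert len(f) == 20
        assert all(v == 0.0 for v in f.values())

    def test_point_mass_entropy_zero(self):
        assert shannon_entropy(np.array([0.0, 0.7, 0.0])) == 0.0

    def test_four_equal_coefficients_two_bits(self):
        assert shannon_entropy(np.array([1.0, -1.0, 1.0, -1.0])) == pytest.approx(2.0)

    def test_component_count_and_names(self, random_patch):
        f = wavelet_entropies(random_patch)
        assert len(f) == 20
        assert sum("_" in k[len("wavelet_") :] for k in f) == 16

    def test_indivisible_side_rejected(self):
        with pytest.raises(ValueError):
            wavelet_entropies(np.zeros((10, 10)))


class TestLBP:
    def test_hand_example_code_85(self):
        """Neighbors alternating 6, 4 around a center of 5 set exactly the
        even-numbered bits: 2^0 + 2^2 + 2^4 + 2^6 = 85."""
        patch = np.full((3, 3), 4.0)
        patch[1, 1] = 5.0
        patch[1, 2] = 6.0  # p=0 (angle 0)
        patch[2, 1] = 6.0  # p=2 (angle 90: +y)
        patch[1, 0] = 6.0  # p=4
        patch[0, 1] = 6.0  # p=6
        codes = lbp_codes(patch)
        assert codes[1, 1] == 85

    def test_equal_neighbors_give_code_zero(self, constant_patch):
        codes = lbp_codes(constant_patch.astype(float))
        assert np.all(codes[1:-1, 1:-1] == 0)

    def test_constant_patch_histograms(self, constant_patch):
        hist = lbp_histogram(constant_patch, LBPConfig(cell_size=14))
        assert hist.shape == (16 * 256,)
        per_cell = hist.reshape(16, 256)
        assert np.all(per_cell.argmax(axis=1) == 0)
        # every counted pixel landed in bin 0
        assert per_cell.sum() == per_cell[:, 0].sum()

    def test_cell_size_must_divide(self, constant_patch):
        with pytest.raises(ValueError):
            lbp_histogram(constant_patch, LBPConfig(cell_size=13))


class TestFeatureVector:
    def test_canonical_inventory(self, random_patch):
        fv = extract_feature_vector(random_patch)
        assert list(fv.values.keys()) == list(FEATURE_NAMES)
        assert len(fv.values) == 47
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_deterministic(self, random_patch):
        a = extract_feature_vector(random_patch)
        b = extract_feature_vector(random_patch)
        assert a.values == b.values

    @pytest.mark.parametrize(
        "patch",
        [
            np.zeros((56, 56), np.uint8),
            np.full((56, 56), 255, np.uint8),
            np.eye(56, dtype=np.uint8) * 255,
        ],
        ids=["zeros", "saturated", "impulse-diagonal"],
    )
    def test_degenerate_inputs_stay_finite(self, patch):
        fv = extract_feature_vector(patch)
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_lbp_extension(self, random_patch):
        fv = extract_feature_vector(random_patch, include_lbp=True)
        assert len(fv.values) == 47 + 16 * 256
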