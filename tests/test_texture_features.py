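"""Window statistics, GLCM construction, Haralick features, feature table."""

import numpy as np
import pytest

from coroclust.phantom import generate_phantom
from coroclust.skeleton import extract_skeleton, local_frames
from coroclust.texture_features import (DEFAULT_OFFSETS, compute_glcm,
                                        extract_feature_table,
                                        haralick_features, window_statistics,
                                        GLCM, _batch_haralick, _batch_stats,
                                        _gather_windows)
from coroclust.volume_io import VesselMask, quantize_hu
from tests.conftest import small_spec


# ---------------------------------------------------------------------------
# Independent brute-force oracles (nested loops, no shared code paths)
# ---------------------------------------------------------------------------

def oracle_glcm(window, n_levels, offsets):
    m = np.zeros((n_levels, n_levels))
    for dx, dy, dz in offsets:
        for x in range(3):
            for y in range(3):
                for z in range(3):
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if 0 <= nx < 3 and 0 <= ny < 3 and 0 <= nz < 3:
                        m[window[x, y, z], window[nx, ny, nz]] += 1
                        m[window[nx, ny, nz], window[x, y, z]] += 1
    return m / m.sum()


def oracle_haralick(p):
    n = p.shape[0]
    feats = dict(contrast=0.0, homogeneity=0.0, dissimilarity=0.0,
                 entropy=0.0, energy=0.0, max_probability=0.0,
                 correlation=0.0, sum_entropy=0.0, difference_entropy=0.0)
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            feats["contrast"] += v * (i - j) ** 2
            feats["homogeneity"] += v / (1 + abs(i - j))
            feats["dissimilarity"] += v * abs(i - j)
            if v > 0:
                feats["entropy"] -= v * np.log2(v)
            feats["energy"] += v * v
            feats["max_probability"] = max(feats["max_probability"], v)
    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    mu = sum(i * px[i] for i in range(n))
    var = sum((i - mu) ** 2 * px[i] for i in range(n))
    if var > 0:
        num = sum((i - mu) * (j - mu) * p[i, j]
                  for i in range(n) for j in range(n))
        feats["correlation"] = num / var
    psum = [0.0] * (2 * n - 1)
    pdiff = [0.0] * n
    for i in range(n):
        for j in range(n):
            psum[i + j] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]
    for v in psum:
        if v > 0:
            feats["sum_entropy"] -= v * np.log2(v)
    for v in pdiff:
        if v > 0:
            feats["difference_entropy"] -= v * np.log2(v)
    return feats


class TestWindowStatistics:
    def test_constant_window(self):
        sv = window_statistics(np.full((3, 3, 3), 100.0))
        assert sv.mean == sv.median == sv.q1 == sv.q3 == 100.0
        assert sv.sd == sv.skewness == sv.kurtosis == 0.0
        assert sv.grad_x == sv.grad_y == sv.grad_z == 0.0

    def test_central_difference_gradient(self):
        w = np.zeros((3, 3, 3))
        w[0, 1, 1] = 0.0
        w[2, 1, 1] = 250.0
        sv = window_statistics(w, spacing=(1.0, 1.0, 1.0))
        assert sv.grad_x == pytest.approx(125.0)

    def test_order_statistics_1_to_27(self):
        rng = np.random.default_rng(3)
        w = rng.permutation(np.arange(1.0, 28.0)).reshape(3, 3, 3)
        sv = window_statistics(w)
        assert sv.mean == pytest.approx(14.0)
        assert sv.median == pytest.approx(14.0)
        assert sv.q1 == pytest.approx(7.5)
        assert sv.q3 == pytest.approx(20.5)

    def test_scipy_moment_agreement(self):
        from scipy import stats as ss
        rng = np.random.default_rng(11)
        w = rng.normal(size=(3, 3, 3)) * 50 + 100
        sv = window_statistics(w)
        assert sv.skewness == pytest.approx(ss.skew(w.ravel()))
        assert sv.kurtosis == pytest.approx(ss.kurtosis(w.ravel()))
        assert sv.sd == pytest.approx(w.ravel().std(ddof=1))

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="3x3x3"):
            window_statistics(np.zeros((3, 3)))


class TestComputeGLCM:
    def test_constant_window_single_entry(self):
        w = np.full((3, 3, 3), 5, dtype=int)
        g = compute_glcm(w, n_levels=8)
        assert g.matrix[5, 5] == pytest.approx(1.0)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_stripe_pattern_hand_enumeration(self):
        w = np.zeros((3, 3, 3), dtype=int)
        w[1, :, :] = 1  # pattern 0,1,0 along x
        g = compute_glcm(w, n_levels=2, offsets=[(1, 0, 0)])
        assert g.matrix[0, 1] == pytest.approx(0.5)
        assert g.matrix[1, 0] == pytest.approx(0.5)
        assert g.matrix[0, 0] == g.matrix[1, 1] == 0.0

    def test_row_sums_are_marginals(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            w = rng.integers(0, 6, size=(3, 3, 3))
            g = compute_glcm(w, n_levels=6)
            oracle = oracle_glcm(w, 6, DEFAULT_OFFSETS)
            np.testing.assert_allclose(g.matrix.sum(axis=1), oracle.sum(axis=1),
                                       atol=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        w = rng.integers(0, 4, size=(3, 3, 3))
        g = compute_glcm(w, n_levels=4)
        np.testing.assert_allclose(g.matrix, g.matrix.T, atol=1e-15)

    def test_level_out_of_range_rejected(self):
        w = np.full((3, 3, 3), 9, dtype=int)
        with pytest.raises(ValueError, match="range"):
            compute_glcm(w, n_levels=8)


class TestHaralickFeatures:
    def test_two_diagonal_entries_hand_values(self):
        g = GLCM(np.array([[0.5, 0.0], [0.0, 0.5]]), offsets=(), normalized=True)
        h = haralick_features(g)
        assert h.contrast == 0.0
        assert h.dissimilarity == 0.0
        assert h.homogeneity == pytest.approx(1.0)
        assert h.energy == pytest.approx(0.5)
        assert h.max_probability == pytest.approx(0.5)
        assert h.entropy == pytest.approx(1.0)
        assert h.difference_entropy == pytest.approx(0.0)
        assert h.sum_entropy == pytest.approx(1.0)

    def test_single_entry_conventions(self):
        m = np.zeros((4, 4))
        m[2, 2] = 1.0
        h = haralick_features(GLCM(m, offsets=(), normalized=True))
        assert h.entropy == 0.0
        assert h.energy == pytest.approx(1.0)
        assert h.correlation == 0.0  # sigma = 0 convention

    def test_unnormalized_rejected(self):
        g = GLCM(np.ones((2, 2)), offsets=(), normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            haralick_features(g)

    def test_oracle_equivalence_on_random_windows(self):
        """All nine features match a brute-force implementation to 1e-10
        on >= 100 random quantized windows."""
        rng = np.random.default_rng(42)
        for _ in range(120):
            w = rng.integers(0, 32, size=(3, 3, 3))
            g = compute_glcm(w, n_levels=32)
            got = haralick_features(g)
            exp = oracle_haralick(oracle_glcm(w, 32, DEFAULT_OFFSETS))
            for name, val in exp.items():
                assert getattr(got, name) == pytest.approx(val, abs=1e-10), name


class TestBatchAgreement:
    """The vectorized batch path must equal the scalar reference functions."""

    def test_batch_stats_match_scalar(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(100, 50, size=(8, 8, 8))
        coords = np.argwhere(np.ones((8, 8, 8), bool))[::7]
        wins = _gather_windows(vol, coords)
        batch = _batch_stats(wins, (0.43, 0.43, 0.5))
        padded = np.pad(vol, 1, mode="edge")
        for r, (x, y, z) in enumerate(coords):
            w = padded[x:x + 3, y:y + 3, z:z + 3]
            sv = window_statistics(w, (0.43, 0.43, 0.5))
            for f in ("mean", "median", "q1", "q3", "sd", "kurtosis",
                      "skewness", "grad_x", "grad_y", "grad_z"):
                assert batch[f][r] == pytest.approx(getattr(sv, f)), f

    def test_batch_haralick_match_scalar(self):
        rng = np.random.default_rng(2)
        vol = rng.integers(0, 16, size=(8, 8, 8))
        coords = np.argwhere(np.ones((8, 8, 8), bool))[::11]
        wins = _gather_windows(vol, coords).astype(np.int64)
        batch = _batch_haralick(wins, 16)
        padded = np.pad(vol, 1, mode="edge")
        for r, (x, y, z) in enumerate(coords):
            w = padded[x:x + 3, y:y + 3, z:z + 3]
            h = haralick_features(compute_glcm(w, 16))
            for f in batch:
                assert batch[f][r] == pytest.approx(getattr(h, f), abs=1e-10), f


class TestExtractFeatureTable:
    def test_row_count_equals_mask_voxels(self, healthy_case_small):
        case = healthy_case_small
        skel = extract_skeleton(case.mask)
        local_frames(skel)
        quant = quantize_hu(case.ct)
        table = extract_feature_table(case.ct, quant, case.mask, skel)
        assert len(table) == int(case.mask.data.sum())
        assert not table.isna().any().any()

    def test_calcified_rows_brighter_than_lumen(self, diseased_case_small):
        case = diseased_case_small
        skel = extract_skeleton(case.mask)
        local_frames(skel)
        quant = quantize_hu(case.ct)
        table = extract_feature_table(case.ct, quant, case.mask, skel)
        calc = case.truth.lesions[0]
        calcset = {tuple(v) for v in np.asarray(calc.voxels)}
        is_calc = np.array([(x, y, z) in calcset
                            for x, y, z in table[["x", "y", "z"]].to_numpy()])
        assert is_calc.sum() > 0
        assert (table.loc[is_calc, "mean"].mean()
                > table.loc[~is_calc, "mean"].mean())

    def test_deterministic(self, healthy_case_small):
        case = healthy_case_small
        skel = extract_skeleton(case.mask)
        local_frames(skel)
        quant = quantize_hu(case.ct)
        t1 = extract_feature_table(case.ct, quant, case.mask, skel)
        t2 = extract_feature_table(case.ct, quant, case.mask, skel)
        assert t1.equals(t2)

    def test_constant_tube_features_spatially_constant(self):
        """Noise-free constant-HU tube: interior texture features constant."""
        spec = small_spec(seed=0)
        spec.noise_sd = 0.0
        spec.hu_params = {k: (m, 0.0) for k, (m, s) in spec.hu_params.items()}
        case = generate_phantom(spec)
        skel = extract_skeleton(case.mask)
        local_frames(skel)
        quant = quantize_hu(case.ct)
        table = extract_feature_table(case.ct, quant, case.mask, skel)
        # interior voxels: window entirely inside the mask
        from scipy import ndimage
        interior = ndimage.binary_erosion(case.mask.data.astype(bool),
                                          structure=np.ones((3, 3, 3), bool))
        sel = interior[table["x"], table["y"], table["z"]]
        assert sel.sum() > 50
        for col in ("mean", "sd", "entropy", "energy", "contrast"):
            vals = table.loc[sel, col].to_numpy()
            assert np.allclose(vals, vals[0]), col

    def test_empty_mask_rejected(self, healthy_case_small):
        case = healthy_case_small
        skel = extract_skeleton(case.mask)
        empty = VesselMask(np.zeros_like(case.mask.data), case.mask.spacing)
        quant = quantize_hu(case.ct)
        with pytest.raises(ValueError, match="empty mask"):
            extract_feature_table(case.ct, quant, empty, skel)
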