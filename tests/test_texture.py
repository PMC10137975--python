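import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btrkit.image_core import quantize
from btrkit.texture import (FEATURE_NAMES, GLCM, GLCMConfig, coarseness,
                            compute_glcm, feature_vector,
                            first_order_features, glcm_features)


def _first_order_oracle(img, L):
    """Direct flattened-loop moments and histogram entropy."""
    vals = list(img.ravel())
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    sd = var ** 0.5
    counts = [0] * L
    for v in vals:
        counts[min(int(v * L), L - 1)] += 1
    ent = -sum((c / n) * np.log2(c / n) for c in counts if c)
    if sd == 0:
        return mean, sd, ent, 0.0, 0.0
    sk = sum(((v - mean) / sd) ** 3 for v in vals) / n
    ku = sum(((v - mean) / sd) ** 4 for v in vals) / n
    return mean, sd, ent, sk, ku


def _glcm_oracle(q, L, offsets, symmetric):
    """Exhaustive pair enumeration."""
    m, n = q.shape
    mat = np.zeros((L, L))
    total = 0
    for dr, dc in offsets:
        for r in range(m):
            for c in range(n):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < m and 0 <= c2 < n:
                    mat[q[r, c], q[r2, c2]] += 1
                    total += 1
                    if symmetric:
                        mat[q[r2, c2], q[r, c]] += 1
                        total += 1
    return mat, total


def _glcm_features_oracle(p):
    """Direct double sums over the matrix entries."""
    L = p.shape[0]
    en = con = idm = dm = 0.0
    mx = my = 0.0
    for x in range(L):
        for y in range(L):
            en += p[x, y] ** 2
            con += (x - y) ** 2 * p[x, y]
            idm += p[x, y] / (1 + (x - y) ** 2)
            dm += abs(x - y) * p[x, y]
            mx += x * p[x, y]
            my += y * p[x, y]
    sx = sum((x - mx) ** 2 * p[x, y] for x in range(L)
             for y in range(L)) ** 0.5
    sy = sum((y - my) ** 2 * p[x, y] for x in range(L)
             for y in range(L)) ** 0.5
    if sx * sy == 0:
        corr = 0.0
    else:
        corr = sum((x - mx) * (y - my) * p[x, y]
                   for x in range(L) for y in range(L)) / (sx * sy)
    return en, con, idm, dm, corr


class TestFirstOrder:
    def test_constant_image_degenerate_conventions(self):
        m, sd, ent, sk, ku = first_order_features(np.full((4, 4), 0.5), 8)
        assert (m, sd, ent, sk, ku) == (0.5, 0.0, 0.0, 0.0, 0.0)

    def test_two_point_distribution(self):
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        m, sd, ent, sk, ku = first_order_features(img, 2)
        assert m == pytest.approx(0.5)
        assert sd == pytest.approx(0.5)
        assert ent == pytest.approx(1.0)  # one bit

    def test_matches_brute_force_oracle(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        got = first_order_features(img, 8)
        want = _first_order_oracle(img, 8)
        assert np.allclose(got, want, atol=1e-10)


class TestComputeGlcm:
    def test_constant_image_single_entry(self):
        q = np.full((5, 5), 3, dtype=np.int64)
        g = compute_glcm(q, GLCMConfig(levels=8))
        assert g.matrix[3, 3] == pytest.approx(1.0)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_four_by_four_horizontal_pairs(self):
        q = np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                      [2, 2, 3, 3], [2, 2, 3, 3]])
        cfg = GLCMConfig(levels=4, offsets=((0, 1),), symmetric=False,
                         normalize=False)
        g = compute_glcm(q, cfg)
        want, total = _glcm_oracle(q, 4, ((0, 1),), False)
        assert np.array_equal(g.matrix, want)
        assert g.pair_count == total == 12

    def test_matches_enumeration_oracle_all_offsets(self, rng):
        q = rng.integers(0, 8, (16, 16))
        for symmetric in (True, False):
            cfg = GLCMConfig(levels=8, symmetric=symmetric, normalize=True)
            g = compute_glcm(q, cfg)
            want, total = _glcm_oracle(q, 8, cfg.offsets, symmetric)
            assert np.allclose(g.matrix, want / total, atol=1e-12)

    def test_agrees_with_skimage_reference(self, rng):
        from skimage.feature import graycomatrix

        q = rng.integers(0, 8, (12, 12)).astype(np.uint8)
        # angle 0 in the reference corresponds to offset (0, 1)
        ref = graycomatrix(q, [1], [0], levels=8, symmetric=True,
                           normed=True)[:, :, 0, 0]
        cfg = GLCMConfig(levels=8, offsets=((0, 1),), symmetric=True)
        assert np.allclose(compute_glcm(q, cfg).matrix, ref, atol=1e-12)

    def test_symmetric_matrix_is_symmetric(self, rng):
        q = rng.integers(0, 5, (10, 10))
        g = compute_glcm(q, GLCMConfig(levels=5, symmetric=True))
        assert np.allclose(g.matrix, g.matrix.T)

    def test_offset_reaching_outside_errors(self):
        q = np.zeros((3, 3), dtype=np.int64)
        with pytest.raises(ValueError):
            compute_glcm(q, GLCMConfig(levels=2, offsets=((0, 5),)))

    def test_rejects_zero_offset_and_bad_levels(self):
        with pytest.raises(ValueError):
            GLCMConfig(offsets=((0, 0),))
        with pytest.raises(ValueError):
            GLCMConfig(levels=1)


class TestGlcmFeatures:
    def test_single_entry_matrix(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        en, con, idm, dm, corr = glcm_features(
            GLCM(p, GLCMConfig(levels=4), 1))
        assert (en, con, idm, dm) == (1.0, 0.0, 1.0, 0.0)
        assert corr == 0.0  # degenerate marginals

    def test_antidiagonal_two_entry_matrix(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        en, con, idm, dm, corr = glcm_features(
            GLCM(p, GLCMConfig(levels=2), 2))
        assert en == pytest.approx(0.5)
        assert con == pytest.approx(1.0)
        assert idm == pytest.approx(0.5)
        assert dm == pytest.approx(1.0)
        assert corr == pytest.approx(-1.0)

    def test_matches_double_loop_oracle(self, rng):
        p = rng.uniform(0, 1, (8, 8))
        p /= p.sum()
        got = glcm_features(GLCM(p, GLCMConfig(levels=8), 0))
        want = _glcm_features_oracle(p)
        assert np.allclose(got, want, atol=1e-12)

    def test_rejects_unnormalized_matrix(self):
        with pytest.raises(ValueError):
            glcm_features(GLCM(np.ones((3, 3)), GLCMConfig(levels=3), 9))

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10 ** 9))
    def test_correlation_bounded_on_random_glcms(self, seed):
        r = np.random.default_rng(seed)
        p = r.uniform(0, 1, (6, 6))
        p /= p.sum()
        corr = glcm_features(GLCM(p, GLCMConfig(levels=6), 0))[4]
        assert -1.0 - 1e-9 <= corr <= 1.0 + 1e-9


class TestCoarseness:
    def test_two_by_two_ones(self):
        c = coarseness(np.ones((2, 2)))
        assert c.value == pytest.approx(0.25)  # 2^-4 * 4
        assert c.log2_value == pytest.approx(-2.0)

    def test_all_zero_image(self):
        c = coarseness(np.zeros((4, 4)))
        assert c.value == 0.0
        assert c.log2_value == float("-inf")

    def test_log_form_finite_at_realistic_size(self, rng):
        img = rng.uniform(0.1, 0.9, (255, 255))
        c = coarseness(img)
        # literal prefactor 2^-510 underflows any useful magnitude; the log
        # form stays finite and equals log2(sum f) - (m + n)
        assert np.isfinite(c.log2_value)
        assert c.log2_value == pytest.approx(np.log2(img.sum()) - 510)


class TestFeatureVector:
    def test_constant_image_degenerate_vector(self):
        fv = feature_vector(np.full((8, 8), 0.5))
        arr = fv.as_array()
        # (mean, sd, entropy, skew, kurt, energy, contrast, idm, dm, corr)
        assert np.allclose(arr[:10], [0.5, 0, 0, 0, 0, 1, 0, 1, 0, 0])
        assert arr[10] == coarseness(np.full((8, 8), 0.5)).value

    def test_deterministic(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        assert np.array_equal(feature_vector(img).as_array(),
                              feature_vector(img).as_array())

    def test_transpose_invariant_with_default_offsets(self, rng):
        img = rng.uniform(0, 1, (24, 24))
        a = feature_vector(img).as_array()
        b = feature_vector(img.T).as_array()
        assert np.allclose(a, b, atol=1e-12)

    def test_fixed_feature_order(self):
        assert FEATURE_NAMES == ("mean", "sd", "entropy", "skewness",
                                 "kurtosis", "energy", "contrast", "idm",
                                 "dm", "correlation", "coarseness")

    def test_tumor_and_normal_phantoms_separate(self):
        from btrkit.phantom import PhantomSpec, generate_phantom

        tumor_img, _, _ = generate_phantom(PhantomSpec(seed=0, tumor=True))
        normal_img, _, _ = generate_phantom(PhantomSpec(seed=0, tumor=False))
        ft = feature_vector(tumor_img)
        fn = feature_vector(normal_img)
        assert abs(ft.contrast - fn.contrast) > 1e-3
        assert abs(ft.energy - fn.energy) > 1e-3
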