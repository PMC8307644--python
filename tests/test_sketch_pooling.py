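"""Bilinear pooling oracle and the Tensor-Sketch approximation guarantees."""

import numpy as np
import pytest

from drgrade import (
    bilinear_inner_product,
    bilinear_pool,
    compact_bilinear_pool,
    count_sketch,
    make_sketch_projection,
    normalize_descriptor,
    tensor_sketch,
)
from drgrade.sketch_pooling import SketchProjection


class TestBilinearPool:
    def test_single_position_outer_product(self):
        fm = np.array([[[1.0, 2.0]]])
        np.testing.assert_allclose(bilinear_pool(fm, fm), [[1, 2], [2, 4]])

    def test_zero_stream_annihilates(self, rng):
        fm_b = rng.normal(size=(3, 3, 4))
        np.testing.assert_allclose(
            bilinear_pool(np.zeros((3, 3, 2)), fm_b), np.zeros((2, 4))
        )

    def test_orthonormal_positions_sum_to_identity(self):
        fm = np.array([[[1.0, 0.0], [0.0, 1.0]]])   # two positions e1, e2
        np.testing.assert_allclose(bilinear_pool(fm, fm), np.eye(2))

    def test_self_stream_descriptor_is_symmetric_psd(self, rng):
        fm = rng.normal(size=(4, 5, 6))
        b = bilinear_pool(fm, fm)
        np.testing.assert_allclose(b, b.T)
        assert np.linalg.eigvalsh(b).min() > -1e-10

    def test_spatial_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="[Ss]patial|shape"):
            bilinear_pool(rng.normal(size=(2, 2, 3)), rng.normal(size=(3, 2, 3)))


class TestBilinearInnerProduct:
    @pytest.mark.parametrize("x,y,expected", [
        ((1.0, 0.0), (1.0, 1.0), 1.0),   # ⟨x,y⟩² = 1
        ((1.0, 0.0), (0.0, 1.0), 0.0),   # orthogonal
        ((1.0, 1.0), (1.0, 1.0), 4.0),   # (1+1)²
    ])
    def test_single_position_kernel_values(self, x, y, expected):
        fx = np.array(x).reshape(1, 1, 2)
        fy = np.array(y).reshape(1, 1, 2)
        assert bilinear_inner_product(fx, fx, fy, fy) == pytest.approx(expected)

    def test_matches_sum_of_squared_inner_products(self, rng):
        """⟨B(X),B(Y)⟩ from explicit matrices equals Σ_s Σ_u ⟨x_s, y_u⟩²."""
        fx = rng.normal(size=(3, 4, 5))
        fy = rng.normal(size=(2, 6, 5))
        direct = bilinear_inner_product(fx, fx, fy, fy)
        xs = fx.reshape(-1, 5)
        ys = fy.reshape(-1, 5)
        brute = sum((xs[s] @ ys[u]) ** 2 for s in range(len(xs)) for u in range(len(ys)))
        assert direct == pytest.approx(brute, rel=1e-12)


class TestSketchProjection:
    def test_tables_in_range(self):
        proj = make_sketch_projection(4, 4, 16, seed=0)
        for h in proj.hash_tables:
            assert h.shape == (4,) and h.min() >= 0 and h.max() < 16
        for s in proj.sign_tables:
            assert set(np.unique(s)) <= {-1.0, 1.0}

    def test_deterministic_regeneration(self):
        a = make_sketch_projection(8, 12, 64, seed=3)
        b = make_sketch_projection(8, 12, 64, seed=3)
        for ta, tb in zip(a.hash_tables + a.sign_tables,
                          b.hash_tables + b.sign_tables):
            np.testing.assert_array_equal(ta, tb)

    def test_distinct_seeds_give_distinct_tables(self):
        tables = [
            tuple(make_sketch_projection(8, 8, 64, seed=s).hash_tables[0])
            for s in range(100)
        ]
        assert len(set(tables)) >= 99

    def test_invalid_dimension_rejected(self):
        with pytest.raises(ValueError):
            make_sketch_projection(4, 4, 0, seed=0)

    def test_serialization_round_trip(self, tmp_path):
        proj = make_sketch_projection(6, 9, 128, seed=11)
        proj.save(tmp_path / "proj.json")
        loaded = SketchProjection.load(tmp_path / "proj.json")
        np.testing.assert_array_equal(proj.hash_tables[0], loaded.hash_tables[0])
        np.testing.assert_array_equal(proj.sign_tables[1], loaded.sign_tables[1])


class TestCountSketch:
    def test_direct_evaluation(self):
        out = count_sketch(np.array([2.0]), np.array([3]), np.array([-1.0]), 8)
        expected = np.zeros(8)
        expected[3] = -2.0
        np.testing.assert_allclose(out, expected)

    def test_zero_vector_maps_to_zero(self):
        proj = make_sketch_projection(5, 5, 16, seed=0)
        np.testing.assert_allclose(
            count_sketch(np.zeros(5), proj.hash_tables[0], proj.sign_tables[0], 16),
            np.zeros(16),
        )

    def test_linearity(self, rng):
        proj = make_sketch_projection(10, 10, 32, seed=2)
        h, s = proj.hash_tables[0], proj.sign_tables[0]
        a, b = rng.normal(size=10), rng.normal(size=10)
        np.testing.assert_allclose(
            count_sketch(a + b, h, s, 32),
            count_sketch(a, h, s, 32) + count_sketch(b, h, s, 32),
            atol=1e-12,
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_sketch(np.ones(3), np.array([0, 1]), np.array([1.0, 1.0]), 4)


class TestTensorSketch:
    def test_zero_input_annihilates(self, rng):
        proj = make_sketch_projection(6, 6, 32, seed=0)
        out = tensor_sketch(np.zeros(6), rng.normal(size=6), proj)
        np.testing.assert_allclose(out, np.zeros(32))

    def test_fft_matches_direct_circular_convolution(self, rng):
        proj = make_sketch_projection(8, 8, 17, seed=4)   # odd d stresses rfft
        x, y = rng.normal(size=8), rng.normal(size=8)
        s1 = count_sketch(x, proj.hash_tables[0], proj.sign_tables[0], 17)
        s2 = count_sketch(y, proj.hash_tables[1], proj.sign_tables[1], 17)
        direct = np.array([
            sum(s1[j] * s2[(k - j) % 17] for j in range(17)) for k in range(17)
        ])
        np.testing.assert_allclose(tensor_sketch(x, y, proj), direct, atol=1e-10)

    def test_unbiased_kernel_estimate(self, rng):
        """E⟨φ(x,y), φ(x,y)⟩ = ⟨x,x⟩·⟨y,y⟩ = 1 for unit vectors."""
        x = rng.normal(size=16)
        x /= np.linalg.norm(x)
        vals = []
        for seed in range(500):
            proj = make_sketch_projection(16, 16, 64, seed=seed)
            phi = tensor_sketch(x, x, proj)
            vals.append(phi @ phi)
        assert abs(np.mean(vals) - 1.0) < 0.05

    def test_dimension_mismatch_rejected(self, rng):
        proj = make_sketch_projection(6, 6, 32, seed=0)
        with pytest.raises(ValueError):
            tensor_sketch(rng.normal(size=5), rng.normal(size=6), proj)


class TestCompactBilinearPool:
    def test_zero_maps_give_zero_descriptor(self):
        proj = make_sketch_projection(3, 3, 16, seed=0)
        out = compact_bilinear_pool(np.zeros((2, 2, 3)), np.zeros((2, 2, 3)), proj)
        np.testing.assert_allclose(out, np.zeros(16))

    def test_single_position_equals_tensor_sketch(self, rng):
        proj = make_sketch_projection(5, 7, 32, seed=1)
        fa = rng.normal(size=(1, 1, 5))
        fb = rng.normal(size=(1, 1, 7))
        np.testing.assert_allclose(
            compact_bilinear_pool(fa, fb, proj),
            tensor_sketch(fa[0, 0], fb[0, 0], proj),
        )

    def test_position_additivity(self, rng):
        """Pooling a union of position sets equals the sum of poolings."""
        proj = make_sketch_projection(4, 4, 32, seed=5)
        fa = rng.normal(size=(2, 3, 4))
        fb = rng.normal(size=(2, 3, 4))
        full = compact_bilinear_pool(fa, fb, proj)
        parts = (compact_bilinear_pool(fa[:1], fb[:1], proj)
                 + compact_bilinear_pool(fa[1:], fb[1:], proj))
        np.testing.assert_allclose(full, parts, atol=1e-10)

    def test_approximates_bilinear_inner_product(self, rng):
        """Median relative error vs the exact kernel is modest at d=1024."""
        fa = rng.normal(size=(4, 4, 8))
        fb = rng.normal(size=(4, 4, 8))
        oracle = bilinear_inner_product(fa, fa, fb, fb)
        errs = []
        for seed in range(50):
            proj = make_sketch_projection(8, 8, 1024, seed=seed)
            approx = compact_bilinear_pool(fa, fa, proj) @ compact_bilinear_pool(fb, fb, proj)
            errs.append(abs(approx - oracle) / abs(oracle))
        assert np.median(errs) < 0.20


class TestNormalizeDescriptor:
    def test_signed_sqrt_then_unit_length(self):
        out = normalize_descriptor(np.array([4.0, 0.0, -4.0]))
        np.testing.assert_allclose(out, np.array([2.0, 0.0, -2.0]) / np.sqrt(8.0))
        assert np.linalg.norm(out) == pytest.approx(1.0)

    def test_unit_basis_vector_is_fixed_point(self):
        e = np.array([0.0, 1.0, 0.0])
        np.testing.assert_allclose(normalize_descriptor(e), e)

    def test_zero_vector_unchanged(self):
        np.testing.assert_allclose(normalize_descriptor(np.zeros(5)), np.zeros(5))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            normalize_descriptor(np.array([1.0, np.inf]))
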