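import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ctqa
from ctqa.scf import GradientField, SCFParams

from conftest import make_image


def ramp_image(step_per_px=5.0, spacing=1.0, n=32):
    cols = np.arange(n, dtype=float)
    return make_image(np.tile(step_per_px * cols, (n, 1)), (spacing, spacing))


class TestGradient:
    def test_linear_ramp_units(self):
        g = ctqa.compute_gradient(ramp_image(5.0, spacing=1.0))
        inner = (slice(1, -1), slice(1, -1))
        np.testing.assert_allclose(g.gx[inner], 5.0)
        np.testing.assert_allclose(g.gy[inner], 0.0)
        np.testing.assert_allclose(g.magnitude[inner], 5.0)

    def test_spacing_scales_gradient(self):
        # 5 HU per pixel at 0.5 mm spacing -> 10 HU/mm
        g = ctqa.compute_gradient(ramp_image(5.0, spacing=0.5))
        np.testing.assert_allclose(g.magnitude[1:-1, 1:-1], 10.0)

    def test_constant_image_zero_magnitude(self, flat_image):
        g = ctqa.compute_gradient(flat_image)
        np.testing.assert_array_equal(g.magnitude, 0.0)

    def test_angle_range_half_open(self):
        g = ctqa.compute_gradient(ramp_image(-3.0))
        assert g.angle.min() >= -np.pi
        assert g.angle.max() < np.pi


class TestStructureTensor:
    def _field(self, gx, gy):
        gx = np.asarray(gx, float)
        gy = np.asarray(gy, float)
        return GradientField(gx, gy, np.hypot(gx, gy), np.arctan2(gy, gx))

    def test_pure_x_gradient_axis_aligned(self):
        t = ctqa.compute_structure_tensor(self._field(np.full((8, 8), 3.0), np.zeros((8, 8))))
        np.testing.assert_allclose(t.t11, 9.0)
        np.testing.assert_allclose(t.t12, 0.0)
        np.testing.assert_allclose(t.lambda1, 9.0)
        np.testing.assert_allclose(t.vt_angle, 0.0)

    def test_diagonal_gradient(self):
        t = ctqa.compute_structure_tensor(self._field(np.ones((4, 4)), np.ones((4, 4))))
        np.testing.assert_allclose(t.lambda1, 2.0)
        np.testing.assert_allclose(t.vt_angle, np.pi / 4)

    def test_pure_y_gradient_vertical_eigenvector(self):
        t = ctqa.compute_structure_tensor(self._field(np.zeros((4, 4)), np.full((4, 4), 2.0)))
        np.testing.assert_allclose(t.vt_angle, np.pi / 2)

    @given(st.integers(0, 2**20 - 1))
    def test_closed_form_matches_numeric_eigensolver(self, bits):
        rng = np.random.default_rng(bits)
        t = ctqa.compute_structure_tensor(
            self._field(rng.normal(size=(16, 16)), rng.normal(size=(16, 16))),
            SCFParams(tensor_smooth_sigma_px=1.0),  # smoothed tensors are full rank
        )
        T = np.stack([np.stack([t.t11, t.t12], -1), np.stack([t.t12, t.t22], -1)], -2)
        w, V = np.linalg.eigh(T)
        np.testing.assert_allclose(t.lambda1, w[..., 1], atol=1e-10)
        ang = np.mod(np.arctan2(V[..., 1, 1], V[..., 0, 1]), np.pi)
        d = np.abs(t.vt_angle - ang)
        assert np.minimum(d, np.pi - d).max() < 1e-7

    def test_lambda1_at_least_mean_trace(self):
        rng = np.random.default_rng(3)
        t = ctqa.compute_structure_tensor(
            self._field(rng.normal(size=(16, 16)), rng.normal(size=(16, 16))))
        assert np.all(t.lambda1 >= (t.t11 + t.t22) / 2 - 1e-12)


class TestEdginess:
    def test_weight_combinations(self):
        gx = np.full((4, 4), 3.0)
        grad = GradientField(gx, np.zeros_like(gx), np.abs(gx), np.zeros_like(gx))
        tensor = ctqa.compute_structure_tensor(grad)
        cases = [((1.0, 0.0), 3.0), ((0.0, 1.0), 9.0), ((0.5, 0.5), 6.0)]
        for (w1, w2), expected in cases:
            p = SCFParams(omega1=w1, omega2=w2)
            np.testing.assert_allclose(ctqa.edginess(grad, tensor, p), expected)


class TestDirectionalEntropy:
    def test_single_orientation_zero(self):
        assert ctqa.directional_entropy(np.full(40, 0.3), n_bins=8) == 0.0

    def test_uniform_bins_maximum(self):
        centers = -np.pi + (np.arange(8) + 0.5) * (2 * np.pi / 8)
        angles = np.repeat(centers, 5)
        assert ctqa.directional_entropy(angles, n_bins=8) == pytest.approx(np.log(8))

    def test_two_equal_bins(self):
        angles = np.array([0.1] * 8 + [np.pi / 2 + 0.1] * 8)
        assert ctqa.directional_entropy(angles, n_bins=8) == pytest.approx(np.log(2))

    def test_empty_after_exclusion_returns_zero(self):
        assert ctqa.directional_entropy(np.zeros(5), valid=np.zeros(5, bool)) == 0.0

    @given(st.integers(0, 2**20 - 1), st.sampled_from([4, 8, 16]),
           st.sampled_from(["full_circle", "half_circle"]))
    def test_bounds(self, bits, n_bins, domain):
        rng = np.random.default_rng(bits)
        hi = np.pi if domain == "half_circle" else np.pi * 2
        angles = rng.uniform(0, hi, size=rng.integers(1, 200)) - (0 if domain == "half_circle" else np.pi)
        h = ctqa.directional_entropy(angles, n_bins=n_bins, domain=domain)
        assert 0.0 <= h <= np.log(n_bins) + 1e-12


class TestSCFMap:
    def test_constant_image_scf_zero(self, flat_image):
        scf = ctqa.compute_scf_map(flat_image, np.ones((32, 32), bool))
        assert np.all(scf.values[scf.defined] == 0.0)
        assert scf.defined.all()

    def test_undefined_outside_mask(self, flat_image):
        mask = np.zeros((32, 32), bool)
        mask[8:24, 8:24] = True
        scf = ctqa.compute_scf_map(flat_image, mask)
        assert np.isnan(scf.values[~mask]).all()
        assert np.isfinite(scf.values[mask]).all()

    def test_coherent_edge_scores_above_noise(self):
        # a straight 100 HU edge vs same-contrast pure noise, 9x9 windows
        rng = np.random.default_rng(5)
        edge = np.zeros((9, 9))
        edge[:, 5:] = 100.0
        noise = rng.normal(0, 100 / 2, (9, 9))
        mask = np.ones((17, 17), bool)
        vals = []
        for win in (edge, noise):
            img = make_image(np.pad(win, 4, mode="edge"))
            scf = ctqa.compute_scf_map(img, mask)
            vals.append(scf.values[8, 8])
        assert vals[0] > vals[1]

    def test_scf_nonnegative_on_phantom(self, analyzed):
        _, _, scf, _ = analyzed
        assert np.all(scf.values[scf.defined] >= 0.0)

    @given(st.integers(-2000, 2000))
    def test_offset_invariance_exact(self, offset):
        bundle = ctqa.generate_phantom(ctqa.PhantomSpec(seed=4, quantize_hu=True))
        eroded = ctqa.erode_mask(bundle.organ_mask)
        a = ctqa.compute_scf_map(bundle.image, eroded)
        shifted = ctqa.CTImage(bundle.image.pixels + float(offset),
                               bundle.image.spacing_row_mm, bundle.image.spacing_col_mm)
        b = ctqa.compute_scf_map(shifted, eroded)
        np.testing.assert_array_equal(a.values[a.defined], b.values[b.defined])

    def test_edge_pixels_outrank_parenchyma(self, analyzed):
        bundle, eroded, scf, _ = analyzed
        edges = bundle.truth_edge_pixels & eroded
        interior = eroded & ~bundle.truth_edge_pixels & scf.defined
        assert scf.values[edges].mean() > scf.values[interior].mean()
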