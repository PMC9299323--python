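import numpy as np
import pytest

import ctqa

from conftest import make_image


def analyze(bundle):
    eroded = ctqa.erode_mask(bundle.organ_mask)
    scf = ctqa.compute_scf_map(bundle.image, eroded)
    return scf, ctqa.partition_regions(scf, eroded)


class TestNoiseLevel:
    def test_constant_image_zero_noise(self, analyzed):
        bundle, _, _, part = analyzed
        flat = make_image(np.zeros(bundle.image.shape), (0.7, 0.7))
        res = ctqa.noise_level(flat, part, seed=1)
        assert res.noise_hu == 0.0

    def test_reproducible_given_seed(self, analyzed):
        bundle, _, _, part = analyzed
        a = ctqa.noise_level(bundle.image, part, seed=42)
        b = ctqa.noise_level(bundle.image, part, seed=42)
        assert a.noise_hu == b.noise_hu
        assert a.roi_centers == b.roi_centers

    def test_seed_changes_rois_not_scale(self, analyzed):
        bundle, _, _, part = analyzed
        a = ctqa.noise_level(bundle.image, part, seed=1)
        b = ctqa.noise_level(bundle.image, part, seed=2)
        assert a.roi_centers != b.roi_centers
        assert abs(a.noise_hu - b.noise_hu) / a.noise_hu < 0.25

    def test_rois_inside_rh(self, analyzed):
        bundle, _, _, part = analyzed
        res = ctqa.noise_level(bundle.image, part, seed=3)
        half = res.roi_size_px // 2
        for r, c in res.roi_centers:
            assert part.r_h[r - half : r + half + 1, c - half : c + half + 1].all()

    def test_proportional_recovery_across_sigma(self):
        """Measured noise scales linearly with true sigma (r > 0.99).

        The absolute level is biased low: R_H selects the calmest decile
        of the same noise field being measured, so the conditional SD
        underestimates sigma by a scale factor that is constant across
        noise levels (scale equivariance of the SCF selection).
        """
        truths, measured = [], []
        for sigma in (5.0, 10.0, 20.0, 40.0):
            for seed in range(3):
                b = ctqa.generate_phantom(ctqa.PhantomSpec(noise_sigma_hu=sigma, seed=seed))
                _, part = analyze(b)
                truths.append(sigma)
                measured.append(ctqa.noise_level(b.image, part, seed=seed + 50).noise_hu)
        ag = ctqa.agreement_stats(measured, truths)
        assert ag.pearson_r > 0.99
        ratio = np.array(measured) / np.array(truths)
        assert 0.6 < ratio.mean() < 1.0  # biased low, but bounded
        assert ratio.std() / ratio.mean() < 0.15  # stable scale factor

    def test_scale_equivariance(self, analyzed):
        bundle, _, _, part = analyzed
        base = ctqa.noise_level(bundle.image, part, seed=9).noise_hu
        doubled = make_image(bundle.image.pixels * 2.0, (0.7, 0.7))
        assert ctqa.noise_level(doubled, part, seed=9).noise_hu == pytest.approx(2 * base)

    def test_fragmented_rh_raises(self, flat_image):
        from ctqa.partition import RegionPartition
        r_h = np.zeros((32, 32), bool)
        r_h[4, 4] = True  # cannot host any 5x5 ROI
        part = RegionPartition(r_h=r_h, r_s=np.zeros((32, 32), bool),
                               eroded_mask=np.ones((32, 32), bool), p_low=0, p_high=1)
        with pytest.raises(RuntimeError, match="fragmented"):
            ctqa.noise_level(flat_image, part, seed=0)


class TestStructureSharpness:
    def test_mean_of_constant_scf(self, analyzed):
        _, _, scf, part = analyzed
        const = ctqa.SCFMap(np.where(np.isfinite(scf.values), 7.5, np.nan), 9, scf.params)
        assert ctqa.structure_sharpness(const, part).ssi_raw == pytest.approx(7.5)

    def test_calibration_intercept_at_zero(self, analyzed):
        _, _, scf, part = analyzed
        zero = ctqa.SCFMap(np.where(np.isfinite(scf.values), 0.0, np.nan), 9, scf.params)
        res = ctqa.structure_sharpness(zero, part)
        assert res.ssi_calibrated == pytest.approx(4.2813)

    def test_empty_rs_flagged(self, analyzed):
        _, eroded, scf, _ = analyzed
        from ctqa.partition import RegionPartition
        part = RegionPartition(r_h=eroded.copy(), r_s=np.zeros_like(eroded),
                               eroded_mask=eroded, p_low=0, p_high=0, degenerate=True)
        assert not ctqa.structure_sharpness(scf, part).valid

    def test_blur_ladder_strictly_decreasing(self):
        ssi = []
        for b in ctqa.generate_sharpness_series(ctqa.PhantomSpec(seed=21), blur_sigmas=[0.5, 1.0, 1.6]):
            scf, part = analyze(b)
            ssi.append(ctqa.structure_sharpness(scf, part).ssi_raw)
        assert ssi[0] > ssi[1] > ssi[2]

    def test_unsharp_ladder_strictly_increasing(self):
        ssi = []
        for b in ctqa.generate_sharpness_series(ctqa.PhantomSpec(seed=21, edge_sigma_px=0.8),
                                                unsharp_amounts=[1.5, 2.5]):
            scf, part = analyze(b)
            ssi.append(ctqa.structure_sharpness(scf, part).ssi_raw)
        assert ssi[1] > ssi[0]


class TestCalibrationFit:
    def test_exact_line(self):
        pairs = [(x, 2 * x + 1) for x in (0.0, 1.0, 2.0, 5.0)]
        a, b, r = ctqa.fit_ssi_calibration(pairs)
        assert (a, b, r) == (pytest.approx(2), pytest.approx(1), pytest.approx(1))

    def test_recovers_default_coefficients(self):
        xs = np.linspace(0.5, 4.0, 12)
        pairs = [(x, 6.1398 * x + 4.2813) for x in xs]
        a, b, r = ctqa.fit_ssi_calibration(pairs)
        assert a == pytest.approx(6.1398)
        assert b == pytest.approx(4.2813)
        assert r == pytest.approx(1.0)

    def test_anticorrelated_line(self):
        pairs = [(x, -x) for x in (0.0, 1.0, 3.0)]
        assert ctqa.fit_ssi_calibration(pairs)[2] == pytest.approx(-1.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ctqa.fit_ssi_calibration([(1.0, 0.0), (1.0, 1.0), (1.0, 2.0)])


class TestStructureAlteration:
    def test_iid_difference_near_one(self, analyzed):
        bundle, _, _, part = analyzed
        rng = np.random.default_rng(17)
        target = make_image(bundle.image.pixels + rng.normal(0, 8, bundle.image.shape), (0.7, 0.7))
        res = ctqa.structure_alteration(bundle.image, target, part)
        assert res.sai == pytest.approx(1.0, abs=0.1)

    def test_blurring_denoiser_above_one(self, analyzed):
        bundle, _, _, part = analyzed
        target = ctqa.apply_denoiser(bundle, "blurring", 1.5)
        assert ctqa.structure_alteration(bundle.image, target, part).sai > 1.0

    def test_structure_sparing_denoiser_below_one(self, analyzed):
        bundle, _, _, part = analyzed
        target = ctqa.apply_denoiser(bundle, "ideal", 0.5)
        assert ctqa.structure_alteration(bundle.image, target, part).sai < 1.0

    def test_identical_images_flagged(self, analyzed):
        bundle, _, _, part = analyzed
        res = ctqa.structure_alteration(bundle.image, ctqa.apply_denoiser(bundle, "none"), part)
        assert not res.valid

    def test_scale_invariance(self, analyzed):
        bundle, _, _, part = analyzed
        target = ctqa.apply_denoiser(bundle, "blurring", 1.0)
        base = ctqa.structure_alteration(bundle.image, target, part).sai
        ref3 = make_image(bundle.image.pixels * 3, (0.7, 0.7))
        tgt3 = make_image(target.pixels * 3, (0.7, 0.7))
        assert ctqa.structure_alteration(ref3, tgt3, part).sai == pytest.approx(base)

    def test_shape_mismatch_rejected(self, analyzed, flat_image):
        bundle, _, _, part = analyzed
        with pytest.raises(ValueError):
            ctqa.structure_alteration(bundle.image, flat_image, part)
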