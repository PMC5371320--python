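"""Mutual information, NMI, noise calibration, and variability reports."""

import numpy as np
import pytest

from conftest import make_classified
from hestain.assign import TissueClass
from hestain.metrics import (
    PAPER_SIGMA_GRID,
    NoiseParams,
    VariabilityReport,
    add_hsv_noise,
    inter_image_variability,
    intra_image_variability,
    mutual_information,
    nmi,
    noise_nmi_curve,
)
from hestain.normalize import (
    TargetColors,
    normalize_image,
    normalize_without_deviation,
    structure_means,
)


def _brute_force_mi(x_codes, y_codes):
    """Independent oracle: direct sum over the joint histogram, in bits."""
    n = len(x_codes)
    mi = 0.0
    for xv in set(x_codes):
        for yv in set(y_codes):
            pxy = sum(1 for a, b in zip(x_codes, y_codes) if a == xv and b == yv) / n
            if pxy == 0:
                continue
            px = sum(1 for a in x_codes if a == xv) / n
            py = sum(1 for b in y_codes if b == yv) / n
            mi += pxy * np.log2(pxy / (px * py))
    return mi


class TestMutualInformation:
    def test_constant_marginal_gives_zero(self):
        x = np.full((8, 8), 0.3)
        y = np.linspace(0, 1, 64).reshape(8, 8)
        assert mutual_information(x, y, bins=16) == 0.0

    def test_fair_bit_gives_one_bit(self):
        x = np.tile([0.1, 0.9], 32).reshape(8, 8)
        assert mutual_information(x, x, bins=4) == pytest.approx(1.0)

    def test_matches_brute_force_on_toy_rasters(self):
        """Estimator equals the hand-computed sum over a 4x4 joint histogram."""
        rng = np.random.default_rng(5)
        levels = np.array([0.05, 0.3, 0.55, 0.8])
        x = rng.choice(levels, size=(4, 4))
        y = np.where(rng.random((4, 4)) < 0.5, x, rng.choice(levels, size=(4, 4)))
        bins = 4
        xc = np.clip((x.ravel() * bins).astype(int), 0, bins - 1)
        yc = np.clip((y.ravel() * bins).astype(int), 0, bins - 1)
        expected = _brute_force_mi(list(xc), list(yc))
        assert mutual_information(x, y, bins=bins) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(9)
        x, y = rng.random((2, 32, 32))
        bins = 8
        mi = mutual_information(x, y, bins=bins)
        hx = mutual_information(x, x, bins=bins)
        hy = mutual_information(y, y, bins=bins)
        assert 0.0 <= mi <= min(hx, hy) + 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            mutual_information(np.zeros((4, 4)), np.zeros((5, 5)))


class TestNMI:
    def test_self_nmi_is_exactly_one(self, tile):
        from hestain.color import rgb_to_hsv

        hsv = rgb_to_hsv(tile[0])
        scores = nmi(hsv, hsv)
        assert scores["value"] == 1.0
        assert scores["hue_sat"] == 1.0

    def test_constant_image_is_undefined(self):
        x = np.tile(np.array([0.5, 0.5, 0.5]), (8, 8, 1))
        with pytest.raises(ValueError, match="NMI undefined"):
            nmi(x, x)

    def test_independent_images_score_near_zero(self):
        rng = np.random.default_rng(3)
        x, y = rng.random((2, 100, 100, 3))
        scores = nmi(x, y, bins=16)
        assert scores["value"] < 0.15  # plug-in bias bound at this n and binning

    def test_deviation_normalized_beats_flat_mapping(self, pipeline_result):
        """Keeping dd preserves more of the original image's information
        than flat class->target mapping."""
        hsv, classified = pipeline_result.hsv, pipeline_result.classified
        means = structure_means(hsv, classified)
        shifted = TargetColors(
            colors={c: np.clip(m + [0.02, 0.05, -0.05], 0, 1) for c, m in means.items()}
        )
        with_dd = normalize_image(hsv, classified, shifted)
        flat = normalize_without_deviation(hsv, classified, shifted)
        s_dd, s_flat = nmi(hsv, with_dd), nmi(hsv, flat)
        assert s_flat["value"] < s_dd["value"]
        assert s_flat["hue_sat"] < s_dd["hue_sat"]


class TestNoise:
    def test_sigma_zero_is_identity(self, tile):
        from hestain.color import rgb_to_hsv

        hsv = rgb_to_hsv(tile[0])
        np.testing.assert_array_equal(add_hsv_noise(hsv, sigma=0.0, seed=1), hsv)

    def test_same_seed_same_output(self, tile):
        from hestain.color import rgb_to_hsv

        hsv = rgb_to_hsv(tile[0])
        a = add_hsv_noise(hsv, NoiseParams(sigma=0.5, seed=7))
        b = add_hsv_noise(hsv, NoiseParams(sigma=0.5, seed=7))
        np.testing.assert_array_equal(a, b)
        c = add_hsv_noise(hsv, NoiseParams(sigma=0.5, seed=8))
        assert not np.array_equal(a, c)

    def test_empirical_noise_std_matches_sigma(self):
        """Per-channel std of (out - in) ~ sigma within 2% at ~1e6 samples,
        on a mid-gray image where no clipping occurs."""
        hsv = np.tile(np.array([0.5, 0.5, 0.5]), (600, 600, 1))
        sigma = 0.01
        noisy = add_hsv_noise(hsv, sigma=sigma, seed=11)
        diff = noisy - hsv
        for ch in range(3):
            assert np.std(diff[..., ch]) == pytest.approx(sigma, rel=0.02)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseParams(sigma=-0.1)

    def test_noise_curve_zero_sigma_anchor(self, tile):
        from hestain.color import rgb_to_hsv

        hsv = rgb_to_hsv(tile[0])
        assert noise_nmi_curve(hsv, sigmas=(0.0,), seed=1) == [(0.0, 1.0, 1.0)]

    def test_noise_curve_nonincreasing_on_standard_grid(self):
        """Requires a tile large enough that plug-in MI bias (which grows
        with occupied joint-histogram cells over sample count) stays small."""
        import hestain as hs
        from hestain.color import rgb_to_hsv

        layout = hs.generate_layout((512, 512), seed=41)
        rgb, _ = hs.render_tile(layout, hs.StainProfile(sigma=0.02), seed=42)
        hsv = rgb_to_hsv(rgb)
        curve = noise_nmi_curve(hsv, PAPER_SIGMA_GRID, seed=2)
        vals = [c[1] for c in curve]
        huesats = [c[2] for c in curve]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(huesats, huesats[1:]))


class TestVariability:
    def _nuclei_image(self, value):
        hsv = np.tile(np.array([0.7, 0.5, value]), (4, 4, 1))
        return hsv, make_classified(np.full((4, 4), int(TissueClass.NUCLEI)))

    def test_identical_cohort_has_zero_std(self):
        pair = self._nuclei_image(0.5)
        report = inter_image_variability([pair, pair, pair])
        assert all(v == 0.0 for v in report[TissueClass.NUCLEI].values())

    def test_two_point_population_std(self):
        """Value means 0.4 and 0.6 give population std 0.1 (divide by n)."""
        report = inter_image_variability(
            [self._nuclei_image(0.4), self._nuclei_image(0.6)]
        )
        assert report[TissueClass.NUCLEI]["val"] == pytest.approx(0.1)

    def test_white_hue_is_omitted(self):
        hsv = np.tile(np.array([0.1, 0.02, 0.97]), (4, 4, 1))
        classified = make_classified(np.full((4, 4), int(TissueClass.WHITE)))
        report = inter_image_variability([(hsv, classified)] * 2)
        assert "hue" not in report[TissueClass.WHITE]
        intra = intra_image_variability(hsv, classified)
        assert "hue" not in intra[TissueClass.WHITE]

    def test_flat_mapped_image_has_zero_intra_variability(self, pipeline_result):
        flat = normalize_without_deviation(
            pipeline_result.hsv,
            pipeline_result.classified,
            TargetColors(
                colors=structure_means(pipeline_result.hsv, pipeline_result.classified)
            ),
        )
        intra = intra_image_variability(flat, pipeline_result.classified)
        for chans in intra.values():
            for v in chans.values():
                # circstd of a constant sample bottoms out near 1e-8
                assert v == pytest.approx(0.0, abs=1e-7)

    def test_normalization_preserves_intra_variability(self, pipeline_result):
        """Unclipped dd-normalization leaves within-structure stds unchanged."""
        hsv, classified = pipeline_result.hsv, pipeline_result.classified
        means = structure_means(hsv, classified)
        shifted = TargetColors(
            colors={c: np.clip(m + [0.01, 0.03, -0.03], 0.1, 0.9) for c, m in means.items()}
        )
        out = normalize_image(hsv, classified, shifted)
        pre = intra_image_variability(hsv, classified)
        post = intra_image_variability(out, classified)
        for cls in pre:
            if cls == TissueClass.WHITE:
                continue  # white saturation clips at 0
            for chan in pre[cls]:
                assert post[cls][chan] == pytest.approx(pre[cls][chan], abs=1e-3)

    def test_report_min_reduction(self):
        pre = {TissueClass.NUCLEI: {"hue": 0.1, "sat": 0.2, "val": 0.3}}
        post = {TissueClass.NUCLEI: {"hue": 0.01, "sat": 0.01, "val": 0.05}}
        report = VariabilityReport(pre=pre, post=post)
        assert report.min_reduction((TissueClass.NUCLEI,)) == pytest.approx(6.0)
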