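"""Histogram fitting and Bhattacharyya contrast machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import swirindex as sx
from swirindex.bimodality import BimodalityConfig, Histogram


def gaussian_overlap(mu1, s1, mu2, s2):
    """Independent oracle: C_B = integral of sqrt(p·q) over the real line."""
    val, _ = quad(
        lambda x: np.sqrt(norm.pdf(x, mu1, s1) * norm.pdf(x, mu2, s2)),
        -np.inf, np.inf, limit=200,
    )
    return val


class TestBhattacharyya:
    def test_identical_distributions_zero(self):
        assert sx.bhattacharyya_distance(0, 1, 0, 1) == 0.0

    def test_equal_variance_closed_form(self):
        # D_B = (mu1-mu2)^2 / (8 sigma^2) when sigmas agree
        assert sx.bhattacharyya_distance(0, 1, 2, 1) == pytest.approx(0.5)

    def test_unequal_variance_against_integral_oracle(self):
        d = sx.bhattacharyya_distance(0, 1, 1, 2)
        # frozen from the overlap-integral oracle: 0.05 + ln(5/4)/2
        assert d == pytest.approx(0.1615718, abs=1e-6)
        assert math.exp(-d) == pytest.approx(gaussian_overlap(0, 1, 1, 2), abs=1e-9)

    def test_oracle_equivalence_on_random_parameters(self):
        gen = np.random.default_rng(99)
        for _ in range(100):
            mu1, mu2 = gen.uniform(-10, 10, 2)
            s1, s2 = gen.uniform(0.2, 5.0, 2)
            d = sx.bhattacharyya_distance(mu1, s1, mu2, s2)
            assert math.exp(-d) == pytest.approx(
                gaussian_overlap(mu1, s1, mu2, s2), abs=1e-6
            )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(-5, 5), st.floats(0.1, 3), st.floats(-5, 5), st.floats(0.1, 3),
        st.floats(-10, 10), st.floats(0.1, 10),
    )
    def test_affine_invariance(self, mu1, s1, mu2, s2, shift, scale):
        d0 = sx.bhattacharyya_distance(mu1, s1, mu2, s2)
        d1 = sx.bhattacharyya_distance(
            scale * mu1 + shift, scale * s1, scale * mu2 + shift, scale * s2
        )
        assert d1 == pytest.approx(d0, rel=1e-9, abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            sx.bhattacharyya_distance(0, 0.0, 1, 1)

    def test_coefficient_is_exp_minus_distance(self):
        assert sx.bhattacharyya_coefficient(0.0) == 1.0
        assert sx.bhattacharyya_coefficient(5.128) == pytest.approx(0.006, abs=5e-4)
        assert sx.bhattacharyya_coefficient(0.846) == pytest.approx(0.429, abs=5e-4)
        with pytest.raises(ValueError):
            sx.bhattacharyya_coefficient(-0.1)


class TestSigmaFromC:
    def test_values(self):
        assert sx.sigma_from_c(math.sqrt(2)) == pytest.approx(1.0)
        assert sx.sigma_from_c(2.0) == pytest.approx(math.sqrt(2))
        with pytest.raises(ValueError):
            sx.sigma_from_c(0.0)

    def test_matches_second_moment_of_curve(self):
        """Numerically integrate the normalized exp(-((x-b)/c)^2) density:
        its variance must equal c^2/2 = sigma_from_c(c)^2."""
        b, c = 3.0, 1.7
        f = lambda x: np.exp(-(((x - b) / c) ** 2))
        z, _ = quad(f, -np.inf, np.inf)
        m2, _ = quad(lambda x: (x - b) ** 2 * f(x), -np.inf, np.inf)
        assert m2 / z == pytest.approx(sx.sigma_from_c(c) ** 2, rel=1e-9)


class TestClassifyContrast:
    @pytest.mark.parametrize(
        "d_b, expected",
        [(0.286, "poor"), (0.536, "poor"), (0.599, "poor"),
         (0.6, "indeterminate"), (1.0, "indeterminate"),
         (1.142, "moderate"), (3.0, "moderate"), (5.128, "strong")],
    )
    def test_thresholds(self, d_b, expected):
        assert sx.classify_contrast(d_b) == expected

    def test_monotone_in_d_b(self):
        order = {"poor": 0, "indeterminate": 1, "moderate": 2, "strong": 3}
        grid = np.linspace(0, 6, 601)
        ranks = [order[sx.classify_contrast(d)] for d in grid]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))


class TestImageHistogram:
    def test_constant_image_single_bin(self):
        img = sx.ScalarImage(np.full((10, 10), 3.0), np.ones((10, 10), bool))
        h = sx.image_histogram(img, bins=10)
        assert h.counts.sum() == 100
        assert (h.counts > 0).sum() == 1

    def test_counts_conserved(self, rng):
        img = sx.ScalarImage(rng.normal(size=(50, 50)), np.ones((50, 50), bool))
        h = sx.image_histogram(img, bins=32, value_range=(-10, 10))
        assert h.counts.sum() == h.n_pixels == 2500

    def test_standard_normal_mean_recovered(self):
        gen = np.random.default_rng(5)
        vals = gen.standard_normal(100_000)
        img = sx.ScalarImage(vals.reshape(400, 250), np.ones((400, 250), bool))
        h = sx.image_histogram(img, bins=256)
        mean = np.average(h.bin_centers, weights=h.counts)
        assert abs(mean) < 3 / np.sqrt(100_000)

    def test_robust_range_excludes_tails(self, rng):
        vals = np.concatenate([rng.normal(size=9_990), np.full(10, 1e6)])
        img = sx.ScalarImage(vals.reshape(100, 100), np.ones((100, 100), bool))
        h = sx.image_histogram(img)
        assert h.n_excluded >= 10
        assert h.bin_centers[-1] < 100

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            sx.ScalarImage(np.ones((3, 3)), np.zeros((3, 3), bool))


class TestFitBimodal:
    def _exact_histogram(self, params, lo=0.0, hi=30.0, n=200):
        x = np.linspace(lo, hi, n)
        y = np.zeros_like(x)
        for a, b, c in params:
            y += a * np.exp(-(((x - b) / c) ** 2))
        return Histogram(bin_centers=x, counts=np.round(y).astype(int),
                         n_pixels=int(np.round(y).sum()))

    def test_exact_parameter_recovery(self):
        # counts synthesized from known parameters; integer rounding of the
        # 1e6-scale curve limits attainable accuracy to ~1e-6 relative
        params = [(1_000_000.0, 8.0, 1.5), (600_000.0, 20.0, 3.0)]
        fit = sx.fit_bimodal(self._exact_histogram(params))
        assert fit.converged
        for comp, (a, b, c) in zip(fit.components, params):
            assert comp.a == pytest.approx(a, rel=1e-5)
            assert comp.b == pytest.approx(b, rel=1e-6)
            assert comp.c == pytest.approx(c, rel=1e-5)
        assert fit.r_squared > 0.999999

    def test_mixture_sample_recovery(self):
        gen = np.random.default_rng(17)
        vals = np.concatenate([gen.normal(10, 1, 50_000), gen.normal(20, 2, 50_000)])
        img = sx.ScalarImage(vals.reshape(400, 250), np.ones((400, 250), bool))
        fit = sx.fit_bimodal(sx.image_histogram(img, bins=256))
        lo, hi = fit.components
        assert lo.b == pytest.approx(10.0, rel=0.01)
        assert hi.b == pytest.approx(20.0, rel=0.01)
        assert lo.sigma == pytest.approx(1.0, rel=0.05)
        assert hi.sigma == pytest.approx(2.0, rel=0.05)

    def test_single_gaussian_degenerates_gracefully(self):
        """A unimodal histogram yields either two strongly overlapping
        components or a fit flagged effectively unimodal — and never a
        usable non-poor contrast."""
        gen = np.random.default_rng(23)
        vals = gen.standard_normal(50_000)
        img = sx.ScalarImage(vals.reshape(250, 200), np.ones((250, 200), bool))
        fit = sx.fit_bimodal(sx.image_histogram(img, bins=128))
        lo, hi = fit.components
        overlapping = hi.b - lo.b < max(lo.sigma, hi.sigma)
        assert overlapping or fit.minor_area_fraction < 0.10
        res = sx.bimodality_report(img, config=BimodalityConfig(bins=128))
        assert res.contrast_class == "poor" or not res.usable

    def test_components_sorted_by_center(self):
        params = [(500.0, 22.0, 2.0), (800.0, 6.0, 1.0)]
        fit = sx.fit_bimodal(self._exact_histogram(params))
        assert fit.components[0].b < fit.components[1].b

    def test_too_few_bins_rejected(self):
        h = Histogram(np.arange(5.0), np.array([1, 2, 3, 2, 1]), 9)
        with pytest.raises(ValueError):
            sx.fit_bimodal(h)


class TestBimodalityReport:
    def test_separated_patches_strong(self, rng):
        vals = np.concatenate([
            rng.normal(10, 0.5, 2000), rng.normal(30, 0.5, 2000)
        ]).reshape(40, 100)
        img = sx.ScalarImage(vals, np.ones((40, 100), bool))
        res = sx.bimodality_report(img)
        assert res.contrast_class == "strong"
        assert res.usable

    def test_pure_noise_poor(self, rng):
        img = sx.ScalarImage(rng.normal(100, 5, (40, 100)), np.ones((40, 100), bool))
        res = sx.bimodality_report(img)
        assert res.contrast_class == "poor"

    def test_coefficient_consistency(self, rng):
        img = sx.ScalarImage(rng.normal(0, 1, (40, 40)), np.ones((40, 40), bool))
        res = sx.bimodality_report(img)
        assert res.c_b == pytest.approx(math.exp(-res.d_b), rel=1e-12)

    def test_mask_intersection(self, rng):
        vals = rng.normal(size=(20, 20))
        img = sx.ScalarImage(vals, np.ones((20, 20), bool))
        half = np.zeros((20, 20), bool)
        half[:10] = True
        res = sx.bimodality_report(img, mask=half, config=BimodalityConfig(bins=16))
        total = sum(comp.area for comp in res.fit.components)
        assert total > 0
        with pytest.raises(ValueError):
            sx.bimodality_report(img, mask=np.zeros((20, 20), bool))
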