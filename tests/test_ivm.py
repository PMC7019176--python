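"""Fluorescence corrections, weighted statistics and colocalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdtvasc import (FluorescenceImage, WeightedSummary, corrected_density,
                     spearman_coloc, tnr, weighted_mean)
from pdtvasc.ivm import synthetic_coloc_pair
from .conftest import spearman_oracle


def _img(pixels, **kw):
    kw.setdefault("pixel_area", 1.0)
    return FluorescenceImage(pixels=np.asarray(pixels, dtype=float), **kw)


class TestCorrectedDensity:
    def test_pure_background_is_zero(self):
        img = _img(np.full((10, 10), 7.0), dark_current=7.0)
        m = corrected_density(img, np.ones((10, 10), bool))
        assert m.integrated_density_per_5000um2 == 0.0

    def test_uniform_signal_matches_brute_force(self):
        # 5000 um^2 ROI (50x100 px at 1 um^2/px), uniform dark + 10
        pixels = np.full((50, 100), 12.0)
        img = _img(pixels, dark_current=2.0)
        roi = np.ones((50, 100), bool)
        m = corrected_density(img, roi)
        brute = np.sum(pixels[roi] - 2.0) * 5000.0 / (roi.sum() * 1.0)
        assert m.integrated_density_per_5000um2 == pytest.approx(brute)
        assert m.integrated_density_per_5000um2 == pytest.approx(10.0 * 5000.0)

    def test_reference_factor_halves_exactly(self):
        pixels = np.random.default_rng(0).uniform(5, 50, (20, 20))
        roi = np.ones((20, 20), bool)
        m1 = corrected_density(_img(pixels, reference_factor=1.0), roi)
        m2 = corrected_density(_img(pixels, reference_factor=2.0), roi)
        assert m2.integrated_density_per_5000um2 == pytest.approx(
            m1.integrated_density_per_5000um2 / 2.0)

    def test_negative_result_clipped_and_flagged(self):
        img = _img(np.full((5, 5), 1.0), dark_current=0.0, autofluorescence=1e6)
        m = corrected_density(img, np.ones((5, 5), bool))
        assert m.integrated_density_per_5000um2 == 0.0
        assert m.clipped

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            corrected_density(_img(np.ones((5, 5))), np.zeros((5, 5), bool))


class TestTnr:
    def test_equal_tissues_give_unity(self):
        s = WeightedSummary(wmean=10.0, wsd=1.0, n=3)
        assert tnr(s, s).ratio == pytest.approx(1.0)

    def test_error_propagation_formula(self):
        t = WeightedSummary(wmean=30.0, wsd=3.0, n=4)
        n = WeightedSummary(wmean=10.0, wsd=1.0, n=4)
        res = tnr(t, n)
        assert res.ratio == pytest.approx(3.0)
        assert res.sd == pytest.approx(np.sqrt((3.0 / 10.0) ** 2 +
                                               (30.0 * 1.0 / 100.0) ** 2))

    def test_zero_denominator_rejected(self):
        t = WeightedSummary(wmean=30.0, wsd=3.0, n=4)
        z = WeightedSummary(wmean=0.0, wsd=1.0, n=4)
        with pytest.raises(ValueError):
            tnr(t, z)

    def test_constructed_threefold_contrast(self):
        rng = np.random.default_rng(8)
        tumor_vals, normal_vals = [], []
        for _ in range(5):
            tum = rng.normal(30.0, 1.0, (40, 40))
            nor = rng.normal(10.0, 1.0, (40, 40))
            roi = np.ones((40, 40), bool)
            tumor_vals.append(corrected_density(_img(tum), roi).integrated_density_per_5000um2)
            normal_vals.append(corrected_density(_img(nor), roi).integrated_density_per_5000um2)
        t = weighted_mean(tumor_vals, [1.0] * 5)
        n = weighted_mean(normal_vals, [1.0] * 5)
        assert tnr(t, n).ratio == pytest.approx(3.0, rel=0.05)


class TestWeightedMean:
    def test_equal_sds_reduce_to_arithmetic_mean(self):
        res = weighted_mean([1.0, 2.0, 6.0], [0.5, 0.5, 0.5])
        assert res.wmean == pytest.approx(3.0)

    def test_hand_arithmetic_example(self):
        res = weighted_mean([10.0, 20.0], [1.0, 2.0])
        assert res.wmean == pytest.approx(12.0)
        assert res.wsd == pytest.approx(np.sqrt(0.8))

    def test_single_value_passthrough(self):
        res = weighted_mean([5.0], [0.7])
        assert res.wmean == 5.0
        assert res.wsd == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean([], [])

    def test_zero_sd_capped_not_infinite(self):
        res = weighted_mean([10.0, 20.0], [0.0, 1.0])
        assert np.isfinite(res.wmean)
        assert res.wmean == pytest.approx(15.0)  # capped to equal weights

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(0.01, 10)),
                    min_size=1, max_size=8))
    def test_mean_between_min_and_max(self, pairs):
        vals = [p[0] for p in pairs]
        sds = [p[1] for p in pairs]
        res = weighted_mean(vals, sds)
        assert min(vals) - 1e-9 <= res.wmean <= max(vals) + 1e-9


class TestSpearmanColoc:
    def test_monotone_transform_gives_plus_one(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0, 100, (12, 12))
        r = np.exp(g / 40.0)  # strictly increasing transform
        res = spearman_coloc(_img(g), _img(r), np.ones((12, 12), bool))
        assert res.spearman_rho == pytest.approx(1.0)

    def test_antitone_gives_minus_one(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(0, 100, (12, 12))
        res = spearman_coloc(_img(g), _img(-g), np.ones((12, 12), bool))
        assert res.spearman_rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_brute_force(self):
        rng = np.random.default_rng(42)
        g = rng.integers(0, 20, (5, 10)).astype(float)  # ties present
        r = rng.integers(0, 20, (5, 10)).astype(float)
        roi = np.ones((5, 10), bool)
        res = spearman_coloc(_img(g), _img(r), roi)
        assert res.spearman_rho == pytest.approx(
            spearman_oracle(g.ravel(), r.ravel()), abs=1e-12)

    def test_constant_channel_is_missing(self):
        g = np.full((5, 5), 3.0)
        r = np.arange(25.0).reshape(5, 5)
        res = spearman_coloc(_img(g), _img(r), np.ones((5, 5), bool))
        assert np.isnan(res.spearman_rho)

    def test_dark_current_invariance(self):
        # dark subtraction is a shift; Spearman is rank-based, so invariant
        rng = np.random.default_rng(3)
        g = rng.uniform(10, 100, (8, 8))
        r = rng.uniform(10, 100, (8, 8))
        roi = np.ones((8, 8), bool)
        r1 = spearman_coloc(_img(g), _img(r), roi)
        r2 = spearman_coloc(_img(g + 5, dark_current=5.0),
                            _img(r + 9, dark_current=9.0), roi)
        assert r1.spearman_rho == pytest.approx(r2.spearman_rho, abs=1e-12)

    def test_rho_increases_with_colocalized_fraction(self):
        rhos = []
        for f in np.linspace(0.0, 1.0, 10):
            g, r = synthetic_coloc_pair(colocalized_fraction=float(f), seed=77)
            res = spearman_coloc(_img(g), _img(r), np.ones(g.shape, bool))
            rhos.append(res.spearman_rho)
        # monotone over 10 levels (rank test): strictly increasing ranks
        assert np.all(np.diff(rhos) > 0)
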