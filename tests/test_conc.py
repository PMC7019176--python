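"""Concentration conversion, enhancement rule and AUC against oracles."""

import numpy as np
import pytest

from pdtvasc import (DceSeries, NoiseSpec, R1Map, ScanProtocol, auc_map,
                     classify_enhancement, default_truth, fit_t1_vfa,
                     signal_to_concentration, sigma_for_snr, simulate_study,
                     spgr_signal)
from pdtvasc.phantom import tissue_concentration_map
from .conftest import enhancement_rule_oracle


def _series_from_r1(r1_curves, protocol, m0=1000.0):
    """Build a DceSeries + matching R1Map from per-voxel R1(t) curves."""
    r1_curves = np.atleast_2d(r1_curves)
    n_vox, n_frames = r1_curves.shape
    shape = (n_vox, 1, 1)
    prot = protocol
    sig = spgr_signal(m0, 1.0 / r1_curves, prot.fa_dce, prot.tr_dce)
    series = DceSeries(signal=sig.reshape(shape + (n_frames,)),
                       times=prot.frame_times[:n_frames], protocol=prot,
                       mask=np.ones(shape, bool))
    r1map = R1Map(r1_pre=np.full(shape, r1_curves[:, 0].reshape(shape[:3])),
                  m0=np.full(shape, m0),
                  fit_residual=np.zeros(shape),
                  valid=np.ones(shape, bool))
    return series, r1map


class TestSignalToConcentration:
    def test_delta_r1_of_relaxivity_gives_one_millimolar(self, protocol):
        r1_pre = 0.5
        r1 = np.full(protocol.n_frames, r1_pre)
        r1[100:] = r1_pre + protocol.r1_relaxivity  # Delta R1 = 3.53 s^-1
        series, r1map = _series_from_r1(r1, protocol)
        maps = signal_to_concentration(series, r1map)
        assert maps.conc[0, 0, 0, 150] == pytest.approx(1.0, abs=1e-9)

    def test_constant_signal_gives_zero_concentration(self, protocol):
        r1 = np.full(protocol.n_frames, 0.6)
        series, r1map = _series_from_r1(r1, protocol)
        maps = signal_to_concentration(series, r1map)
        assert np.all(maps.conc[0, 0, 0] == 0.0)
        assert not maps.enhanced[0, 0, 0]

    def test_noiseless_phantom_round_trip(self, protocol, aif):
        truth = default_truth(shape=(16, 16, 5))
        vfa, dce = simulate_study(truth, protocol, aif, NoiseSpec(sigma=0.0))
        r1map = fit_t1_vfa(vfa)
        maps = signal_to_concentration(dce, r1map)
        tis = truth.tissue_mask
        expected = tissue_concentration_map(truth.ktrans_map[tis],
                                            truth.ve_map[tis], aif,
                                            protocol.frame_times, protocol.t0)
        assert np.nanmax(np.abs(maps.conc[tis] - expected)) < 1e-6

    def test_pre_injection_concentration_exactly_zero_noiseless(self, protocol, aif):
        truth = default_truth(shape=(16, 16, 5))
        _, dce = simulate_study(truth, protocol, aif, NoiseSpec(sigma=0.0))
        vfa, _ = simulate_study(truth, protocol, aif, NoiseSpec(sigma=0.0))
        maps = signal_to_concentration(dce, fit_t1_vfa(vfa))
        pre = maps.times < maps.t0
        tis = truth.tissue_mask
        assert np.all(maps.conc[tis][:, pre] == 0.0)

    def test_invalid_voxels_excluded(self, protocol):
        r1 = np.full((2, protocol.n_frames), 0.6)
        series, r1map = _series_from_r1(r1, protocol)
        r1map.valid[1] = False
        maps = signal_to_concentration(series, r1map)
        assert np.all(np.isnan(maps.conc[1, 0, 0]))
        assert not maps.enhanced[1, 0, 0]


class TestClassifyEnhancement:
    def test_zero_baseline_sd_tie_rule(self):
        times = np.array([0.0, 1.0, 2.0, 3.0])
        curve = np.array([0.0, 0.0, 0.5, 0.5])
        assert classify_enhancement(curve, times, t0=2.0)

    def test_direct_rule_application(self):
        # pre SD = 0.05 mM, post median = 0.09 < 2 * 0.05 -> non-enhanced
        d = 0.05 * np.sqrt(2.0) / 2.0
        times = np.array([0.0, 1.0, 2.0, 3.0])
        curve = np.array([-d, d, 0.09, 0.09])
        assert np.std(curve[:2], ddof=1) == pytest.approx(0.05)
        assert not classify_enhancement(curve, times, t0=2.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            classify_enhancement([0.0, 1.0], np.array([0.0, 1.0]), t0=0.5)

    def test_agrees_with_literal_oracle_on_random_curves(self):
        rng = np.random.default_rng(7)
        times = np.arange(60) * 3.5
        t0 = 60.0
        agree = 0
        n = 1000
        for _ in range(n):
            curve = rng.normal(0.0, 0.1, times.size)
            if rng.random() < 0.5:
                curve[times >= t0] += rng.uniform(0.0, 0.5)
            got = classify_enhancement(curve, times, t0)
            assert got == enhancement_rule_oracle(curve, times, t0)
            agree += 1
        assert agree == n

    def test_core_detection_under_noise(self, protocol, aif):
        truth = default_truth()
        sigma = sigma_for_snr(truth, protocol, 20.0)
        vfa, dce = simulate_study(truth, protocol, aif,
                                  NoiseSpec("rician", sigma, 11))
        maps = signal_to_concentration(dce, fit_t1_vfa(vfa))
        core = truth.nonenhanced_core_mask & maps.valid
        rim = truth.tumor_mask & ~truth.nonenhanced_core_mask & maps.valid
        assert (~maps.enhanced[core]).mean() >= 0.95
        assert (~maps.enhanced[rim]).mean() <= 0.05


class TestAucMap:
    def test_zero_curve_zero_auc(self, protocol):
        r1 = np.full(protocol.n_frames, 0.6)
        series, r1map = _series_from_r1(r1, protocol)
        maps = signal_to_concentration(series, r1map)
        assert auc_map(maps)[0, 0, 0] == 0.0

    def test_rectangle_window(self, protocol):
        r1 = np.full(protocol.n_frames, 0.5)
        r1[:] = 0.5 + protocol.r1_relaxivity  # constant C = 1 mM
        series, r1map = _series_from_r1(r1, protocol, m0=1000.0)
        # baseline equals the enhanced plateau here, so C(t) = 0; instead
        # integrate a synthetic constant concentration directly
        maps = signal_to_concentration(series, r1map)
        maps.conc[...] = 1.0
        auc = auc_map(maps, window=(200.0, 260.0))
        assert auc[0, 0, 0] == pytest.approx(60.0, rel=1e-9)

    def test_empty_window_rejected(self, protocol):
        r1 = np.full(protocol.n_frames, 0.6)
        series, r1map = _series_from_r1(r1, protocol)
        maps = signal_to_concentration(series, r1map)
        with pytest.raises(ValueError):
            auc_map(maps, window=(500.0, 400.0))

    def test_matches_fine_grid_quadrature(self, protocol, aif):
        from .conftest import tofts_convolution_oracle

        t = protocol.frame_times
        curve = tofts_convolution_oracle(0.25, 0.4, aif, t, protocol.t0)
        r1 = np.full(protocol.n_frames, 0.6)
        series, r1map = _series_from_r1(r1, protocol)
        maps = signal_to_concentration(series, r1map)
        maps.conc[0, 0, 0] = curve
        auc = auc_map(maps)[0, 0, 0]
        # fine-grid oracle integral of the same model curve
        tf = np.arange(protocol.t0, t[-1], 0.01)
        cf = tofts_convolution_oracle(0.25, 0.4, aif, tf, protocol.t0)
        oracle = np.trapezoid(cf, tf)
        assert auc == pytest.approx(oracle, rel=0.005)
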