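import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhythmbench.matrix import ExpressionMatrix, SampleDesign
from rhythmbench.methods import (MethodConfig, empirical_jtk, fisher_g_sf,
                                 fisher_integration, jtk_cycle, lomb_scargle,
                                 results_frame, robust_g_periodogram,
                                 run_method_on_matrix, _get_context)
from rhythmbench.kendall import pair_signs
from rhythmbench.preprocess import zscore_normalize
from rhythmbench.waveforms import WaveformSpec, generate_waveform


def _cosine_series(design, phase=0.0, amp=0.5, base=100.0):
    wf = WaveformSpec("cosine", phase=phase, rel_amplitude=amp)
    return base * (1 + amp * generate_waveform(wf, design.times))


class TestJtk:
    def test_perfect_cosine_has_tau_one(self, design12, fast_cfg):
        # on-grid phase: the series ordering matches a reference exactly
        r = jtk_cycle(_cosine_series(design12, phase=0.0), design12, fast_cfg)
        assert r.statistic == pytest.approx(1.0)
        assert r.raw_p < 0.01
        assert abs(r.best_period - 24) <= 4

    def test_constant_series_guard(self, design12, fast_cfg):
        r = jtk_cycle(np.ones(12), design12, fast_cfg)
        assert r.raw_p == 1.0 and r.statistic == 0.0

    def test_raw_p_equals_exhaustive_scan_tail_n6(self, fast_cfg):
        # independent oracle: enumerate all 6! orderings of the series and
        # compare the scan-minimum-p tail with the implementation's raw p
        design = SampleDesign.regular(6, 4.0)
        series = np.array([5.0, 3.0, 6.0, 1.0, 2.0, 4.0])
        r = jtk_cycle(series, design, fast_cfg)
        ctx = _get_context(design, fast_cfg, "jtk")
        p_obs, _, _ = ctx.scan.best(pair_signs(series))
        hits = 0
        for perm in itertools.permutations(series):
            p, _, _ = ctx.scan.best(pair_signs(np.asarray(perm)))
            if p[0] <= p_obs[0]:
                hits += 1
        assert r.raw_p == pytest.approx(hits / math.factorial(6), rel=1e-12)

    def test_invariant_under_zscore_shift(self, design12, fast_cfg):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(5, 1, size=(6, 12))
        m = ExpressionMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(6)],
                                          columns=design12.labels()), design12)
        a = results_frame(run_method_on_matrix(m, "jtk", fast_cfg))
        b = results_frame(run_method_on_matrix(zscore_normalize(m), "jtk", fast_cfg))
        assert np.allclose(a["raw_p"], b["raw_p"])
        assert np.allclose(a["statistic"], b["statistic"])


class TestLombScargle:
    def test_recovers_24h_period(self, design24, fast_cfg):
        rng = np.random.default_rng(0)
        series = _cosine_series(design24) + rng.normal(0, 1, 24)
        r = lomb_scargle(series, design24, fast_cfg)
        assert abs(r.best_period - 24.0) <= 4.0
        assert r.raw_p < 1e-4

    def test_offset_invariance(self, design24, fast_cfg):
        rng = np.random.default_rng(1)
        series = rng.normal(size=24)
        a = lomb_scargle(series, design24, fast_cfg)
        b = lomb_scargle(series + 100.0, design24, fast_cfg)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)
        assert a.raw_p == pytest.approx(b.raw_p, rel=1e-9)

    def test_white_noise_calibration(self, design24, fast_cfg):
        rng = np.random.default_rng(2)
        p = [lomb_scargle(rng.normal(size=24), design24, fast_cfg).raw_p
             for _ in range(400)]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_handles_irregular_times(self, fast_cfg):
        design = SampleDesign((0.0, 3.0, 5.0, 9.0, 14.0, 17.0, 21.0, 23.0),
                              (1,) * 8, (1,) * 8)
        series = np.cos(2 * np.pi * design.times / 24.0)
        r = lomb_scargle(series, design, fast_cfg)
        assert r.raw_p < 0.05


class TestRobustG:
    def test_sinusoid_at_fourier_frequency(self, design24, fast_cfg):
        series = np.cos(2 * np.pi * np.arange(24) * 2.0 / 24.0)  # k=2 of n=24
        r = robust_g_periodogram(series, design24, fast_cfg)
        assert r.statistic > 0.9
        assert r.raw_p < 1e-3
        assert r.best_period == pytest.approx(24.0)

    def test_monotone_transform_invariance(self, design24, fast_cfg):
        rng = np.random.default_rng(5)
        series = rng.normal(size=24)
        a = robust_g_periodogram(series, design24, fast_cfg)
        b = robust_g_periodogram(np.exp(series) + 3, design24, fast_cfg)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert a.raw_p == b.raw_p

    def test_irregular_design_rejected(self, fast_cfg):
        design = SampleDesign((0.0, 3.0, 5.0, 9.0, 14.0, 18.0), (1,) * 6, (1,) * 6)
        with pytest.raises(ValueError, match="regular"):
            robust_g_periodogram(np.arange(6.0), design, fast_cfg)

    def test_fisher_g_flat_spectrum(self):
        # uniform spectrum: g = 1/m sits at the lower support, tail ~ 1
        assert fisher_g_sf(1.0 / 11, 11) == pytest.approx(1.0, abs=1e-6)
        assert fisher_g_sf(0.9, 11) < 1e-8


class TestEmpiricalJtk:
    def test_permutation_floor_and_min_contract(self, design12, fast_cfg):
        series = _cosine_series(design12, phase=1.0)
        r = empirical_jtk(series, design12, fast_cfg)
        # empirical p can never undercut the permutation resolution
        assert r.default_p >= min(1.0 / (fast_cfg.n_permutations + 1),
                                  r.raw_p * 144)
        rng = np.random.default_rng(6)
        noise = rng.normal(size=12)
        r2 = empirical_jtk(noise, design12, fast_cfg)
        assert r2.default_p <= 1.0

    def test_sawtooth_beats_symmetric_scan(self, design24, fast_cfg):
        wf = WaveformSpec("ramp", phase=4.0, asymmetry=0.25, rel_amplitude=0.5)
        series = 100 * (1 + 0.5 * generate_waveform(wf, design24.times))
        re = empirical_jtk(series, design24, fast_cfg)
        rj = jtk_cycle(series, design24, fast_cfg)
        assert re.best_asymmetry == pytest.approx(6.0)
        assert re.statistic > rj.statistic
        assert re.raw_p < rj.raw_p

    def test_low_permutation_warning(self, design12):
        cfg = MethodConfig(n_permutations=50, null_size=5000, seed=1)
        with pytest.warns(UserWarning, match="100 permutations"):
            empirical_jtk(_cosine_series(design12), design12, cfg)


class TestFisherIntegration:
    def test_unit_pvalues_combine_to_one(self):
        assert fisher_integration([1.0, 1.0]) == pytest.approx(1.0)

    def test_matches_chi_square_closed_form(self):
        # closed form for even df: sf(x; 4) = exp(-x/2) (1 + x/2)
        x = -2 * (math.log(0.05) + math.log(0.05))
        expected = math.exp(-x / 2) * (1 + x / 2)
        assert fisher_integration([0.05, 0.05]) == pytest.approx(expected, abs=1e-12)
        assert fisher_integration([0.05, 0.05]) == pytest.approx(0.0175, abs=5e-4)

    def test_single_identity_and_zero_clamp(self):
        assert fisher_integration([0.3]) == 0.3
        with pytest.warns(UserWarning, match="clamped"):
            p = fisher_integration([0.0, 0.5])
        assert 0 <= p < 1e-100


class TestMatrixDriver:
    def test_ids_aligned(self, tiny_matrix, fast_cfg):
        res = run_method_on_matrix(tiny_matrix, "ls", fast_cfg)
        assert [r.gene_id for r in res] == tiny_matrix.gene_ids

    def test_ejtk_deterministic(self, tiny_matrix, fast_cfg):
        a = results_frame(run_method_on_matrix(tiny_matrix, "ejtk", fast_cfg))
        b = results_frame(run_method_on_matrix(tiny_matrix, "ejtk", fast_cfg))
        assert np.allclose(a["default_p"], b["default_p"])

    def test_unknown_method_rejected(self, tiny_matrix, fast_cfg):
        with pytest.raises(ValueError, match="unknown method"):
            run_method_on_matrix(tiny_matrix, "cosopt", fast_cfg)

    def test_jtk_default_is_genewise_bonferroni_bound(self, tiny_matrix, fast_cfg):
        res = results_frame(run_method_on_matrix(tiny_matrix, "jtk", fast_cfg))
        assert np.all(res["default_p"] >= res["raw_p"] - 1e-12)
        assert np.all(res["default_p"] <= 1.0)
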