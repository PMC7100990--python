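import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhythmbench.conservation import (build_benchmark_set, compare_curves,
                                      ks_conserved_vs_not, naive_curve,
                                      proportion_curve)
from rhythmbench.simulate import OrthologMap


def _results(p, raw=None, ids=None):
    ids = ids or [f"g{i}" for i in range(len(p))]
    return pd.DataFrame({"gene_id": ids, "default_p": p,
                         "raw_p": raw if raw is not None else p},
                        index=ids)


def _map(n, a="a", b="b"):
    return OrthologMap([(f"{a}{i}", f"{b}{i}") for i in range(n)])


class TestBenchmarkSet:
    def test_threshold_enumeration(self):
        p = [0.001, 0.2, 0.005, 0.5, 0.009, 0.03]
        res = _results(p, ids=[f"b{i}" for i in range(6)])
        bench = build_benchmark_set(res, _map(6), "m", "p", 0.01)
        assert len(bench.members) == 3
        assert bench.base_rate == pytest.approx(0.5)

    def test_all_pass_base_rate_one(self):
        res = _results([0.001] * 5, ids=[f"b{i}" for i in range(5)])
        bench = build_benchmark_set(res, _map(5), "m", "p", 0.01)
        assert bench.base_rate == 1.0

    def test_empty_set_rejected(self):
        res = _results([0.5] * 5, ids=[f"b{i}" for i in range(5)])
        with pytest.raises(ValueError, match="empty benchmark"):
            build_benchmark_set(res, _map(5), "m", "p", 0.01)

    def test_fdr_kind_applies_bh(self):
        p = [0.001, 0.002, 0.003, 0.5, 0.5, 0.5]
        res = _results(p, ids=[f"b{i}" for i in range(6)])
        bench = build_benchmark_set(res, _map(6), "m", "FDR", 0.01)
        assert len(bench.members) == 3


class TestKs:
    def test_separated_groups_d_one(self):
        n = 40
        omap = _map(n)
        pa = np.concatenate([np.linspace(0.001, 0.01, 10),
                             np.linspace(0.5, 0.99, 30)])
        resA = _results(pa, ids=[f"a{i}" for i in range(n)])
        pb = np.concatenate([np.full(10, 0.001), np.full(30, 0.9)])
        resB = _results(pb, ids=[f"b{i}" for i in range(n)])
        bench = build_benchmark_set(resB, omap, "m", "p", 0.01)
        d, p, direction = ks_conserved_vs_not(resA, omap, bench)
        assert d == pytest.approx(1.0)
        assert direction == -1

    def test_random_membership_is_null(self):
        rng = np.random.default_rng(1)
        n = 2000
        omap = _map(n)
        resA = _results(rng.uniform(size=n), ids=[f"a{i}" for i in range(n)])
        pb = np.where(rng.random(n) < 0.5, 0.001, 0.9)
        resB = _results(pb, ids=[f"b{i}" for i in range(n)])
        bench = build_benchmark_set(resB, omap, "m", "p", 0.01)
        d, p, _ = ks_conserved_vs_not(resA, omap, bench)
        assert p > 0.01
        assert d < 0.05


class TestCurves:
    def test_cumulative_enumeration(self):
        omap = _map(4)
        resA = _results([0.001, 0.01, 0.02, 0.05], ids=[f"a{i}" for i in range(4)])
        resB = _results([0.001, 0.5, 0.001, 0.5], ids=[f"b{i}" for i in range(4)])
        bench = build_benchmark_set(resB, omap, "m", "p", 0.01)
        curve = proportion_curve(resA, omap, bench)
        assert np.allclose(curve.proportions, [1, 0.5, 2 / 3, 0.5])
        assert curve.marker_rank == 2  # two genes at default_p <= 0.01

    def test_all_in_benchmark_constant_one(self):
        omap = _map(4)
        resA = _results([0.01, 0.02, 0.03, 0.04], ids=[f"a{i}" for i in range(4)])
        resB = _results([0.001] * 4, ids=[f"b{i}" for i in range(4)])
        bench = build_benchmark_set(resB, omap, "m", "p", 0.01)
        curve = proportion_curve(resA, omap, bench)
        assert np.all(curve.proportions == 1.0)

    def test_terminal_value_is_base_rate(self):
        rng = np.random.default_rng(2)
        n = 300
        omap = _map(n)
        resA = _results(rng.uniform(size=n), ids=[f"a{i}" for i in range(n)])
        pb = np.where(rng.random(n) < 0.3, 0.001, 0.9)
        resB = _results(pb, ids=[f"b{i}" for i in range(n)])
        bench = build_benchmark_set(resB, omap, "m", "p", 0.01)
        curve = proportion_curve(resA, omap, bench)
        assert curve.proportions[-1] == pytest.approx(bench.base_rate)
        naive = naive_curve(pd.Series(rng.lognormal(5, 1, n),
                                      index=[f"a{i}" for i in range(n)]),
                            omap, bench)
        assert naive.proportions[-1] == pytest.approx(bench.base_rate)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        n = 50
        omap = _map(n)
        p = rng.uniform(size=n)
        resA = _results(p, ids=[f"a{i}" for i in range(n)])
        resA2 = _results(np.sqrt(p), raw=np.sqrt(p), ids=[f"a{i}" for i in range(n)])
        pb = np.where(rng.random(n) < 0.4, 0.001, 0.9)
        resB = _results(pb, ids=[f"b{i}" for i in range(n)])
        bench = build_benchmark_set(resB, omap, "m", "p", 0.01)
        c1 = proportion_curve(resA, omap, bench)
        c2 = proportion_curve(resA2, omap, bench)
        assert np.allclose(c1.proportions, c2.proportions)
        assert c1.gene_ids == c2.gene_ids

    def test_naive_enumeration_and_all_zero(self):
        omap = _map(4)
        levels = pd.Series([10.0, 8.0, 6.0, 4.0], index=[f"a{i}" for i in range(4)])
        resB = _results([0.001, 0.5, 0.001, 0.5], ids=[f"b{i}" for i in range(4)])
        bench = build_benchmark_set(resB, omap, "m", "p", 0.01)
        curve = naive_curve(levels, omap, bench)
        assert np.allclose(curve.proportions, [1, 0.5, 2 / 3, 0.5])
        resB0 = _results([0.001, 0.5, 0.5, 0.5], ids=[f"b{i}" for i in range(4)])
        bench0 = build_benchmark_set(resB0, omap, "m", "p", 0.01)
        levels0 = pd.Series([4.0, 10.0, 8.0, 6.0], index=[f"a{i}" for i in range(4)])
        curve0 = naive_curve(levels0, omap, bench0)
        assert np.all(curve0.proportions[:-1] == 0.0)  # member ranked last

    def test_null_curve_within_hypergeometric_bands(self):
        rng = np.random.default_rng(4)
        n = 2000
        omap = _map(n)
        resA = _results(rng.uniform(size=n), ids=[f"a{i}" for i in range(n)])
        pb = np.where(rng.random(n) < 0.3, 0.001, 0.9)
        resB = _results(pb, ids=[f"b{i}" for i in range(n)])
        bench = build_benchmark_set(resB, omap, "m", "p", 0.01)
        curve = proportion_curve(resA, omap, bench)
        K = len(bench.members)
        for frac in np.arange(0.1, 1.01, 0.1):
            N = int(frac * n)
            mean = K / n
            sd = np.sqrt(N * (K / n) * (1 - K / n) * (n - N) / (n - 1)) / N
            assert abs(curve.proportions[N - 1] - mean) <= max(3 * sd, 1e-9)


class TestCompareCurves:
    def _curves(self, method_props, naive_props):
        from rhythmbench.conservation import ProportionCurve
        n = len(naive_props)
        mk = lambda pr, marker: ProportionCurve(
            gene_ids=[f"g{i}" for i in range(n)],
            ordering_values=np.arange(n, dtype=float),
            in_benchmark=np.zeros(n, dtype=bool),
            proportions=np.asarray(pr, dtype=float), marker_rank=marker)
        return {"m": mk(method_props, 2)}, mk(naive_props, None)

    def test_method_always_above_gives_sentinel(self):
        curves, naive = self._curves([0.9] * 20, [0.5] * 20)
        out = compare_curves(curves, naive)
        assert out.loc["m", "crossing_rank"] == 21

    def test_equal_curves_cross_at_one(self):
        curves, naive = self._curves([0.5] * 20, [0.5] * 20)
        out = compare_curves(curves, naive)
        assert out.loc["m", "crossing_rank"] == 1

    def test_mid_crossing_with_run_length(self):
        method = [0.9] * 10 + [0.4] * 20
        naive = [0.5] * 30
        curves, nv = self._curves(method, naive)
        out = compare_curves(curves, nv)
        assert out.loc["m", "crossing_rank"] == 11

    def test_mismatched_universe_rejected(self):
        curves, _ = self._curves([0.5] * 20, [0.5] * 20)
        _, naive_short = self._curves([0.5] * 10, [0.5] * 10)
        with pytest.raises(ValueError, match="universe"):
            compare_curves(curves, naive_short)
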