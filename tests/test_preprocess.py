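import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhythmbench.matrix import ExpressionMatrix, SampleDesign
from rhythmbench.preprocess import (GeneAnnotation, combine_probe_pvalues,
                                    filter_dataset, quartile_subset,
                                    regularize_timepoints, reshape_replicates,
                                    restrict_timepoints, summarize_expression,
                                    zscore_normalize)


def _matrix(values, ids=None, design=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"g{i}" for i in range(values.shape[0])]
    design = design or SampleDesign.regular(values.shape[1], 2.0)
    return ExpressionMatrix(pd.DataFrame(values, index=ids,
                                         columns=design.labels()), design)


class TestFilter:
    def test_each_rule_removes_one_probe(self):
        m = _matrix([[1, 2, 3], [1, 2, 3], [1, np.nan, 3], [0, 0, 0], [1, 2, 3]],
                    ids=["multi", "noncode", "hasnan", "zero", "clean"],
                    design=SampleDesign.regular(3, 2.0))
        ann = GeneAnnotation(pd.DataFrame({
            "probe_id": ["multi", "multi", "noncode", "hasnan", "zero", "clean"],
            "gene_id": ["gA", "gB", "gC", "gD", "gE", "gF"]}),
            {"gA": True, "gB": True, "gC": False, "gD": True, "gE": True, "gF": True})
        out, tally = filter_dataset(m, ann)
        assert out.gene_ids == ["clean"]
        assert tally == {"unmapped": 0, "multi": 1, "noncoding": 1,
                         "missing": 1, "allzero": 1}

    def test_clean_input_is_identity_and_idempotent(self, tiny_matrix):
        ann = GeneAnnotation.identity(tiny_matrix.gene_ids)
        out, tally = filter_dataset(tiny_matrix, ann)
        assert out.values.equals(tiny_matrix.values)
        again, _ = filter_dataset(out, ann)
        assert again.values.equals(out.values)

    def test_partial_zero_row_retained(self):
        m = _matrix([[0, 2, 3]], design=SampleDesign.regular(3, 2.0))
        ann = GeneAnnotation.identity(m.gene_ids)
        out, _ = filter_dataset(m, ann)
        assert out.n_genes == 1

    def test_empty_result_raises(self):
        m = _matrix([[0, 0, 0]], design=SampleDesign.regular(3, 2.0))
        ann = GeneAnnotation.identity(m.gene_ids)
        with pytest.raises(ValueError, match="no rows survive"):
            filter_dataset(m, ann)


class TestZscore:
    def test_hand_example(self):
        m = _matrix([[1, 1], [3, 3]], design=SampleDesign.regular(2, 2.0))
        out = zscore_normalize(m)
        assert np.allclose(out.array(), [[-1, -1], [1, 1]])

    def test_shift_only_preserves_shape(self, tiny_matrix):
        out = zscore_normalize(tiny_matrix)
        diff = out.array() - tiny_matrix.array()
        assert np.allclose(diff, diff[:, :1])  # constant per gene
        # within-gene differences preserved exactly
        assert np.allclose(np.diff(out.array(), axis=1),
                           np.diff(tiny_matrix.array(), axis=1))

    def test_degenerate_dataset_rejected(self):
        m = _matrix([[2, 2], [2, 2]], design=SampleDesign.regular(2, 2.0))
        with pytest.raises(ValueError, match="degenerate"):
            zscore_normalize(m)


class TestBrown:
    def test_single_probe_identity(self):
        assert combine_probe_pvalues([0.2]) == 0.2

    def test_duplicated_probe_no_double_counting(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=24)
        p = combine_probe_pvalues([0.05, 0.05], np.vstack([x, x]), "brown")
        assert 0.04 <= p <= 0.06

    def test_independent_probes_match_fisher(self):
        # simulation oracle: with independent probes Brown reduces to Fisher
        rng = np.random.default_rng(1)
        brown, fisher = [], []
        for _ in range(2000):
            pv = rng.uniform(size=2)
            series = rng.normal(size=(2, 12))
            brown.append(combine_probe_pvalues(pv, series, "brown"))
            fisher.append(combine_probe_pvalues(pv, None, "fisher"))
        d = stats.ks_2samp(brown, fisher).statistic
        assert d < 0.03

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            combine_probe_pvalues([1.2], None, "fisher")

    def test_permutation_invariant(self):
        rng = np.random.default_rng(2)
        series = rng.normal(size=(3, 10))
        p = [0.1, 0.5, 0.9]
        a = combine_probe_pvalues(p, series, "brown")
        b = combine_probe_pvalues(p[::-1], series[::-1], "brown")
        assert a == pytest.approx(b, rel=1e-12)
        assert 0 <= a <= 1


class TestSummaries:
    def test_named_statistics(self):
        m = _matrix([[1, 2, 9]], design=SampleDesign.regular(3, 2.0))
        assert summarize_expression(m, "median").iloc[0] == 2
        assert summarize_expression(m, "mean").iloc[0] == 4
        assert summarize_expression(m, "min").iloc[0] == 1

    def test_even_length_median_midpoint(self):
        m = _matrix([[1, 3]], design=SampleDesign.regular(2, 2.0))
        assert summarize_expression(m, "median").iloc[0] == 2

    def test_quartiles_by_rank(self):
        m = _matrix(np.arange(1, 9)[:, None] * np.ones((1, 4)),
                    design=SampleDesign.regular(4, 2.0))
        levels = summarize_expression(m, "median")
        q1 = quartile_subset(m, levels, "Q1")
        q4 = quartile_subset(m, levels, "Q4")
        assert q1.gene_ids == ["g0", "g1"] and q4.gene_ids == ["g6", "g7"]

    def test_quartile_ties_stable_and_guard(self):
        m = _matrix(np.ones((8, 4)), design=SampleDesign.regular(4, 2.0))
        levels = summarize_expression(m, "median")
        assert quartile_subset(m, levels, "Q1").gene_ids == ["g0", "g1"]
        small = _matrix(np.ones((3, 4)), design=SampleDesign.regular(4, 2.0))
        with pytest.raises(ValueError):
            quartile_subset(small, summarize_expression(small, "median"), "Q1")


class TestDesignTransforms:
    def test_regularize_bins_and_averages(self):
        design = SampleDesign((0.0, 0.5, 2.0), (1, 1, 1), (1, 2, 1))
        m = _matrix([[1.0, 3.0, 5.0]], design=design)
        out = regularize_timepoints(m, 2.0)
        assert list(out.design.time) == [0.0, 0.0, 2.0]
        # the 0h and 0.5h samples carry different replicate labels here, so
        # averaging happens within (time, replicate) bins
        assert sorted(out.array()[0]) == [1.0, 3.0, 5.0]
        merged = regularize_timepoints(
            _matrix([[1.0, 3.0, 5.0]],
                    design=SampleDesign((0.0, 0.5, 2.0), (1, 1, 1), (1, 1, 2))),
            2.0)
        assert merged.array()[0][0] == pytest.approx(2.0)  # mean of 1 and 3

    def test_regularize_idempotent_and_guard(self, tiny_matrix):
        out = regularize_timepoints(tiny_matrix, 2.0)
        assert np.allclose(out.array(), tiny_matrix.array())
        with pytest.raises(ValueError):
            regularize_timepoints(tiny_matrix, 0.0)

    def test_restrict_counts_and_identity(self):
        m = _matrix(np.arange(24)[None, :] * 1.0,
                    design=SampleDesign.regular(24, 2.0))
        first = restrict_timepoints(m, lambda t, c: c == 1)
        assert first.n_samples == 12
        ident = restrict_timepoints(m, lambda t, c: True)
        assert np.allclose(ident.array(), m.array())
        every4 = restrict_timepoints(m, lambda t, c: c == 1 and t % 4 == 0)
        assert list(every4.design.time) == [0, 4, 8, 12, 16, 20]
        again = restrict_timepoints(every4, lambda t, c: True)
        assert np.allclose(again.array(), every4.array())
        with pytest.raises(ValueError, match="fewer than 3"):
            restrict_timepoints(m, lambda t, c: t == 0)

    def test_reshape_as_cycles(self):
        design = SampleDesign.regular(12, 2.0, n_replicates=2)
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(2, 24)), design=design)
        out = reshape_replicates(m, "as_cycles")
        assert out.n_samples == 24
        assert set(out.design.cycle) == {1, 2}
        assert set(out.design.replicate) == {1}

    def test_reshape_average(self):
        design = SampleDesign((0.0, 0.0), (1, 1), (1, 2))
        m = _matrix([[2.0, 4.0]], design=design)
        out = reshape_replicates(m, "average")
        assert out.array()[0][0] == pytest.approx(3.0)
        same = reshape_replicates(_matrix([[5.0, 5.0]], design=design), "average")
        assert same.array()[0][0] == 5.0

    def test_reshape_unbalanced_rejected(self):
        design = SampleDesign((0.0, 0.0, 2.0), (1, 1, 1), (1, 2, 1))
        m = _matrix([[1.0, 2.0, 3.0]], design=design)
        with pytest.raises(ValueError, match="balanced"):
            reshape_replicates(m, "as_cycles")
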