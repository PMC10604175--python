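"""Z-scoring, Welch/BH differential expression, and the DEG gate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sandcatfs import LabeledExpression
from sandcatfs.prefilter import (
    DifferentialExpressionFilter,
    differential_expression,
    filter_degs,
    zscore_normalize,
    zscore_values,
)
from sandcatfs.synthetic import SyntheticSpec, make_synthetic_expression


def brute_force_bh(p):
    """Oracle: textbook step-up with explicit cumulative minimum."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(1.0, p[i] * m / rank_from_top)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def _make_data(X, labels):
    n, d = X.shape
    return LabeledExpression(
        values=X,
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(d)],
        labels=labels,
    )


class TestZScore:
    def test_mean_zero_sd_one(self, rng):
        X = rng.normal(5, 3, size=(25, 10))
        Z, flags = zscore_values(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-10)
        assert not flags.any()

    def test_constant_gene_zeroed_and_flagged(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 7.0
        Z, flags = zscore_values(X)
        assert np.all(Z[:, 1] == 0.0)
        assert flags.tolist() == [False, True, False]

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(15, 4))
        Z1, _ = zscore_values(X)
        Z2, _ = zscore_values(X * 3.7 + 11.0)
        assert np.allclose(Z1, Z2, atol=1e-10)

    def test_container_wrapper_warns_on_constant(self, rng):
        X = rng.normal(size=(10, 2))
        X[:, 0] = 1.0
        data = _make_data(X, ["a"] * 5 + ["b"] * 5)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = zscore_normalize(data)
        assert out.zero_variance_flags.tolist() == [True, False]


class TestDifferentialExpression:
    def test_no_signal_gene(self, rng):
        X = np.tile(rng.normal(size=(10, 1)), (2, 1))
        X += rng.normal(0, 1e-9, size=X.shape)  # jitter guard
        data = _make_data(X, ["a"] * 10 + ["b"] * 10)
        table = differential_expression(data)
        assert abs(table.t_stat[0]) < 1e-3
        assert table.p_value[0] > 0.99

    def test_planted_gene_matches_welch_oracle(self, rng):
        X = rng.normal(size=(60, 5))
        X[30:, 2] += 3.0  # group means 0 vs 3, sd 1, n = 30/30
        data = _make_data(X, ["a"] * 30 + ["b"] * 30)
        table = differential_expression(data)
        g0, g1 = X[:30, 2], X[30:, 2]
        se = np.sqrt(g0.var(ddof=1) / 30 + g1.var(ddof=1) / 30)
        t_hand = (g1.mean() - g0.mean()) / se
        assert table.t_stat[2] == pytest.approx(t_hand, rel=1e-9)
        assert table.p_value[2] < 1e-6
        assert table.logfc[2] == pytest.approx(g1.mean() - g0.mean(), rel=1e-12)

    def test_adjusted_p_dominates_raw_p(self, rng):
        X = rng.normal(size=(20, 40))
        data = _make_data(X, ["a"] * 10 + ["b"] * 10)
        table = differential_expression(data)
        assert np.all(table.adj_p >= table.p_value - 1e-15)
        assert np.all(table.adj_p <= 1.0)

    def test_single_sample_class_rejected(self, rng):
        data = _make_data(rng.normal(size=(5, 3)), ["a"] * 4 + ["b"])
        with pytest.raises(ValueError):
            differential_expression(data)

    def test_zero_variance_gene_gets_p_one(self, rng):
        X = rng.normal(size=(12, 2))
        X[:, 0] = 4.2
        data = _make_data(X, ["a"] * 6 + ["b"] * 6)
        table = differential_expression(data)
        assert table.p_value[0] == 1.0
        assert table.t_stat[0] == 0.0


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force_step_up(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(pvals)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adj, brute_force_bh(p), atol=1e-12)

    def test_pipeline_adjustment_matches_oracle(self, rng):
        X = rng.normal(size=(8, 30))
        data = _make_data(X, ["a"] * 4 + ["b"] * 4)
        table = differential_expression(data)
        assert np.allclose(table.adj_p, brute_force_bh(table.p_value), atol=1e-12)

    def test_tied_pvalues_share_adjustment(self):
        p = np.full(7, 0.03)
        assert np.allclose(brute_force_bh(p), 0.03)
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adj, 0.03, atol=1e-12)


class TestDegGate:
    def _table(self, rng, n_genes=60):
        X = rng.normal(size=(16, n_genes))
        data = _make_data(X, ["a"] * 8 + ["b"] * 8)
        return differential_expression(data)

    def test_alpha_one_keeps_all(self, rng):
        table = self._table(rng)
        assert len(filter_degs(table, alpha=1.0)) == 60

    def test_logfc_gate_excludes_small_shifts(self, rng):
        table = self._table(rng, n_genes=3)
        table.adj_p[:] = 0.01
        table.logfc[:] = 0.5
        with pytest.warns(UserWarning):
            survivors = filter_degs(table, alpha=0.05, logfc_min=0.68)
        assert len(survivors) == 0

    @given(st.floats(0.001, 0.5), st.floats(0.001, 0.5))
    @settings(derandomize=True, max_examples=30)
    def test_monotone_in_alpha(self, a1, a2):
        table = self._table(np.random.default_rng(3))
        lo, hi = sorted([a1, a2])
        assert set(filter_degs(table, alpha=lo)).issubset(set(filter_degs(table, alpha=hi)))

    def test_null_bh_rarely_passes(self):
        # under a global null, median survivor count at alpha 0.05 is 0
        counts = []
        for seed in range(20):
            gen = np.random.default_rng(seed)
            table = self._table(gen, n_genes=200)
            counts.append(len(filter_degs(table, alpha=0.05)))
        assert np.median(counts) == 0

    def test_permuted_labels_fdr_smoke(self):
        # fraction of null replicates with any survivor stays near alpha
        truth = make_synthetic_expression(
            SyntheticSpec(n_samples=20, n_genes=150, n_informative=0, seed=0)
        )
        hits = 0
        gen = np.random.default_rng(17)
        for _ in range(100):
            labels = list(truth.matrix.labels)
            gen.shuffle(labels)
            data = _make_data(truth.matrix.values, labels)
            table = differential_expression(data)
            if len(filter_degs(table, alpha=0.05)) > 0:
                hits += 1
        assert hits / 100 <= 0.12


class TestSklearnFilter:
    def test_selects_planted_genes(self):
        truth = make_synthetic_expression(SyntheticSpec(seed=5))
        X, y = truth.matrix.values, truth.matrix.y
        sel = DifferentialExpressionFilter(alpha=0.05).fit(X, y)
        picked = set(np.flatnonzero(sel.support_).tolist())
        planted = set(truth.planted_indices.tolist())
        assert len(picked & planted) >= 8
        Xt = sel.transform(X)
        assert Xt.shape == (X.shape[0], len(picked))

    def test_clone_and_params_roundtrip(self):
        from sklearn.base import clone

        sel = DifferentialExpressionFilter(alpha=0.01, logfc_min=0.68)
        params = sel.get_params()
        assert params["alpha"] == 0.01 and params["logfc_min"] == 0.68
        assert clone(sel).get_params() == params
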