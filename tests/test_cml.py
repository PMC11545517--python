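import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from gclayers.cml import (
    IntegrityError,
    build_cml,
    cluster_cml,
    crosstab,
    split_group_by_layer,
)
from gclayers.layers import Layer


def _layer(index, genes):
    return Layer(
        index=index, genes=list(genes),
        weights=pd.Series(1.0, index=list(genes)),
        labels=pd.Series([1], index=["S1"]), k=1, pac=0.0,
    )


def _fake_layers(sizes, start_indices=None):
    layers, offset = [], 0
    for i, size in enumerate(sizes, start=1):
        genes = [f"G{offset + j:05d}" for j in range(size)]
        layers.append(_layer(i, genes))
        offset += size
    return layers


class TestBuildCml:
    def test_reported_panel_size(self):
        """Layers of 118, 97, 125 and 116 genes merge into a 456-gene panel."""
        layers = _fake_layers([118, 97, 46, 125, 116])
        genes = build_cml(layers, include=[1, 2, 4, 5])
        assert len(genes) == 456

    def test_single_layer_identity(self):
        layers = _fake_layers([10, 20])
        assert build_cml(layers, [2]) == layers[1].genes

    def test_size_additivity_over_all_inclusion_patterns(self):
        sizes = [7, 11, 13, 5]
        layers = _fake_layers(sizes)
        for r in range(1, 5):
            for inc in itertools.combinations([1, 2, 3, 4], r):
                genes = build_cml(layers, list(inc))
                assert len(genes) == sum(sizes[i - 1] for i in inc)
                assert len(set(genes)) == len(genes)

    def test_overlap_raises_integrity_error(self):
        a = _layer(1, ["G1", "G2"])
        b = _layer(2, ["G2", "G3"])
        with pytest.raises(IntegrityError):
            build_cml([a, b], [1, 2])

    def test_unknown_layer_rejected(self):
        with pytest.raises(KeyError):
            build_cml(_fake_layers([4]), [9])


class TestClusterCml:
    def _three_group_matrix(self, seed=0):
        from gclayers.matrix import ExpressionMatrix

        rng = np.random.default_rng(seed)
        sizes = [8, 12, 16]
        cols, vals = [], []
        for g, size in enumerate(sizes):
            for i in range(size):
                cols.append(f"S{g}_{i}")
                v = rng.normal(0, 0.3, 6) + g * np.arange(1, 7)
                vals.append(v)
        return ExpressionMatrix(pd.DataFrame(
            np.array(vals).T, index=[f"G{i}" for i in range(6)], columns=cols))

    def test_forced_k_and_size_ordered_names(self):
        m = self._three_group_matrix()
        labels, cc = cluster_cml(m, m.genes, k_range=(3,), n_resample=20, seed=0)
        assert cc.k_star == 3
        sizes = labels.value_counts()
        assert list(sizes.sort_values().index) == ["CML1", "CML2", "CML3"]
        assert sorted(sizes) == [8, 12, 16]

    def test_partition_invariant_to_sample_order(self):
        from gclayers.matrix import ExpressionMatrix

        m = self._three_group_matrix(seed=1)
        perm = np.random.default_rng(3).permutation(m.n_samples)
        m2 = ExpressionMatrix(m.values.iloc[:, perm])
        lab1, _ = cluster_cml(m, m.genes, k_range=(3,), n_resample=20,
                              p_sample=1.0, seed=4)
        lab2, _ = cluster_cml(m2, m.genes, k_range=(3,), n_resample=20,
                              p_sample=1.0, seed=4)
        assert (lab1.loc[lab2.index] == lab2).all()

    def test_too_few_genes(self):
        m = self._three_group_matrix()
        with pytest.raises(ValueError):
            cluster_cml(m, ["G0"], k_range=(2,))


class TestCrossTab:
    def test_perfect_diagonal_table(self):
        a = pd.Series(["x"] * 10 + ["y"] * 10, index=range(20))
        b = pd.Series(["u"] * 10 + ["v"] * 10, index=range(20))
        res = crosstab(a, b)
        assert res.test == "chi-squared (Yates)"
        assert res.p_value < 0.001
        assert res.table.loc["x", "v"] == 0 and res.table.loc["y", "u"] == 0

    def test_small_2x2_fisher_matches_enumeration(self):
        # [[4,0],[0,4]]: Fisher two-sided p = 2 / C(8,4)
        a = pd.Series(["x"] * 4 + ["y"] * 4, index=range(8))
        b = pd.Series(["u"] * 4 + ["v"] * 4, index=range(8))
        res = crosstab(a, b)
        assert res.test == "Fisher exact"
        assert res.p_value == pytest.approx(2 / comb(8, 4), rel=1e-12)

    def test_montecarlo_fisher_close_to_exact_enumeration(self):
        # small 3x2 table forces the Monte-Carlo branch
        a = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5, index=range(15))
        b = pd.Series((["u"] * 4 + ["v"]) + (["u"] * 2 + ["v"] * 3) + (["v"] * 5),
                      index=range(15))
        res = crosstab(a, b, n_montecarlo=200_000, seed=0)
        assert res.test == "Fisher (Monte Carlo)"
        exact = _exact_fisher_rxc(res.table.to_numpy())
        assert res.p_value == pytest.approx(exact, abs=0.01)

    def test_type_one_error_rate_under_independence(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            a = pd.Series(rng.integers(0, 2, 200), index=range(200))
            b = pd.Series(rng.integers(0, 3, 200), index=range(200))
            rejections += crosstab(a, b).p_value < 0.05
        assert abs(rejections / n_sim - 0.05) <= 0.03

    def test_disjoint_samples_rejected(self):
        with pytest.raises(ValueError):
            crosstab(pd.Series({"a": 1}), pd.Series({"b": 1}))


def _exact_fisher_rxc(counts):
    """Exhaustive Fisher for a small r×c table: total probability of
    tables with the observed margins that are no more probable."""
    from scipy.special import gammaln

    rows, cols = counts.sum(1), counts.sum(0)

    def log_pmf(tab):
        tab = np.asarray(tab)
        return (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                - gammaln(counts.sum() + 1) - gammaln(tab + 1).sum())

    obs = log_pmf(counts)
    total = 0.0

    def rec(i, remaining_cols, rows_left, table):
        nonlocal total
        if i == len(rows) - 1:
            last = remaining_cols
            if (last >= 0).all():
                tab = table + [list(last)]
                lp = log_pmf(tab)
                if lp <= obs + 1e-9:
                    total += np.exp(lp)
            return
        def fill(j, left, row):
            if j == len(cols) - 1:
                if 0 <= left <= remaining_cols[j]:
                    rec(i + 1, remaining_cols - np.array(row + [left]),
                        rows_left, table + [row + [left]])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                fill(j + 1, left - v, row + [v])
        fill(0, rows[i], [])

    rec(0, cols.astype(int).copy(), None, [])
    return total


class TestSplitGroup:
    def test_constant_split_is_no_refinement(self):
        groups = pd.Series({"S1": "CIN", "S2": "CIN", "S3": "GS"})
        splits = pd.Series({"S1": "CML3", "S2": "CML3", "S3": "CML1"})
        out = split_group_by_layer(groups, splits, "CIN")
        assert set(out[["S1", "S2"]]) == {"CIN-CML3"}
        assert out["S3"] == "GS"

    def test_partition_accounting(self, rng):
        samples = [f"S{i}" for i in range(50)]
        groups = pd.Series(rng.choice(["CIN", "GS"], 50), index=samples)
        splits = pd.Series(rng.choice(["1", "2", "3"], 50), index=samples)
        out = split_group_by_layer(groups, splits, "CIN")
        n_cin = (groups == "CIN").sum()
        refined = out[out.str.startswith("CIN-")]
        assert len(refined) == n_cin
        assert (out[groups != "CIN"] == groups[groups != "CIN"]).all()

    def test_unknown_target(self):
        with pytest.raises(KeyError):
            split_group_by_layer(pd.Series({"S1": "A"}), pd.Series({"S1": "x"}), "Z")
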