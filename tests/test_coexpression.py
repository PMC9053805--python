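"""Soft-threshold selection, TOM algebra, module detection/merging and
module-trait selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from polypnet import simulate
from polypnet.coexpression import (detect_modules, merge_close_modules,
                                   module_eigengenes, module_trait_select,
                                   pick_soft_threshold, run_wgcna,
                                   tom_from_adjacency, tom_from_expression)
from polypnet.containers import ValidationError
from polypnet.preprocess import drop_unannotated_and_aggregate

from conftest import make_expression


@pytest.fixture(scope="module")
def small_em(small_bundle):
    from polypnet.preprocess import combat_adjust
    return combat_adjust(drop_unannotated_and_aggregate(small_bundle[0]))


class TestPowerSelection:
    def test_connectivity_decreases_with_power(self, small_em):
        sel = pick_soft_threshold(small_em)
        assert all(a > b for a, b in zip(sel.mean_connectivity,
                                         sel.mean_connectivity[1:]))
        assert sel.power in sel.candidates

    def test_forced_single_candidate(self, small_em):
        sel = pick_soft_threshold(small_em, candidates=(1,), r2_cut=-1.0)
        assert sel.power == 1

    def test_constant_gene_rejected(self):
        x = np.random.default_rng(0).normal(size=(12, 8))
        x[3] = 1.0
        em = make_expression(x, ["normal"] * 4 + ["polyp"] * 4)
        with pytest.raises(ValidationError, match="g003"):
            pick_soft_threshold(em)


class TestTom:
    def test_power_of_half_correlation(self):
        assert abs(0.5 ** 8 - 0.00390625) < 1e-15
        rng = np.random.default_rng(1)
        f = rng.normal(size=200)
        # two genes engineered to correlate exactly 0.5
        g = 0.5 * (f - f.mean()) / f.std()
        h = rng.normal(size=200)
        h = h - np.polyfit(f, h, 1)[0] * f
        h = (h - h.mean()) / h.std() * np.sqrt(1 - 0.25)
        em = make_expression(np.vstack([f, g + h, rng.normal(size=(10, 200))]),
                             ["normal"] * 100 + ["polyp"] * 100)
        cor = np.corrcoef(em.values.to_numpy())[0, 1]
        adj = np.abs(np.corrcoef(em.values.to_numpy())) ** 8
        assert abs(adj[0, 1] - abs(cor) ** 8) < 1e-12

    def test_full_adjacency_gives_tom_one(self):
        adj = np.ones((3, 3)) - np.eye(3)
        tom = tom_from_adjacency(adj)
        # (1*1 + 1) / (2 + 1 - 1) = 1 for every off-diagonal pair
        assert np.allclose(tom, 1.0)

    def test_disjoint_genes_give_tom_zero(self):
        adj = np.zeros((4, 4))
        adj[0, 1] = adj[1, 0] = 1.0
        adj[2, 3] = adj[3, 2] = 1.0
        tom = tom_from_adjacency(adj)
        assert tom[0, 2] == 0.0 and tom[0, 3] == 0.0

    def test_invariant_to_gene_scaling(self, small_em):
        tom1 = tom_from_expression(small_em, 6)
        scaled = small_em.values * np.random.default_rng(0).uniform(
            0.5, 4.0, size=(len(small_em.genes), 1))
        em2 = make_expression(scaled.to_numpy(),
                              list(small_em.metadata.table["phenotype"]),
                              batches=list(small_em.metadata.table["batch"]),
                              genes=list(scaled.index))
        tom2 = tom_from_expression(em2, 6)
        assert np.allclose(tom1.to_numpy(), tom2.to_numpy(), atol=1e-12)


class TestDetectModules:
    def test_planted_modules_recovered(self, small_em, small_cfg, small_bundle):
        truth = small_bundle[2]
        tom = tom_from_expression(small_em, pick_soft_threshold(small_em).power)
        labels = detect_modules(tom, min_module_size=20, cut_height=0.95)
        target = pd.Series({g: truth.module_of_gene.get(g, "bg")
                            for g in labels.index})
        assert adjusted_rand_score(target, labels) >= 0.8

    def test_cut_above_root_gives_single_module(self, small_em):
        tom = tom_from_expression(small_em, 4)
        labels = detect_modules(tom, min_module_size=2, cut_height=1.01)
        assert set(labels) == {1}

    def test_tie_break_is_permutation_invariant(self):
        genes = [f"g{i}" for i in range(8)]
        tom = pd.DataFrame(np.full((8, 8), 0.4) + 0.6 * np.eye(8),
                           index=genes, columns=genes)
        lab1 = detect_modules(tom, min_module_size=2, cut_height=0.7)
        perm = genes[::-1]
        lab2 = detect_modules(tom.loc[perm, perm], min_module_size=2,
                              cut_height=0.7)
        # equidistant genes: result must agree up to relabelling
        assert adjusted_rand_score(lab1[genes], lab2[genes]) == 1.0

    def test_min_size_validation(self, small_em):
        tom = tom_from_expression(small_em, 4)
        with pytest.raises(ValidationError):
            detect_modules(tom, min_module_size=1)


class TestEigengenes:
    def test_identical_rows_give_perfect_correlation(self):
        profile = np.sin(np.linspace(0, 3, 10))
        x = np.tile(profile, (4, 1))
        em = make_expression(x + 1e-9 * np.random.default_rng(0).normal(
            size=x.shape), ["normal"] * 5 + ["polyp"] * 5)
        labels = pd.Series(1, index=em.values.index)
        eig = module_eigengenes(em, labels)
        for g in em.genes:
            r = np.corrcoef(eig.iloc[0], em.values.loc[g])[0, 1]
            assert r > 0.999

    def test_sign_orientation_stable_under_global_flip(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 12))
        em = make_expression(x, ["normal"] * 6 + ["polyp"] * 6)
        labels = pd.Series(1, index=em.values.index)
        e1 = module_eigengenes(em, labels)
        em2 = make_expression(-x, ["normal"] * 6 + ["polyp"] * 6)
        e2 = module_eigengenes(em2, labels)
        assert np.corrcoef(e1.iloc[0], e2.iloc[0])[0, 1] < -0.99 or \
            np.allclose(e1.to_numpy(), e2.to_numpy(), atol=1e-8) or \
            np.allclose(e1.to_numpy(), -e2.to_numpy(), atol=1e-8)

    def test_pc1_dominates_pc2(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 20))
        em = make_expression(x, ["normal"] * 10 + ["polyp"] * 10)
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        eigvals = np.linalg.eigvalsh(z @ z.T)[::-1]
        assert eigvals[0] >= eigvals[1]
        eig = module_eigengenes(em, pd.Series(1, index=em.values.index))
        var_pc1 = ((z @ eig.iloc[0].to_numpy()) ** 2).sum()
        assert abs(var_pc1 - eigvals[0]) < 1e-8

    def test_single_gene_module_rejected(self):
        em = make_expression(np.random.default_rng(0).normal(size=(3, 6)),
                             ["normal"] * 3 + ["polyp"] * 3)
        labels = pd.Series([1, 2, 2], index=em.values.index)
        with pytest.raises(ValidationError):
            module_eigengenes(em, labels)


def _correlated_module_pair(rho: float, n: int = 40, genes_per: int = 10,
                            seed: int = 0):
    """Expression with two modules whose eigengenes correlate exactly rho."""
    rng = np.random.default_rng(seed)
    f1 = rng.normal(size=n)
    f1 = (f1 - f1.mean()) / f1.std()
    g = rng.normal(size=n)
    g = g - (g @ f1) / (f1 @ f1) * f1
    g = (g - g.mean()) / g.std()
    f2 = rho * f1 + np.sqrt(1 - rho ** 2) * g
    x = np.vstack([np.outer(rng.uniform(0.8, 1.2, genes_per), f1),
                   np.outer(rng.uniform(0.8, 1.2, genes_per), f2)])
    x += 1e-6 * rng.normal(size=x.shape)
    em = make_expression(x, ["normal"] * (n // 2) + ["polyp"] * (n - n // 2))
    labels = pd.Series([1] * genes_per + [2] * genes_per,
                       index=em.values.index)
    return em, labels


class TestMerge:
    def test_highly_correlated_modules_merge(self):
        em, labels = _correlated_module_pair(0.9)
        merged = merge_close_modules(em, labels, merge_height=0.25)
        assert merged.nunique() == 1

    def test_uncorrelated_modules_stay_separate(self):
        em, labels = _correlated_module_pair(0.0)
        merged = merge_close_modules(em, labels, merge_height=0.25)
        assert merged.nunique() == 2

    def test_zero_merge_height_is_identity(self):
        em, labels = _correlated_module_pair(0.9)
        merged = merge_close_modules(em, labels, merge_height=0.0)
        assert adjusted_rand_score(labels, merged) == 1.0


class TestTraitSelect:
    def test_phenotype_indicator_eigengene_selected(self):
        y = np.array([0.0] * 5 + [1.0] * 5)
        eig = pd.DataFrame([y - y.mean()], index=[1],
                           columns=[f"s{i:03d}" for i in range(10)])
        em = make_expression(np.random.default_rng(0).normal(size=(3, 10)),
                             ["normal"] * 5 + ["polyp"] * 5)
        table, selected = module_trait_select(eig, em.metadata)
        assert abs(table.loc[1, "r"] - 1.0) < 1e-12
        assert selected == [1]

    def test_weak_correlation_not_selected(self):
        rng = np.random.default_rng(5)
        n = 200
        y = np.array([0.0] * (n // 2) + [1.0] * (n // 2))
        noise = rng.normal(size=n)
        noise -= noise.mean()
        yc = y - y.mean()
        noise -= (noise @ yc) / (yc @ yc) * yc  # exactly orthogonal
        e = 0.2 * yc / yc.std() + np.sqrt(1 - 0.04) * noise / noise.std()
        eig = pd.DataFrame([e], index=[1],
                           columns=[f"s{i:03d}" for i in range(n)])
        em = make_expression(rng.normal(size=(3, n)),
                             ["normal"] * (n // 2) + ["polyp"] * (n // 2))
        table, selected = module_trait_select(eig, em.metadata, r_threshold=0.3)
        assert abs(abs(table.loc[1, "r"]) - 0.2) < 1e-9
        assert selected == []

    def test_matches_direct_pearson_and_t_formula(self):
        e = np.array([0.3, -1.2, 0.5, 2.0, -0.7, 0.1])
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        eig = pd.DataFrame([e], index=[1],
                           columns=[f"s{i:03d}" for i in range(6)])
        em = make_expression(np.zeros((3, 6)) + np.arange(6),
                             ["normal"] * 3 + ["polyp"] * 3)
        table, _ = module_trait_select(eig, em.metadata)
        # brute-force Pearson + t oracle
        r = (((e - e.mean()) * (y - y.mean())).sum()
             / np.sqrt(((e - e.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        from scipy import stats
        t = r * np.sqrt(4 / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), df=4)
        assert abs(table.loc[1, "r"] - r) < 1e-12
        assert abs(table.loc[1, "p"] - p) < 1e-12


def test_selected_modules_cover_planted_genes(small_em, small_cfg):
    res = run_wgcna(small_em, min_module_size=20)
    planted = {g for m in small_cfg.modules for g in m.member_genes}
    selected_genes = set(res.labels.index[res.labels.isin(res.selected)])
    assert len(selected_genes & planted) >= 0.8 * len(planted)
    background = selected_genes - planted
    assert len(background) <= 0.2 * len(selected_genes)
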