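import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ctrlcircuit import wgcna
from ctrlcircuit.synthetic import ExpressionSpec, generate_expression_atlas


def _expr(matrix, prefix="G"):
    g, r = matrix.shape
    return pd.DataFrame(
        matrix,
        index=[f"{prefix}{i}" for i in range(g)],
        columns=[f"L{j}" for j in range(r)],
    )


class TestAdjacency:
    def test_range_and_diagonal(self, rng):
        a = wgcna.adjacency(_expr(rng.normal(size=(30, 40))), beta=6)
        vals = a.to_numpy()
        assert np.all((vals >= 0) & (vals <= 1))
        np.testing.assert_allclose(np.diag(vals), 1.0)

    def test_higher_beta_shrinks_off_diagonal(self, rng):
        expr = _expr(rng.normal(size=(20, 50)))
        a6 = wgcna.adjacency(expr, 6).to_numpy()
        a12 = wgcna.adjacency(expr, 12).to_numpy()
        off = ~np.eye(20, dtype=bool)
        assert np.all(a12[off] <= a6[off])
        assert np.any(a12[off] < a6[off])


class TestSoftPower:
    def test_scale_free_sequence_fits(self, rng):
        # degree sequence with a power-law tail scores a high fit index
        k = rng.pareto(2.0, size=2000) + 1
        assert wgcna.scale_free_fit(k) >= 0.85

    def test_degenerate_connectivity_scores_zero(self):
        assert wgcna.scale_free_fit(np.full(100, 3.0)) == 0.0

    def test_fallback_warns(self, planted_atlas):
        import warnings

        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            beta, table = wgcna.select_soft_power(planted_atlas.expr)
        assert any("default" in str(w.message) for w in rec)
        assert 1 <= beta <= 20
        assert len(table) == 20


class TestTom:
    def test_perfect_module(self):
        a = np.ones((3, 3))
        t = wgcna.tom(a)
        assert t[0, 1] == pytest.approx(1.0)  # (1+1)/(2+1-1)

    def test_shared_neighbour_only(self):
        a = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        # a_12 = 0 but both connect to gene 3: TOM_12 = (1+0)/(1+1-0)
        t = wgcna.tom(a)
        assert t[0, 1] == pytest.approx(0.5)

    def test_isolated_pair(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 1.0
        t = wgcna.tom(a)
        assert t[0, 1] == pytest.approx(1.0)  # (0+1)/(1+1-1)

    def test_range_and_diagonal_on_random(self, rng):
        raw = rng.uniform(0, 1, size=(25, 25))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 1.0)
        t = wgcna.tom(a)
        assert np.all((t >= 0) & (t <= 1 + 1e-12))
        np.testing.assert_allclose(np.diag(t), 1.0)

    def test_permutation_equivariance(self, rng):
        raw = rng.uniform(0, 1, size=(15, 15))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 1.0)
        perm = rng.permutation(15)
        t = np.asarray(wgcna.tom(a))
        tp = np.asarray(wgcna.tom(a[np.ix_(perm, perm)]))
        np.testing.assert_allclose(t[np.ix_(perm, perm)], tp, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            wgcna.tom(np.full((3, 3), 1.5))


class TestEigengene:
    def test_identical_genes(self, rng):
        profile = rng.normal(size=30)
        expr = _expr(np.tile(profile, (5, 1)))
        me, ve = wgcna.module_eigengene(expr, expr.index)
        assert ve == pytest.approx(1.0)
        assert abs(np.corrcoef(me, profile)[0, 1]) == pytest.approx(1.0)

    def test_sign_orientation_consistent_under_global_flip(self, rng):
        # orientation is anchored to the member genes, so negating every
        # gene flips the eigengene coherently: the represented component and
        # every gene's module membership are unchanged
        mat = rng.normal(size=(6, 40))
        me1, _ = wgcna.module_eigengene(_expr(mat), [f"G{i}" for i in range(6)])
        me2, _ = wgcna.module_eigengene(_expr(-mat), [f"G{i}" for i in range(6)])
        assert abs(np.corrcoef(me1, me2)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        mm1 = [np.corrcoef(row, me1)[0, 1] for row in mat]
        mm2 = [np.corrcoef(row, me2)[0, 1] for row in -mat]
        np.testing.assert_allclose(mm1, mm2, atol=1e-10)

    def test_anticorrelated_halves(self, rng):
        base = rng.normal(size=50)
        mat = np.vstack(
            [base + rng.normal(0, 0.05, 50) for _ in range(5)]
            + [-base + rng.normal(0, 0.05, 50) for _ in range(5)]
        )
        expr = _expr(mat)
        me, _ = wgcna.module_eigengene(expr, expr.index)
        r_pos = np.corrcoef(me, mat[0])[0, 1]
        r_neg = np.corrcoef(me, mat[-1])[0, 1]
        assert abs(r_pos) > 0.98 and abs(r_neg) > 0.98
        assert np.sign(r_pos) == -np.sign(r_neg)

    def test_constant_rows_dropped_with_warning(self, rng):
        mat = rng.normal(size=(4, 20))
        mat[1] = 2.5
        with pytest.warns(UserWarning, match="constant"):
            me, _ = wgcna.module_eigengene(_expr(mat), [f"G{i}" for i in range(4)])
        assert len(me) == 20


class TestDetectModules:
    def test_planted_partition_recovered(self, planted_atlas):
        adj = wgcna.adjacency(planted_atlas.expr, 6)
        dissim = 1.0 - np.asarray(wgcna.tom(adj))
        ms = wgcna.detect_modules(planted_atlas.expr, dissim, min_module_size=100)
        truth = [str(planted_atlas.truth["gene_modules"][g])
                 for g in planted_atlas.expr.index]
        assert adjusted_rand_score(truth, list(ms.labels)) >= 0.8
        assert len(ms.module_colors) == 4
        # names follow the size-ordered color convention
        assert ms.labels.value_counts().drop("grey").index[0] == "turquoise"

    def test_pure_noise_goes_to_background(self):
        atlas = generate_expression_atlas(
            ExpressionSpec(n_genes=300, n_regions=60, modules=[], seed=5)
        )
        adj = wgcna.adjacency(atlas.expr, 6)
        dissim = 1.0 - np.asarray(wgcna.tom(adj))
        ms = wgcna.detect_modules(atlas.expr, dissim, min_module_size=100)
        assert (ms.labels == "grey").mean() >= 0.95

    def test_duplicated_blocks_give_two_modules(self, rng):
        base1, base2 = rng.normal(size=60), rng.normal(size=60)
        mat = np.vstack(
            [base1 + rng.normal(0, 0.2, 60) for _ in range(150)]
            + [base2 + rng.normal(0, 0.2, 60) for _ in range(150)]
        )
        expr = _expr(mat)
        adj = wgcna.adjacency(expr, 6)
        dissim = 1.0 - np.asarray(wgcna.tom(adj))
        ms = wgcna.detect_modules(expr, dissim, min_module_size=100)
        assert len(ms.module_colors) == 2

    def test_too_few_genes_all_background(self, rng):
        expr = _expr(rng.normal(size=(30, 20)))
        with pytest.warns(UserWarning, match="background"):
            ms = wgcna.detect_modules(expr, 1 - np.eye(30), min_module_size=100)
        assert (ms.labels == "grey").all()

    def test_deterministic(self, planted_atlas):
        adj = wgcna.adjacency(planted_atlas.expr, 6)
        dissim = 1.0 - np.asarray(wgcna.tom(adj))
        m1 = wgcna.detect_modules(planted_atlas.expr, dissim, min_module_size=100)
        m2 = wgcna.detect_modules(planted_atlas.expr, dissim, min_module_size=100)
        assert m1.labels.equals(m2.labels)


@pytest.fixture(scope="module")
def modules(planted_atlas):
    adj = wgcna.adjacency(planted_atlas.expr, 6)
    dissim = 1.0 - np.asarray(wgcna.tom(adj))
    return wgcna.detect_modules(planted_atlas.expr, dissim, min_module_size=100)


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self, modules, planted_atlas):
        me = modules.eigengenes.iloc[:, 0]
        out = wgcna.module_trait(modules.eigengenes, me.rename("t"))
        row = out[out["module"] == modules.eigengenes.columns[0]]
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_planted_coupling_estimated(self, modules, planted_atlas):
        out = wgcna.module_trait(modules.eigengenes, planted_atlas.trait)
        assert out["r"].abs().max() == pytest.approx(0.5, abs=0.15)

    def test_bh_monotone_in_raw_p(self, modules, planted_atlas):
        out = wgcna.module_trait(modules.eigengenes, planted_atlas.trait)
        s = out.sort_values("p")
        assert (np.diff(s["p_adj"]) >= -1e-12).all()
        assert (out["p_adj"] >= out["p"] - 1e-12).all()

    def test_too_few_regions_rejected(self, modules):
        trait = pd.Series([1.0, 2.0, 3.0], index=modules.eigengenes.index[:3])
        with pytest.raises(ValueError, match="overlapping regions"):
            wgcna.module_trait(modules.eigengenes, trait)


class TestHubGenes:
    def test_gene_equal_to_eigengene_and_trait_is_hub(self, rng):
        base = rng.normal(size=50)
        mat = np.vstack([base + rng.normal(0, 0.05, 50) for _ in range(10)])
        expr = _expr(mat)
        labels = pd.Series("blue", index=expr.index)
        me, _ = wgcna.module_eigengene(expr, expr.index)
        ms = wgcna.ModuleSet(labels=labels, eigengenes=me.to_frame("blue"))
        trait = pd.Series(base, index=expr.columns)
        out = wgcna.hub_genes(expr, ms, trait)
        assert out["hub"].all()

    def test_trait_orthogonal_gene_not_hub(self, rng):
        base = rng.normal(size=200)
        mat = np.vstack([base + rng.normal(0, 0.05, 200) for _ in range(10)])
        expr = _expr(mat)
        labels = pd.Series("blue", index=expr.index)
        me, _ = wgcna.module_eigengene(expr, expr.index)
        ms = wgcna.ModuleSet(labels=labels, eigengenes=me.to_frame("blue"))
        trait = pd.Series(rng.normal(size=200), index=expr.columns)
        out = wgcna.hub_genes(expr, ms, trait)
        assert not out["hub"].any()
        assert (out["MM"].abs() > 0.8).all()

    def test_background_excluded(self, rng):
        mat = rng.normal(size=(5, 30))
        expr = _expr(mat)
        labels = pd.Series("grey", index=expr.index)
        ms = wgcna.ModuleSet(labels=labels, eigengenes=pd.DataFrame(index=expr.columns))
        out = wgcna.hub_genes(expr, ms, pd.Series(rng.normal(size=30), index=expr.columns))
        assert out.empty

    def test_bad_threshold_rejected(self, planted_atlas):
        ms = wgcna.ModuleSet(
            labels=pd.Series("grey", index=planted_atlas.expr.index),
            eigengenes=pd.DataFrame(index=planted_atlas.expr.columns),
        )
        with pytest.raises(ValueError):
            wgcna.hub_genes(planted_atlas.expr, ms, planted_atlas.trait,
                            mm_threshold=1.5)
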