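import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctrlcircuit.synthetic import (
    CellTypeSpec,
    CohortSpec,
    ExpressionSpec,
    generate_celltype_reference,
    generate_connectome_cohort,
    generate_expression_atlas,
    generate_validation_dataset,
)


class TestCohortGenerator:
    def test_network_invariants(self, null_cohort):
        for net in null_cohort.networks[:5]:
            assert np.allclose(net.A, net.A.T)
            assert np.all(np.diag(net.A) == 0)
            assert net.A.min() >= 0 and net.A.max() <= 1

    def test_deterministic(self):
        spec = dict(n_per_group={"MDDNSI": 5, "MDDSI": 5}, n_regions=30, seed=42)
        c1 = generate_connectome_cohort(CohortSpec(**spec))
        c2 = generate_connectome_cohort(CohortSpec(**spec))
        for a, b in zip(c1.networks, c2.networks):
            np.testing.assert_array_equal(a.A, b.A)
        pd.testing.assert_frame_equal(c1.phenotypes, c2.phenotypes)

    def test_zero_effect_no_group_difference(self):
        spec = CohortSpec(
            n_per_group={"MDDNSI": 500, "MDDSI": 500},
            n_regions=20,
            planted_edges=[(0, 1), (1, 2)],
            edge_effect=0.0,
            seed=8,
        )
        c = generate_connectome_cohort(spec)
        groups = c.phenotypes.set_index("subject_id")["group"]
        w = {
            g: [
                np.mean([net.A[i, j] for i, j in spec.planted_edges])
                for net in c.networks
                if groups[net.subject_id] == g
            ]
            for g in ("MDDNSI", "MDDSI")
        }
        t = sps.ttest_ind(w["MDDNSI"], w["MDDSI"])
        assert abs(t.statistic) < 3

    def test_planted_attenuation_matches_spec(self):
        spec = CohortSpec(
            n_per_group={"MDDNSI": 20, "MDDSI": 20},
            n_regions=90,
            planted_edges=[(i, i + 1) for i in range(10)],
            edge_effect=2.0,
            affected_group="MDDSI",
            seed=3,
        )
        c = generate_connectome_cohort(spec)
        groups = c.phenotypes.set_index("subject_id")["group"]
        means = {g: [] for g in ("MDDNSI", "MDDSI")}
        for net in c.networks:
            means[groups[net.subject_id]].append(
                np.mean([net.A[i, j] for i, j in spec.planted_edges])
            )
        gap = np.mean(means["MDDNSI"]) - np.mean(means["MDDSI"])
        assert gap == pytest.approx(2.0 * spec.noise_sd, abs=0.05)

    def test_out_of_range_edge_named(self):
        with pytest.raises(ValueError, match=r"\(5, 99\)"):
            CohortSpec(n_per_group={"HC": 3}, n_regions=30,
                       planted_edges=[(5, 99)], edge_effect=1.0)

    def test_disconnected_planted_edges_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            CohortSpec(n_per_group={"HC": 3}, n_regions=30,
                       planted_edges=[(0, 1), (5, 6)])

    def test_sidecar_round_trip(self, tmp_path, null_cohort):
        import json

        null_cohort.save(tmp_path)
        truth = json.loads((tmp_path / "ground_truth.json").read_text())
        assert truth["n_regions"] == 60
        assert (tmp_path / "phenotypes.csv").exists()


class TestExpressionGenerator:
    def test_perfect_module_profiles_identical(self):
        atlas = generate_expression_atlas(
            ExpressionSpec(n_genes=10, n_regions=30, modules=[(5, 1.0, 0.0)], seed=1)
        )
        sub = atlas.expr.iloc[:5].to_numpy()
        cors = np.corrcoef(sub)
        np.testing.assert_allclose(cors, 1.0, atol=1e-10)

    def test_background_bookkeeping(self):
        atlas = generate_expression_atlas(
            ExpressionSpec(
                n_genes=1000, n_regions=30,
                modules=[(150, 0.7, 0.0)] * 4, seed=1,
            )
        )
        assert (atlas.module_labels == "none").sum() == 400

    def test_zero_trait_coupling_calibrated(self):
        # exact in-sample planting: a tc=0 module factor is orthogonal to the
        # trait, so the empirical eigengene correlation stays small
        hits = 0
        for seed in range(50):
            atlas = generate_expression_atlas(
                ExpressionSpec(n_genes=60, n_regions=120,
                               modules=[(50, 0.7, 0.0)], seed=seed)
            )
            sub = atlas.expr.iloc[:50]
            me = sub.mean(axis=0)
            if abs(np.corrcoef(me, atlas.trait)[0, 1]) < 0.2:
                hits += 1
        assert hits >= 48

    def test_planted_trait_correlation_exact(self):
        atlas = generate_expression_atlas(
            ExpressionSpec(n_genes=30, n_regions=80, modules=[(20, 1.0, 0.6)], seed=2)
        )
        me = atlas.expr.iloc[:20].mean(axis=0)
        assert abs(np.corrcoef(me, atlas.trait)[0, 1]) == pytest.approx(0.6, abs=1e-9)

    def test_infeasible_combination_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            ExpressionSpec(n_genes=10, n_regions=20, modules=[(5, 0.7, 1.0)])

    def test_oversized_modules_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            ExpressionSpec(n_genes=10, n_regions=20, modules=[(8, 0.5, 0.0), (8, 0.5, 0.0)])


class TestCellTypeGenerator:
    def test_uniform_without_enrichment(self, rng):
        labels = pd.Series([0] * 50 + ["none"] * 50,
                           index=[f"G{i}" for i in range(100)])
        ref, _ = generate_celltype_reference(
            labels, CellTypeSpec(cell_type_names=list("abcd"), seed=1)
        )
        spec_m = ref.div(ref.sum(axis=1), axis=0)
        np.testing.assert_allclose(spec_m.mean(axis=0), 0.25, atol=0.02)

    def test_single_cell_type_all_ones(self):
        labels = pd.Series(["none"] * 10, index=[f"G{i}" for i in range(10)])
        ref, _ = generate_celltype_reference(
            labels, CellTypeSpec(cell_type_names=["only"], seed=0)
        )
        spec_m = ref.div(ref.sum(axis=1), axis=0)
        np.testing.assert_allclose(spec_m.to_numpy(), 1.0)

    def test_planted_fold_specificity_closed_form(self):
        labels = pd.Series([1] * 200 + ["none"] * 200,
                           index=[f"G{i}" for i in range(400)])
        ref, _ = generate_celltype_reference(
            labels,
            CellTypeSpec(cell_type_names=list("abcd"), enriched_module=1,
                         enrichment_fold=5.0, target_cell_type="a", seed=2),
        )
        spec_m = ref.div(ref.sum(axis=1), axis=0)
        target_mean = spec_m.loc[labels == 1, "a"].mean()
        other_mean = spec_m.loc[labels == 1, "b"].mean()
        assert target_mean == pytest.approx(5 / 8, abs=0.02)
        assert other_mean == pytest.approx(1 / 8, abs=0.02)

    def test_unknown_module_rejected(self):
        labels = pd.Series([0] * 5, index=[f"G{i}" for i in range(5)])
        with pytest.raises(ValueError, match="unknown module"):
            generate_celltype_reference(
                labels,
                CellTypeSpec(cell_type_names=["a"], enriched_module=3,
                             enrichment_fold=2.0),
            )

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            CellTypeSpec(cell_type_names=["a", "a"])


class TestValidationGenerator:
    def test_null_p_uniform(self):
        genes = [f"g{i}" for i in range(2000)]
        ds = generate_validation_dataset(genes, 20, [], [], seed=6)
        a = ds.data[ds.data["group"] == "control"]
        b = ds.data[ds.data["group"] == "case"]
        pvals = sps.ttest_ind(a[genes], b[genes]).pvalue
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_effect_high_auc(self):
        from ctrlcircuit.stats import roc_auc

        hits = 0
        for seed in range(40):
            ds = generate_validation_dataset(["g"], 30, ["g"], [3.0], seed=seed)
            auc = roc_auc(ds.data["g"], ds.data["group"], positive_label="case").auc
            hits += auc > 0.9
        assert hits >= 38  # >= 95%

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            generate_validation_dataset(["g"], 0, [], [])
        with pytest.raises(ValueError, match="effect sizes"):
            generate_validation_dataset(["g"], 5, ["g"], [])
        with pytest.raises(ValueError, match="not in gene panel"):
            generate_validation_dataset(["g"], 5, ["h"], [1.0])
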