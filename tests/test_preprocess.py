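"""Probe aggregation, cohort assembly and the empirical-Bayes batch
adjustment (including a cross-check against the R reference implementation)."""

import shutil
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polypnet import simulate
from polypnet.containers import (ExpressionMatrix, ProbeMatrix,
                                 SampleMetadata, ValidationError)
from polypnet.preprocess import (assemble_cohort, combat_adjust,
                                 drop_unannotated_and_aggregate)

from conftest import make_expression


def _probe_matrix(values, probe_genes, phenotypes=None):
    values = pd.DataFrame(values)
    probes = [f"p{i}" for i in range(len(values))]
    values.index = probes
    samples = [f"s{i}" for i in range(values.shape[1])]
    values.columns = samples
    phenotypes = phenotypes or ["normal"] * len(samples)
    meta = SampleMetadata(pd.DataFrame(
        {"phenotype": phenotypes, "batch": ["b1"] * len(samples)},
        index=pd.Index(samples, name="sample_id")))
    return ProbeMatrix(values, pd.Series(probe_genes, index=probes,
                                         dtype="object"), meta)


class TestAggregate:
    @pytest.mark.parametrize("probe_values,expected", [
        ([[1.0], [3.0], [5.0]], 3.0),   # odd count -> middle value
        ([[1.0], [3.0]], 2.0),          # even count -> mean of middle two
    ])
    def test_median_per_gene(self, probe_values, expected):
        pm = _probe_matrix(probe_values, ["G"] * len(probe_values))
        em = drop_unannotated_and_aggregate(pm)
        assert em.values.loc["G", "s0"] == expected

    def test_na_probes_dropped_and_gene_count(self):
        genes = ["g1", "g1", "g2", "g3", None, None, "g2", "g3", None, None]
        pm = _probe_matrix(np.arange(10.0)[:, None], genes)
        em = drop_unannotated_and_aggregate(pm)
        assert list(em.values.index) == ["g1", "g2", "g3"]

    def test_all_na_probes_error(self):
        pm = _probe_matrix([[1.0], [2.0]], [None, None])
        with pytest.raises(ValidationError):
            drop_unannotated_and_aggregate(pm)

    def test_single_probe_identity(self):
        pm = _probe_matrix([[1.5, 2.5]], ["G"])
        em = drop_unannotated_and_aggregate(pm)
        assert list(em.values.loc["G"]) == [1.5, 2.5]


class TestAssemble:
    def test_training_cohort_of_eight_datasets_has_150_samples(self):
        # per-dataset sample counts of the eight training sets
        counts = [10, 8 + 15, 32 + 32, 12, 3 + 5, 4, 6 + 6, 17]
        rng = np.random.default_rng(0)
        matrices = []
        for d, n in enumerate(counts):
            em = make_expression(rng.normal(8, 1, (5, n)), ["normal"] * n)
            em.values.columns = [f"d{d}_s{i}" for i in range(n)]
            em.metadata.table.index = em.values.columns
            matrices.append(ExpressionMatrix(em.values, SampleMetadata(
                em.metadata.table)))
        merged = assemble_cohort(matrices, batch_labels=[f"ds{d}" for d in
                                                         range(len(counts))])
        assert merged.n_samples == 150
        assert merged.metadata.table["batch"].nunique() == 8

    def test_single_input_is_identity(self):
        em = make_expression(np.ones((3, 4)) * 2.0, ["normal"] * 4)
        merged = assemble_cohort([em])
        pd.testing.assert_frame_equal(merged.values, em.values)

    def test_gene_intersection(self):
        a = make_expression(np.zeros((3, 2)), ["normal"] * 2,
                            genes=["a", "b", "c"])
        b = make_expression(np.zeros((3, 2)), ["polyp"] * 2,
                            genes=["b", "c", "d"])
        b.values.columns = ["t0", "t1"]
        b.metadata.table.index = b.values.columns
        b = ExpressionMatrix(b.values, SampleMetadata(b.metadata.table))
        merged = assemble_cohort([a, b], batch_labels=["x", "y"])
        assert list(merged.values.index) == ["b", "c"]

    def test_duplicate_sample_ids_rejected(self):
        a = make_expression(np.zeros((2, 2)), ["normal"] * 2)
        b = make_expression(np.zeros((2, 2)), ["normal"] * 2)
        with pytest.raises(ValidationError):
            assemble_cohort([a, b], batch_labels=["x", "y"])


def _two_batch_em(shift=2.0, n=12, g=40, seed=0):
    rng = np.random.default_rng(seed)
    b1 = rng.normal(8, 1.5, (g, n)) + rng.normal(0, 0.5, (g, n))
    x = np.hstack([b1, b1 + shift])
    return make_expression(x, ["normal", "polyp"] * n,
                           batches=["A"] * n + ["B"] * n)


class TestCombat:
    def test_location_shift_removed_exactly_without_shrinkage(self):
        """Closed-form check: a pure constant offset between equal-size
        batches is removed exactly when no prior shrinkage is applied."""
        adj = combat_adjust(_two_batch_em(), shrink=False)
        b = adj.metadata.table["batch"].to_numpy()
        mean_a = adj.values.to_numpy()[:, b == "A"].mean(axis=1)
        mean_b = adj.values.to_numpy()[:, b == "B"].mean(axis=1)
        assert np.abs(mean_a - mean_b).max() < 1e-6

    def test_matches_r_sva_combat(self):
        """Dual-route check of the EB adjustment against sva::ComBat."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the reference oracle")
        em = _two_batch_em(shift=1.0, n=8, g=30, seed=4)
        adj = combat_adjust(em)
        with tempfile.TemporaryDirectory() as td:
            em.values.to_csv(f"{td}/x.tsv", sep="\t")
            batches = em.metadata.table["batch"]
            with open(f"{td}/batch.txt", "w") as fh:
                fh.write("\n".join(batches))
            script = (
                'suppressMessages(library(sva));'
                f'x <- as.matrix(read.table("{td}/x.tsv", sep="\\t", '
                'header=TRUE, row.names=1));'
                f'batch <- scan("{td}/batch.txt", what=character());'
                'out <- ComBat(dat=x, batch=batch, par.prior=TRUE);'
                f'write.table(out, "{td}/out.tsv", sep="\\t", quote=FALSE)')
            subprocess.run(["Rscript", "-e", script], check=True,
                           capture_output=True)
            ref = pd.read_csv(f"{td}/out.tsv", sep="\t").to_numpy()
        assert np.abs(adj.values.to_numpy() - ref).max() < 1e-8

    def test_single_batch_rejected(self):
        em = make_expression(np.random.default_rng(0).normal(size=(5, 6)),
                             ["normal"] * 6)
        with pytest.raises(ValidationError, match="2 batches"):
            combat_adjust(em)

    def test_batch_with_one_sample_rejected_by_name(self):
        em = make_expression(np.random.default_rng(0).normal(size=(5, 5)),
                             ["normal"] * 5, batches=["A"] * 4 + ["lonely"])
        with pytest.raises(ValidationError, match="lonely"):
            combat_adjust(em)

    def test_zero_variance_gene_rejected_with_names(self):
        x = np.random.default_rng(0).normal(size=(4, 8))
        x[2] = 5.0
        em = make_expression(x, ["normal"] * 8, batches=["A"] * 4 + ["B"] * 4)
        with pytest.raises(ValidationError, match="g002"):
            combat_adjust(em)

    def test_near_identity_without_batch_effect(self):
        """With no injected batch effect the adjustment must be almost a
        no-op: per-gene RMS change below the residual noise SD."""
        cfg = simulate.SimConfig(n_genes=200, n_samples_per_batch=[30, 30],
                                 batch_shift_sd=0.0, batch_scale_sd=0.0,
                                 probe_count_weights={1: 1.0},
                                 frac_unannotated_probes=0.0, seed=9)
        pm, _, _ = simulate.simulate_cohort(cfg)
        em = drop_unannotated_and_aggregate(pm)
        adj = combat_adjust(em)
        rms = np.sqrt(((adj.values.to_numpy()
                        - em.values.to_numpy()) ** 2).mean(axis=1))
        assert rms.max() < cfg.noise_sd

    def test_batch_means_indistinguishable_after_adjustment(self):
        """Synthetic null with only batch effects: after adjustment a
        per-gene one-way F test across batches rejects <=5% at alpha=0.05."""
        cfg = simulate.SimConfig(n_genes=300, n_samples_per_batch=[25, 25, 25],
                                 batch_shift_sd=1.0, batch_scale_sd=0.2,
                                 probe_count_weights={1: 1.0},
                                 frac_unannotated_probes=0.0, seed=2)
        pm, _, _ = simulate.simulate_cohort(cfg)
        em = drop_unannotated_and_aggregate(pm)
        adj = combat_adjust(em)
        b = adj.metadata.table["batch"].to_numpy()
        groups = [adj.values.to_numpy()[:, b == lab]
                  for lab in np.unique(b)]
        _, p = stats.f_oneway(*groups, axis=1)
        assert (p < 0.05).mean() <= 0.05

    def test_planted_phenotype_effect_survives_balanced_correction(self):
        cfg = simulate.reference_config(seed=13, n_genes=300, module_size=30,
                                        n_de=8, n_samples_per_batch=(40, 40))
        pm, _, truth = simulate.simulate_cohort(cfg)
        em = drop_unannotated_and_aggregate(pm)
        adj = combat_adjust(em)
        y = adj.metadata.phenotype_code.to_numpy()
        de = [g for g, d in truth.de_direction.items() if d == "down"]
        x = adj.values.loc[de].to_numpy()
        observed = x[:, y == 1].mean(axis=1) - x[:, y == 0].mean(axis=1)
        expected = np.array([truth.true_log2fc[g] for g in de])
        # mean planted effect preserved within 10%
        assert abs(observed.mean() - expected.mean()) < 0.1 * abs(expected.mean())
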