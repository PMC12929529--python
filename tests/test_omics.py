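"""Expression preprocessing: TPM conservation, leak-free z-scoring, DEG screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prommf.omics import (
    DEGRecord,
    ExpressionMatrix,
    OmicsFeaturizer,
    counts_to_cpm,
    counts_to_tpm,
    differential_expression,
    log_z_normalize,
    read_counts,
    read_deg_table,
    select_degs,
    write_counts,
    write_deg_table,
)


def _em(values, patients=None, genes=None, stage="counts"):
    values = np.atleast_2d(np.asarray(values))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    patients = patients or [f"p{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=patients),
                            stage=stage)


class TestTPM:
    def test_hand_computed_two_gene_example(self):
        tpm = counts_to_tpm(_em([[10], [10]]), np.array([1000, 2000]))
        assert np.allclose(tpm.values.to_numpy().ravel(),
                           [666666.6667, 333333.3333], rtol=1e-6)

    def test_single_gene_forces_one_million(self):
        tpm = counts_to_tpm(_em([[37]]), np.array([812]))
        assert np.isclose(tpm.values.iloc[0, 0], 1e6)

    def test_columns_conserve_one_million(self, rng):
        counts = rng.integers(0, 500, size=(50, 12))
        counts[0] += 1  # no all-zero column
        tpm = counts_to_tpm(_em(counts), rng.integers(200, 5000, size=50))
        assert np.allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_error_cases(self):
        with pytest.raises(ValueError, match="all-zero"):
            counts_to_tpm(_em([[0], [0]]), np.array([100, 100]))
        with pytest.raises(ValueError, match="genes"):
            counts_to_tpm(_em([[1], [2]]), np.array([100]))
        with pytest.raises(ValueError, match="positive"):
            counts_to_tpm(_em([[1], [2]]), np.array([100, 0]))

    def test_cpm_fallback_conserves(self):
        cpm = counts_to_cpm(_em([[10, 5], [30, 15]]))
        assert np.allclose(cpm.values.sum(axis=0), 1e6)


class TestZScore:
    def test_fit_on_all_patients_standardises_each_gene(self, rng):
        tpm = _em(rng.gamma(2, 100, size=(20, 30)), stage="tpm")
        z = log_z_normalize(tpm, tpm.patient_ids)
        assert np.allclose(z.values.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.values.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_constant_gene_is_zeroed_and_flagged(self):
        tpm = _em([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], stage="tpm")
        z = log_z_normalize(tpm, tpm.patient_ids)
        assert np.all(z.values.iloc[0] == 0)
        assert z.zero_variance_genes == ["g0"]

    def test_held_out_patient_at_fit_mean_gets_zero(self):
        # fit on p0..p2; p3's value equals the fit-set mean on the log scale
        vals = np.array([[1.0, 4.0, 9.0, 0.0]])
        fit_log_mean = np.log2(vals[0, :3] + 1).mean()
        vals[0, 3] = 2.0 ** fit_log_mean - 1.0
        z = log_z_normalize(_em(vals, stage="tpm"), ["p0", "p1", "p2"])
        assert np.isclose(z.values.iloc[0, 3], 0.0, atol=1e-12)

    def test_disjoint_fit_set_errors(self):
        tpm = _em([[1.0, 2.0]], stage="tpm")
        with pytest.raises(ValueError, match="disjoint"):
            log_z_normalize(tpm, ["nobody"])

    def test_stage_ordering_enforced(self):
        with pytest.raises(ValueError, match="tpm"):
            log_z_normalize(_em([[1.0]]), ["p0"])  # still counts stage


class TestDifferentialExpression:
    def test_null_pvalues_are_uniform(self, rng):
        """No planted effect: KS statistic vs U(0,1) below the 5% critical value."""
        n_genes, n = 2000, 100
        counts = rng.negative_binomial(5, 0.1, size=(n_genes, 2 * n))
        y = np.r_[np.ones(n, int), np.zeros(n, int)]
        recs = differential_expression(_em(counts), y)
        pvals = np.array([r.p_value for r in recs])
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 1.36 / np.sqrt(n_genes)

    def test_planted_gene_logfc_recovered(self):
        """At ~200 patients per group the screen recovers a planted logFC of 3."""
        from prommf.syncohort import SyntheticSpec, generate_cohort

        # a realistic transcriptome width keeps library-size composition bias
        # (planted DE genes inflating one group's totals) negligible
        spec = SyntheticSpec(n_patients=400, prevalence=0.5, n_genes=2000,
                             n_de_up=8, n_de_down=8, de_logfc=3.0,
                             nb_dispersion=0.4, bag_size_range=(1, 2),
                             embedding_dim=8, signal_dim=4, seed=21)
        cohort = generate_cohort(spec)
        counts = ExpressionMatrix(cohort.counts_frame(), stage="counts")
        recs = differential_expression(counts, cohort.labels)
        est = np.array([r.logFC for r in recs[:16]])
        assert np.all(np.abs(est[:8] - 3.0) < 0.5)
        assert np.all(np.abs(est[8:] + 3.0) < 0.5)

    def test_all_zero_gene_convention(self):
        counts = _em([[0, 0, 0, 0], [5, 6, 7, 8]])
        recs = differential_expression(counts, np.array([1, 1, 0, 0]))
        assert recs[0].logFC == 0.0 and recs[0].p_value == 1.0

    def test_swapping_groups_negates_logfc(self, rng):
        counts = _em(rng.integers(0, 200, size=(30, 20)))
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        fwd = differential_expression(counts, y)
        rev = differential_expression(counts, 1 - y)
        assert np.allclose([r.logFC for r in fwd], [-r.logFC for r in rev])

    def test_unknown_method_lists_options(self):
        with pytest.raises(ValueError, match="wilcoxon"):
            differential_expression(_em([[1, 2]]), np.array([1, 0]), method="deseq")

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            differential_expression(_em([[1, 2]]), np.array([1, 1]))


class TestSelectDEGs:
    TOY = [
        DEGRecord("a", 3.1, 0.01),
        DEGRecord("b", -2.5, 0.04),
        DEGRecord("c", 2.5, 0.2),
        DEGRecord("d", -1.0, 0.001),
        DEGRecord("e", 4.0, 0.049),
    ]

    def test_toy_table_yields_two_up_one_down(self):
        up, down = select_degs(self.TOY)
        assert [r.gene_id for r in up] == ["a", "e"]
        assert [r.gene_id for r in down] == ["b"]

    def test_boundary_logfc_exactly_two_is_excluded(self):
        with pytest.warns(UserWarning):  # empty selection also warns
            up, down = select_degs([DEGRecord("x", 2.0, 0.01)])
        assert up == [] and down == []

    def test_empty_input_gives_empty_lists(self):
        assert select_degs([]) == ([], [])

    def test_empty_selection_warns(self):
        with pytest.warns(UserWarning, match="no genes"):
            select_degs([DEGRecord("x", 0.5, 0.9)])


class TestFeaturizer:
    def test_features_are_train_fitted_zscores(self, small_cohort):
        counts = ExpressionMatrix(small_cohort.counts_frame(), stage="counts")
        ids = small_cohort.patient_ids
        train = ids[:40]
        y = np.array([small_cohort.record(p).label for p in train])
        feat = OmicsFeaturizer().fit(counts, y,
                                     gene_lengths=small_cohort.gene_lengths,
                                     fit_patients=train)
        X = feat.transform(ids[40:])
        assert X.shape == (20, feat.n_features_out_)
        assert feat.n_features_out_ > 0
        assert set(feat.fit_patient_ids_) == set(train)

    def test_external_deg_list_bypasses_screen(self, small_cohort):
        counts = ExpressionMatrix(small_cohort.counts_frame(), stage="counts")
        train = small_cohort.patient_ids[:40]
        y = np.array([small_cohort.record(p).label for p in train])
        feat = OmicsFeaturizer(deg_genes=["G00000", "G00003"]).fit(
            counts, y, fit_patients=train)
        assert feat.feature_genes_ == ["G00000", "G00003"]


def test_counts_and_deg_table_roundtrip(tmp_path, rng):
    em = _em(rng.integers(0, 100, size=(8, 4)))
    write_counts(em, tmp_path / "c.tsv")
    back = read_counts(tmp_path / "c.tsv")
    assert np.array_equal(back.values.to_numpy(), em.values.to_numpy())
    recs = [DEGRecord("a", 2.5, 0.01, "up"), DEGRecord("b", -0.3, 0.7, "ns")]
    write_deg_table(recs, tmp_path / "deg.tsv")
    back_recs = read_deg_table(tmp_path / "deg.tsv")
    assert back_recs[0].gene_id == "a" and back_recs[0].direction == "up"
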