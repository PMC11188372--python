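"""QC filtering, RPM/log2 normalization, replicate-outlier flagging and
PC-regression extrapolation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import toxregulon as tr
from toxregulon.io import ExpressionMatrix, QC_COLUMNS

THRESHOLD_VALUES = {
    "sequencing_depth": 300_000,
    "total_alignment_rate": 40.0,
    "unique_alignment_rate": 30.0,
    "aligned_reads": 300_000,
    "pct_probes_ge5": 50.0,
}

GOOD_METRICS = {
    "sequencing_depth": 2_000_000,
    "total_alignment_rate": 90.0,
    "unique_alignment_rate": 70.0,
    "aligned_reads": 1_800_000,
    "pct_probes_ge5": 85.0,
}


def qc_frame(**overrides):
    row = {"sample_id": "s1", **GOOD_METRICS, **overrides}
    return pd.DataFrame([row])


class TestQCFilter:
    @pytest.mark.parametrize("metric", QC_COLUMNS)
    def test_one_unit_below_threshold_fails_and_names_the_rule(self, metric):
        result = tr.qc_filter(qc_frame(**{metric: THRESHOLD_VALUES[metric] - 1}))
        assert not result.loc[0, "qc_pass"]
        assert result.loc[0, "failed_rules"] == metric

    def test_metrics_exactly_at_thresholds_pass(self):
        result = tr.qc_filter(qc_frame(**THRESHOLD_VALUES))
        assert result.loc[0, "qc_pass"]
        assert result.loc[0, "failed_rules"] == ""

    def test_comfortable_metrics_pass_with_no_failed_rules(self):
        result = tr.qc_filter(qc_frame())
        assert result.loc[0, "qc_pass"] and result.loc[0, "failed_rules"] == ""

    def test_missing_metric_names_sample_and_metric(self):
        with pytest.raises(ValueError, match="s1.*aligned_reads"):
            tr.qc_filter(qc_frame(aligned_reads=np.nan))

    @given(
        depth=st.integers(0, 600_000),
        bump=st.floats(0, 200_000, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_raising_a_threshold_never_converts_fail_to_pass(self, depth, bump):
        frame = qc_frame(sequencing_depth=depth)
        base = tr.qc_filter(frame, tr.QCThresholds()).loc[0, "qc_pass"]
        raised = tr.qc_filter(frame, tr.QCThresholds(min_depth=300_000 + bump)).loc[0, "qc_pass"]
        assert base or not raised


class TestNormalization:
    def test_rpm_column_arithmetic(self):
        counts = ExpressionMatrix(
            pd.DataFrame({"s1": [1, 1, 2]}, index=["g1", "g2", "g3"]), "counts"
        )
        rpm = tr.normalize_rpm(counts)
        assert rpm.data["s1"].tolist() == [250_000, 250_000, 500_000]

    def test_all_zero_column_raises_zero_library_size(self):
        counts = ExpressionMatrix(pd.DataFrame({"bad": [0, 0]}, index=["g1", "g2"]), "counts")
        with pytest.raises(ValueError, match="zero library size.*bad"):
            tr.normalize_rpm(counts)

    def test_random_matrix_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = ExpressionMatrix(
            pd.DataFrame(rng.integers(0, 1000, (50, 8)) + 1, columns=[f"s{i}" for i in range(8)]),
            "counts",
        )
        rpm = tr.normalize_rpm(counts)
        np.testing.assert_allclose(rpm.data.sum(axis=0), 1e6, rtol=1e-9)

    @pytest.mark.parametrize("value,expected", [(0.0, 0.0), (1.0, 1.0), (999_999.0, np.log2(1e6))])
    def test_log_transform_values(self, value, expected):
        rpm = ExpressionMatrix(pd.DataFrame({"s1": [value]}, index=["g"]), "rpm")
        assert tr.log_transform(rpm).data.iloc[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_log_transform_rejects_negative_values(self):
        rpm = ExpressionMatrix(pd.DataFrame({"s1": [-0.1]}, index=["g"]), "rpm")
        with pytest.raises(ValueError, match="non-negative"):
            tr.log_transform(rpm)

    def test_rpm_log_pipeline_invariant_to_library_scaling(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 500, (40, 3))
        scaled = base.copy()
        scaled[:, 1] *= 7  # one sample sequenced 7x deeper
        genes = [f"g{i}" for i in range(40)]
        out_a = tr.log_transform(
            tr.normalize_rpm(ExpressionMatrix(pd.DataFrame(base, index=genes), "counts"))
        )
        out_b = tr.log_transform(
            tr.normalize_rpm(ExpressionMatrix(pd.DataFrame(scaled, index=genes), "counts"))
        )
        np.testing.assert_allclose(out_a.data, out_b.data, atol=1e-9)


def _replicate_group(n_samples=5, n_genes=200, seed=0, scramble_last=False):
    rng = np.random.default_rng(seed)
    profile = rng.normal(6, 2, n_genes)
    data = profile[:, None] + rng.normal(0, 0.2, (n_genes, n_samples))
    if scramble_last:
        data[:, -1] = rng.normal(6, 2, n_genes)  # independent noise, uncorrelated
    ids = [f"s{i}" for i in range(n_samples)]
    em = ExpressionMatrix(pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)], columns=ids), "log2")
    md = pd.DataFrame(
        {
            "sample_id": ids,
            "chemical": "c1",
            "class": "PFAS",
            "dose_mg_per_kg": 10.0,
            "sex": "male",
            "replicate": range(1, n_samples + 1),
        }
    )
    return em, md


class TestFlagOutliers:
    def test_identical_replicates_are_never_flagged(self):
        em, md = _replicate_group()
        data = em.data.copy()
        for col in data.columns:
            data[col] = data.iloc[:, 0]
        flags = tr.flag_outliers(ExpressionMatrix(data, "log2"), md, min_median_corr=0.9)
        assert not flags.any()

    def test_scrambled_replicate_is_the_only_one_flagged(self):
        em, md = _replicate_group(scramble_last=True, seed=4)
        flags = tr.flag_outliers(em, md, min_median_corr=0.9)
        assert flags.tolist() == [False, False, False, False, True]

    def test_groups_of_two_are_never_flagged(self):
        em, md = _replicate_group(n_samples=2, seed=2)
        em.data.iloc[:, 1] = -em.data.iloc[:, 1]  # anticorrelated pair
        flags = tr.flag_outliers(ExpressionMatrix(em.data, "log2"), md)
        assert not flags.any()

    def test_flags_invariant_to_sample_order(self):
        em, md = _replicate_group(scramble_last=True, seed=8)
        flags = tr.flag_outliers(em, md, min_median_corr=0.9)
        perm = ["s3", "s0", "s4", "s1", "s2"]
        em2 = ExpressionMatrix(em.data[perm], "log2")
        md2 = md.set_index("sample_id").loc[perm].reset_index()
        flags2 = tr.flag_outliers(em2, md2, min_median_corr=0.9)
        assert flags.sort_index().equals(flags2.sort_index())


class TestPCRExtrapolation:
    def test_noiseless_rank3_compendium_recovered_exactly(self):
        comp = tr.simulate_compendium(60, 300, latent_rank=3, measured_fraction=0.2, noise_sd=0.0, seed=1)
        model = tr.fit_pcr_extrapolator(comp, n_components=3)
        recon = model.predict(comp.expression.loc[comp.measured_genes], passthrough=False)
        assert np.abs(recon.to_numpy() - comp.expression.to_numpy()).max() < 1e-8

    def test_all_genes_measured_reproduces_compendium(self):
        comp = tr.simulate_compendium(30, 80, latent_rank=4, measured_fraction=1.0, noise_sd=0.0, seed=2)
        model = tr.fit_pcr_extrapolator(comp, n_components=4)
        recon = model.predict(comp.expression, passthrough=False)
        assert np.abs(recon.to_numpy() - comp.expression.to_numpy()).max() < 1e-8

    def test_constant_gene_gets_zero_coefficients_and_constant_offset(self):
        comp = tr.simulate_compendium(30, 80, latent_rank=2, measured_fraction=0.3, noise_sd=0.0, seed=3)
        expr = comp.expression.copy()
        expr.loc["G00001"] = 5.5
        comp = tr.Compendium(expr, [g for g in comp.measured_genes if g != "G00001"], 2, 0.0)
        model = tr.fit_pcr_extrapolator(comp, n_components=2)
        i = model.output_genes.index("G00001")
        np.testing.assert_allclose(model.coef[:, i], 0.0, atol=1e-10)
        assert model.intercepts[i] == pytest.approx(5.5)

    def test_fresh_samples_from_same_generative_model_predicted(self):
        rng = np.random.default_rng(5)
        comp = tr.simulate_compendium(60, 300, latent_rank=3, measured_fraction=0.25, noise_sd=0.0, seed=5)
        model = tr.fit_pcr_extrapolator(comp, n_components=3)
        # rebuild the latent factors from the compendium itself and draw new samples
        centered = comp.expression.to_numpy() - comp.expression.to_numpy().mean(axis=1, keepdims=True)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        loadings = u[:, :3] * s[:3] / np.sqrt(centered.shape[1])
        scores = rng.normal(size=(3, 10))
        truth = comp.expression.to_numpy().mean(axis=1, keepdims=True) + loadings @ scores
        truth = pd.DataFrame(truth, index=comp.expression.index, columns=[f"n{i}" for i in range(10)])
        new = ExpressionMatrix(truth.loc[comp.measured_genes], "log2")
        pred = tr.apply_extrapolator(model, new)
        assert np.abs(pred.data.to_numpy() - truth.to_numpy()).max() < 1e-6

    def test_mean_input_predicts_compendium_means(self):
        comp = tr.simulate_compendium(40, 100, latent_rank=3, measured_fraction=0.3, noise_sd=0.1, seed=6)
        model = tr.fit_pcr_extrapolator(comp, n_components=3)
        means = comp.expression.loc[comp.measured_genes].mean(axis=1)
        em = ExpressionMatrix(pd.DataFrame({"m": means}), "log2")
        pred = tr.apply_extrapolator(model, em, passthrough=False)
        np.testing.assert_allclose(pred.data["m"], comp.expression.mean(axis=1), atol=1e-8)

    def test_gene_order_permutation_leaves_output_unchanged(self):
        comp = tr.simulate_compendium(40, 100, latent_rank=3, measured_fraction=0.3, noise_sd=0.0, seed=7)
        model = tr.fit_pcr_extrapolator(comp, n_components=3)
        measured = comp.expression.loc[comp.measured_genes, ["ref0001", "ref0002"]]
        a = tr.apply_extrapolator(model, ExpressionMatrix(measured, "log2"))
        b = tr.apply_extrapolator(model, ExpressionMatrix(measured.iloc[::-1], "log2"))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_gene_set_mismatch_lists_missing_genes(self):
        comp = tr.simulate_compendium(20, 50, latent_rank=2, measured_fraction=0.2, noise_sd=0.0, seed=8)
        model = tr.fit_pcr_extrapolator(comp, n_components=2)
        partial = comp.expression.loc[comp.measured_genes[:-1], ["ref0001"]]
        with pytest.raises(ValueError, match=comp.measured_genes[-1]):
            tr.apply_extrapolator(model, ExpressionMatrix(partial, "log2"))

    def test_component_count_beyond_rank_limit_rejected(self):
        comp = tr.simulate_compendium(10, 50, latent_rank=2, measured_fraction=0.2, noise_sd=0.0, seed=9)
        with pytest.raises(ValueError, match="n_components"):
            tr.fit_pcr_extrapolator(comp, n_components=11)
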