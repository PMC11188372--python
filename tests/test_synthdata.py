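"""Synthetic-data generator: design arithmetic, planted-effect fidelity,
noise calibration and determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import toxregulon as tr
from toxregulon.synthdata import dose_effect_scale


class TestSimulateRegulons:
    def test_fixed_target_count_without_overlap_gives_disjoint_regulons(self):
        reg = tr.simulate_regulons(n_tfs=2, targets_per_tf=(3, 3), overlap_prob=0.0, seed=0)
        assert len(reg) == 6
        t1 = set(reg.loc[reg["tf"] == "TF001", "target"])
        t2 = set(reg.loc[reg["tf"] == "TF002", "target"])
        assert len(t1) == len(t2) == 3
        assert t1.isdisjoint(t2)

    def test_degenerate_mode_simplex_forces_single_mode(self):
        reg = tr.simulate_regulons(n_tfs=3, targets_per_tf=(5, 10), mode_probs=(1, 0, 0), seed=0)
        assert (reg["mode"] == "Activation").all()

    def test_mode_fractions_fall_in_exact_binomial_intervals(self):
        """Realized mode counts of a large table lie in independently computed
        99% binomial intervals around the requested probabilities."""
        probs = (0.5, 0.3, 0.2)
        reg = tr.simulate_regulons(n_tfs=19, targets_per_tf=(5, 300), mode_probs=probs, seed=42)
        n = len(reg)
        counts = reg["mode"].value_counts()
        for mode, p in zip(("Activation", "Repression", "Unknown"), probs):
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= counts.get(mode, 0) <= hi

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            tr.simulate_regulons(n_tfs=2, mode_probs=(0.5, 0.5, 0.5))

    def test_seed_reproducibility(self):
        a = tr.simulate_regulons(n_tfs=4, seed=9)
        b = tr.simulate_regulons(n_tfs=4, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateStudy:
    def test_sample_count_follows_design_arithmetic(self, small_regulons):
        design = tr.StudyDesign(
            [tr.Chemical("c1", "PFAS", (1.0, 10.0))], n_treated=5, n_control=10, n_genes=120
        )
        bundle = tr.simulate_study(design, small_regulons, seed=0)
        # 2 doses x 5 treated x 2 sexes + 10 controls x 2 sexes
        assert bundle.expression.data.shape[1] == 2 * 5 * 2 + 10 * 2 == 40
        assert list(bundle.metadata["sample_id"]) == list(bundle.expression.samples)

    def test_null_study_fc_tail_matches_normal_theory(self, small_regulons):
        """With no planted effects the fraction of |log2FC| >= 0.6 cells
        matches the closed-form two-sided normal tail for
        sd = noise_sd * sqrt(1/n_treated + 1/n_control)."""
        design = tr.StudyDesign(
            [tr.Chemical("c1", "PFAS", (1.0, 10.0, 100.0))], n_treated=5, n_control=10, n_genes=2000
        )
        bundle = tr.simulate_study(design, small_regulons.iloc[:0], noise_sd=0.5, seed=3)
        fc = tr.build_fc_table(bundle.expression, bundle.metadata)
        sd = 0.5 * math.sqrt(1 / 5 + 1 / 10)
        p0 = 2 * stats.norm.sf(0.6 / sd)
        observed = (fc["log2fc"].abs() >= 0.6).mean()
        se = math.sqrt(p0 * (1 - p0) / len(fc))
        assert abs(observed - p0) <= 3 * se
        # grand mean of realized fold changes is centred on zero
        assert abs(fc["log2fc"].mean()) <= 3 * sd / math.sqrt(len(fc))

    def test_planted_effect_realized_at_top_dose_in_target_sex_only(self, small_regulons):
        design = tr.StudyDesign(
            [tr.Chemical("c1", "PFAS", (1.0, 10.0, 100.0))], n_treated=5, n_control=10, n_genes=400
        )
        targets = sorted(set(small_regulons.loc[small_regulons["tf"] == "TF001", "target"]))
        effect = tr.PlantedEffect(tf="TF001", direction="up", max_log2fc=2.0, sexes=("male",))
        bundle = tr.simulate_study(design, small_regulons, [effect], noise_sd=0.5, seed=5)
        fc = tr.build_fc_table(bundle.expression, bundle.metadata)
        top = fc[fc["dose_mg_per_kg"] == 100.0].set_index(["sex", "gene"])
        sd_fc = 0.5 * math.sqrt(1 / 5 + 1 / 10)
        se = sd_fc / math.sqrt(len(targets))
        male_mean = top.loc["male"].loc[targets, "log2fc"].mean()
        female_mean = top.loc["female"].loc[targets, "log2fc"].mean()
        assert abs(male_mean - 2.0) <= 3 * se
        assert abs(female_mean) <= 3 * se

    def test_truth_table_is_exhaustive_and_unique(self, planted_study):
        truth = planted_study.truth
        keys = truth[["gene", "chemical", "dose_mg_per_kg", "sex"]]
        assert not keys.duplicated().any()
        targets = planted_study.truth["gene"].nunique()
        # one row per (target, chemical-in-class, dose, planted sex)
        assert len(truth) == targets * 2 * 3 * 1

    def test_unknown_tf_in_effect_raises_with_name(self, small_design, small_regulons):
        effect = tr.PlantedEffect(tf="NOPE1", max_log2fc=1.0)
        with pytest.raises(ValueError, match="NOPE1"):
            tr.simulate_study(small_design, small_regulons, [effect], seed=0)

    def test_counts_mode_column_sums_near_drawn_library_sizes(self, small_regulons):
        design = tr.StudyDesign(
            [tr.Chemical("c1", "PFAS", (1.0, 10.0))], n_treated=2, n_control=2, n_genes=200
        )
        lo, hi = 200_000, 400_000
        bundle = tr.simulate_study(
            design, small_regulons, noise_sd=0.3, mode="counts", libsize_range=(lo, hi), seed=1
        )
        assert bundle.expression.scale == "counts"
        colsums = bundle.expression.data.sum(axis=0)
        slack = 3 * math.sqrt(hi)  # Poisson fluctuation around the drawn size
        assert ((colsums >= lo - slack) & (colsums <= hi + slack)).all()

    def test_seed_reproduces_bundle_exactly(self, small_design, small_regulons):
        a = tr.simulate_study(small_design, small_regulons, noise_sd=0.2, seed=13)
        b = tr.simulate_study(small_design, small_regulons, noise_sd=0.2, seed=13)
        pd.testing.assert_frame_equal(a.expression.data, b.expression.data)
        pd.testing.assert_frame_equal(a.qc, b.qc)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_qc_fail_fraction_injects_failing_samples(self, small_design, small_regulons):
        bundle = tr.simulate_study(
            small_design, small_regulons, qc_fail_fraction=0.25, seed=2
        )
        result = tr.qc_filter(bundle.qc, tr.QCThresholds())
        n = len(bundle.qc)
        assert (~result["qc_pass"]).sum() == round(0.25 * n)


class TestDoseShapes:
    @pytest.mark.parametrize("shape", ["linear_in_log_dose", "hill"])
    def test_shapes_are_monotone_and_bounded(self, shape):
        ladder = (0.15, 0.5, 1.4, 4, 12, 37, 111, 333, 1000)
        values = [dose_effect_scale(d, ladder, shape) for d in ladder]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert all(0 < v <= 1 for v in values)

    def test_linear_in_log_dose_reaches_one_at_top_dose(self):
        assert dose_effect_scale(1000, (0.15, 1000), "linear_in_log_dose") == pytest.approx(1.0)


class TestSimulateCompendium:
    def test_noiseless_matrix_has_the_requested_rank(self):
        comp = tr.simulate_compendium(40, 100, latent_rank=3, noise_sd=0.0, seed=0)
        centered = comp.expression.to_numpy() - comp.expression.to_numpy().mean(axis=1, keepdims=True)
        assert np.linalg.matrix_rank(centered, tol=1e-8) == 3

    def test_full_measured_fraction_covers_all_genes(self):
        comp = tr.simulate_compendium(10, 30, latent_rank=2, measured_fraction=1.0, seed=0)
        assert comp.measured_genes == list(comp.expression.index)

    def test_rank_exceeding_dimensions_rejected(self):
        with pytest.raises(ValueError, match="latent_rank"):
            tr.simulate_compendium(5, 30, latent_rank=6)
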