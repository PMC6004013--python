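"""QC-SVRC drift correction, between-batch scaling, filters, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from uromet.batch_correction import (
    CorrectionError,
    DEFAULT_GAMMA_GRID,
    apply_between_batch,
    apply_within_batch,
    compute_rsd,
    correct_table,
    fit_drift,
    fit_drift_models,
    filter_blank_features,
    filter_rsd,
    qc_rsd_per_feature,
    qc_trend_diagnostics,
    select_hyperparams,
)
from uromet.core_io import ROLE_QC, exclude_conditioning
from uromet.synthetic import SyntheticConfig, generate_cohort


class TestComputeRsd:
    def test_constant_input_is_zero(self):
        assert compute_rsd([5, 5, 5]) == 0.0

    def test_hand_value(self):
        # sd([90,100,110]) = 10, mean = 100
        assert compute_rsd([90, 100, 110]) == pytest.approx(10.0)

    def test_degenerate_inputs_flagged_nan(self):
        assert np.isnan(compute_rsd([np.nan, np.nan]))
        assert np.isnan(compute_rsd([1.0]))
        assert np.isnan(compute_rsd([0.0, 0.0, 0.0]))


class TestHyperparamRules:
    def test_epsilon_and_cost_from_qc_median(self):
        orders = np.arange(1, 11, dtype=float)
        values = np.full(10, 1000.0)
        values[0] = 999.0  # break exact ties without moving the median
        hp = select_hyperparams(orders, values)
        assert hp.cost == pytest.approx(1000.0)
        assert hp.epsilon == pytest.approx(25.0)

    def test_gamma_grid_has_13_members(self):
        assert len(DEFAULT_GAMMA_GRID) == 13
        assert DEFAULT_GAMMA_GRID[0] == 2.0**-3
        assert DEFAULT_GAMMA_GRID[-1] == 2.0**9

    def test_gamma_tie_breaks_to_smallest(self):
        # constant QC values: every gamma predicts inside the tube, all tie
        orders = np.arange(1, 13, dtype=float)
        values = np.full(12, 500.0)
        hp = select_hyperparams(orders, values)
        assert hp.gamma == DEFAULT_GAMMA_GRID[0]
        rmse = hp.rmsecv
        best = min(rmse.values())
        ties = [g for g in DEFAULT_GAMMA_GRID if rmse[g] == best]
        assert hp.gamma == min(ties)

    def test_too_few_qcs_errors(self):
        with pytest.raises(CorrectionError):
            select_hyperparams([1, 2], [10.0, 11.0])


class TestFitDrift:
    def test_linear_trend_within_tube(self):
        orders = np.arange(5, 51, 5, dtype=float)
        trend = 100.0 + (orders - 1) * (50.0 / 49.0)
        hp = select_hyperparams(orders, trend)
        model = fit_drift(orders, trend, hp)
        err = np.abs(model.predict(orders) - trend)
        assert np.all(err <= hp.epsilon * (1 + 1e-3))

    def test_constant_values_recovered(self):
        orders = np.arange(1, 11, dtype=float)
        values = np.full(10, 250.0)
        hp = select_hyperparams(orders, values)
        model = fit_drift(orders, values, hp)
        assert np.all(np.abs(model.predict(orders) - 250.0) <= hp.epsilon + 1e-9)

    def test_noisy_fit_stays_positive(self):
        rng = np.random.default_rng(1)
        orders = np.arange(1, 31, dtype=float)
        values = 100.0 * np.exp(rng.normal(0, 0.1, 30))
        hp = select_hyperparams(orders, values)
        model = fit_drift(orders, values, hp)
        assert np.all(model.predict(np.arange(1, 100)) > 0)


class TestWithinBatch:
    def test_flat_drift_is_identity(self, clean_cohort):
        table, _ = clean_cohort
        work = exclude_conditioning(table)
        models = fit_drift_models(work)
        out = apply_within_batch(work, models)
        with np.errstate(invalid="ignore"):  # blanks are 0/0
            ratio = out.intensities.to_numpy(float) / work.intensities.to_numpy(float)
        np.testing.assert_allclose(ratio[np.isfinite(ratio)], 1.0, rtol=1e-6)

    def test_zero_noise_drift_cancels_at_qcs(self):
        cfg = SyntheticConfig(
            n_features=15, n_discriminant=0, n_background=0, n_blanks=0,
            n_patients_bc=12, n_patients_monitor=0, drift_amplitude=0.3,
            between_batch_log2_range=0.0, noise_rsd=0.0, n_batches=1, seed=3,
        )
        table, _ = generate_cohort(cfg)
        work = exclude_conditioning(table)
        models = fit_drift_models(work)
        out = apply_within_batch(work, models)
        qc = out.intensities.loc[out.role_mask(ROLE_QC)].to_numpy(float)
        for j, fid in enumerate(out.feature_ids):
            ref = models[(fid, 1)].qc_reference
            eps = models[(fid, 1)].hyperparams.epsilon
            # corrected QC intensities collapse to the reference within the tube
            assert np.all(np.abs(qc[:, j] - ref) <= ref * 0.05 + eps)

    def test_rsd_improves_when_drift_dominates_noise(self):
        """drift 0.3 >= 3 x noise 0.08: correction lowers median QC RSD (5 seeds)."""
        for seed in range(5):
            cfg = SyntheticConfig(
                n_features=10, n_discriminant=0, n_background=0, n_blanks=0,
                n_patients_bc=12, n_patients_monitor=0, drift_amplitude=0.3,
                between_batch_log2_range=0.0, noise_rsd=0.08, n_batches=1,
                seed=100 + seed,
            )
            table, _ = generate_cohort(cfg)
            work = exclude_conditioning(table)
            before = qc_rsd_per_feature(work).median()
            out = apply_within_batch(work, fit_drift_models(work))
            after = qc_rsd_per_feature(out).median()
            assert after < before

    def test_missing_stays_missing(self, hand_table):
        work = exclude_conditioning(hand_table)
        models = fit_drift_models(work)  # falls back to constants (2 QCs)
        out = apply_within_batch(work, models)
        assert np.isnan(out.intensities.loc["S3", "F2"])


class TestBetweenBatch:
    def _two_batch_table(self):
        import pandas as pd
        from uromet.core_io import FeatureTable
        rows = []
        for b, meds in ((1, [80, 100, 120]), (2, [240, 300, 360])):
            for i, v in enumerate(meds):
                rows.append((f"Q{b}{i}", None, b, i + 1, "QC", None, None, float(v)))
            rows.append((f"S{b}", f"P{b}", b, 4, "STUDY", "BC", 0, 100.0 * b))
        samples = pd.DataFrame(
            [r[:7] for r in rows],
            columns=["sample_id", "patient_id", "batch", "injection_order",
                     "role", "class_label", "visit_index"],
        ).set_index("sample_id")
        features = pd.DataFrame({"mz": [111.1], "rt": [1.0]},
                                index=pd.Index(["F1"], name="feature_id"))
        intens = pd.DataFrame({"F1": [r[7] for r in rows]}, index=samples.index)
        return FeatureTable(intens, samples, features).validate()

    def test_direct_arithmetic(self):
        table = self._two_batch_table()
        out = apply_between_batch(table)
        # batch QC medians 100 and 300, cross-batch level 200:
        # batch 1 scales by 2.0, batch 2 by 2/3
        x = out.intensities["F1"]
        assert x["Q10"] == pytest.approx(80 * 2.0)
        assert x["Q20"] == pytest.approx(240 * 2.0 / 3.0)
        qc1 = x[["Q10", "Q11", "Q12"]].median()
        qc2 = x[["Q20", "Q21", "Q22"]].median()
        assert qc1 == pytest.approx(qc2)

    def test_single_batch_is_identity(self, hand_table):
        out = apply_between_batch(hand_table)
        pd.testing.assert_frame_equal(out.intensities, hand_table.intensities)

    def test_qc_medians_equalize_on_any_input(self, small_cohort):
        table, _ = small_cohort
        work = exclude_conditioning(table)
        out = apply_between_batch(work)
        qc = out.samples["role"] == "QC"
        for fid in out.feature_ids:
            meds = out.intensities.loc[qc, fid].groupby(out.samples.loc[qc, "batch"]).median()
            assert meds.max() == pytest.approx(meds.min(), rel=1e-9)


class TestFilters:
    def test_blank_median_rule(self, small_cohort):
        table, truth = small_cohort
        work = exclude_conditioning(table)
        filtered, removed = filter_blank_features(work, 1.0 / 3.0)
        # the generator's designated background features are all removed
        assert set(truth.background_feature_ids) <= set(removed[removed].index)
        assert set(truth.background_feature_ids).isdisjoint(filtered.feature_ids)

    def test_blank_zero_retained_and_half_removed(self, hand_table):
        work = exclude_conditioning(hand_table)
        X = work.intensities.copy()
        X.loc["S6"] = [0.0, 50.0, 5.0]      # blank
        X.loc["S2"] = [100.0, 100.0, 100.0]  # the only QC
        work.intensities = X
        filtered, removed = filter_blank_features(work, 1.0 / 3.0)
        assert not removed["F1"]     # blank median 0 -> retained
        assert removed["F2"]         # 50 >= 100/3 -> removed
        assert not removed["F3"]     # 5 < 100/3 -> retained

    def test_rsd_threshold_strict_and_monotone(self):
        cfg = SyntheticConfig(n_features=60, n_discriminant=0, n_background=0,
                              n_blanks=0, n_patients_bc=12, n_patients_monitor=0,
                              drift_amplitude=0.2, noise_rsd=0.12, n_batches=1, seed=8)
        table, _ = generate_cohort(cfg)
        work = exclude_conditioning(table)
        kept15, rsd = filter_rsd(work, 15.0)
        kept20, _ = filter_rsd(work, 20.0)
        assert set(kept15.feature_ids) <= set(kept20.feature_ids)
        # boundary: exactly at the threshold is retained (strict >)
        at = rsd[np.isclose(rsd, 15.0)]
        for fid in at.index:
            assert fid in kept15.feature_ids
        # and a feature at 16% would be removed under the 15% rule
        removed = set(work.feature_ids) - set(kept15.feature_ids)
        assert all(rsd[f] > 15.0 or np.isnan(rsd[f]) for f in removed)


class TestDiagnostics:
    def test_identical_qcs_give_zero_scores(self, clean_cohort):
        table, _ = clean_cohort
        diag = qc_trend_diagnostics(exclude_conditioning(table))
        pcs = diag.scores[["PC1", "PC2", "PC3"]].to_numpy()
        assert np.allclose(pcs, 0.0, atol=1e-6)

    def test_rsd_cdf_monotone_ends_at_one(self, small_cohort):
        table, _ = small_cohort
        diag = qc_trend_diagnostics(exclude_conditioning(table))
        x, F = diag.rsd_cdf()
        assert np.all(np.diff(x) >= 0)
        assert np.all(np.diff(F) > 0)
        assert F[-1] == pytest.approx(1.0)

    def test_correction_reduces_pc1_order_correlation(self):
        cfg = SyntheticConfig(n_features=40, n_discriminant=0, n_background=0,
                              n_blanks=0, n_patients_bc=14, n_patients_monitor=0,
                              drift_amplitude=0.35, between_batch_log2_range=0.0,
                              noise_rsd=0.05, n_batches=1, seed=21)
        table, _ = generate_cohort(cfg)
        work = exclude_conditioning(table)
        before = qc_trend_diagnostics(work)
        out = apply_within_batch(work, fit_drift_models(work))
        after = qc_trend_diagnostics(out)

        def corr(diag):
            return abs(np.corrcoef(diag.scores["PC1"], diag.scores["injection_order"])[0, 1])

        assert corr(after) < corr(before)


class TestFullStack:
    def test_identity_when_perturbations_zero(self, clean_cohort):
        table, truth = clean_cohort
        corrected, report = correct_table(table)
        raw = exclude_conditioning(table)
        raw = raw.subset_features(corrected.feature_ids)
        np.testing.assert_allclose(
            corrected.intensities.to_numpy(float),
            raw.intensities.to_numpy(float),
            rtol=1e-6,
        )
        # only the designated background features were dropped
        dropped = set(table.feature_ids) - set(corrected.feature_ids)
        assert dropped == set(truth.background_feature_ids)

    def test_report_counts_consistent(self, small_cohort):
        table, _ = small_cohort
        corrected, report = correct_table(table)
        s = report.summary()
        assert s["n_retained"] == corrected.n_features
        assert s["n_retained"] + s["n_removed_rsd"] + s["n_removed_blank"] == s["n_features"]
        pf = report.per_feature
        assert ((pf["removal_reason"] == "none") == pf["retained"]).all()
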