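"""Drift correction and QC feature filters."""

import numpy as np
import pandas as pd
import pytest

from lwas.qc import (correct_drift, cv_filter, dilution_correlation,
                     linearity_filter, qc_cv, remove_redundancies,
                     run_qc_pipeline)

from conftest import make_table


def qc_pattern(n_study: int, every: int = 5) -> list[str]:
    types = []
    for j in range(n_study + n_study // every + 2):
        types.append("qc" if j % every == 0 else "study")
    return types


class TestDriftCorrection:
    def test_flat_qc_signal_leaves_areas_unchanged(self):
        types = qc_pattern(20)
        rng = np.random.default_rng(0)
        areas = rng.uniform(1e5, 1e6, size=(3, len(types)))
        qc_idx = [j for j, t in enumerate(types) if t == "qc"]
        areas[:, qc_idx] = 5e5  # constant QC signal
        t = make_table(areas, types)
        corrected, flags = correct_drift(t)
        assert flags["corrected"].all()
        np.testing.assert_allclose(corrected.areas.to_numpy(), areas,
                                   rtol=1e-9)

    def test_noiseless_linear_drift_removed_exactly(self):
        types = qc_pattern(30)
        n = len(types)
        order = np.arange(1, n + 1)
        base = 2e5
        areas = base * (1 + 0.01 * order)[None, :] * np.ones((2, 1))
        t = make_table(areas, types)
        corrected, _ = correct_drift(t)
        qc_cols = t.injections_of("qc")
        qc_vals = corrected.areas[qc_cols].to_numpy()
        # corrected QC signal is constant to 1e-6 relative
        np.testing.assert_allclose(qc_vals, qc_vals[0, 0], rtol=1e-6)
        # and the study injections are flattened too
        study_vals = corrected.areas[t.injections_of("study")].to_numpy()
        np.testing.assert_allclose(study_vals, study_vals[0, 0], rtol=1e-6)

    def test_noisy_drift_improves_qc_cv_for_most_features(self):
        from lwas.synthetic import simulate_study
        _, table, _ = simulate_study(seed=5, drift_amplitude=0.2)
        before = qc_cv(table)
        corrected, _ = correct_drift(table)
        after = qc_cv(corrected)
        improved = (after < before).mean()
        assert improved >= 0.95

    def test_shape_and_manifest_conserved(self):
        types = qc_pattern(20)
        rng = np.random.default_rng(3)
        t = make_table(rng.uniform(1e4, 1e6, size=(4, len(types))), types)
        corrected, _ = correct_drift(t)
        assert corrected.areas.shape == t.areas.shape
        pd.testing.assert_frame_equal(corrected.manifest, t.manifest)

    def test_too_few_qcs_refused_naming_count(self):
        types = ["qc", "study", "study", "qc", "study"]
        t = make_table(np.full((1, 5), 100.0), types)
        with pytest.raises(ValueError, match="found 2"):
            correct_drift(t, min_qc=5)


class TestCvFilter:
    def make_qc_only(self, rows):
        rows = np.asarray(rows, float)
        return make_table(rows, ["qc"] * rows.shape[1])

    def test_constant_qc_kept(self):
        t = self.make_qc_only([[100, 100, 100]])
        kept, report = cv_filter(t)
        assert kept.n_features == 1
        assert report["cv_qc"].iloc[0] == 0

    def test_cv_25_percent_removed(self):
        t = self.make_qc_only([[75, 100, 125]])
        kept, report = cv_filter(t)
        assert report["cv_qc"].iloc[0] == pytest.approx(0.25)
        assert kept.n_features == 0
        assert report["removal_reason"].iloc[0] == "cv"

    def test_boundary_cv_exactly_threshold_is_kept(self):
        # sd([80,100,120]) = 20, mean = 100 -> CV = 0.20 exactly
        t = self.make_qc_only([[80, 100, 120]])
        kept, report = cv_filter(t)
        assert report["cv_qc"].iloc[0] == pytest.approx(0.20)
        assert kept.n_features == 1

    def test_zero_mean_qc_removed(self):
        t = self.make_qc_only([[0, 0, 0]])
        kept, report = cv_filter(t)
        assert kept.n_features == 0

    def test_threshold_monotonicity_and_idempotence(self):
        rng = np.random.default_rng(8)
        t = self.make_qc_only(rng.lognormal(10, 0.3, size=(30, 6)))
        kept_sizes = [cv_filter(t, threshold=th)[0].n_features
                      for th in (0.05, 0.10, 0.20, 0.50)]
        assert kept_sizes == sorted(kept_sizes)
        once, _ = cv_filter(t, threshold=0.2)
        twice, _ = cv_filter(once, threshold=0.2)
        assert list(twice.areas.index) == list(once.areas.index)


class TestLinearityFilter:
    def make_dqc(self, rows):
        rows = np.asarray(rows, float)
        lv = [100, 50, 25, 12.5, 6.25] * (rows.shape[1] // 5)
        return make_table(rows, ["dqc"] * rows.shape[1], dilution=lv)

    def test_proportional_response_kept(self):
        lv = np.array([100, 50, 25, 12.5, 6.25] * 2)
        t = self.make_dqc((lv * 1e3)[None, :])
        kept, report = linearity_filter(t)
        assert report["dilution_r"].iloc[0] == pytest.approx(1.0)
        assert kept.n_features == 1

    def test_constant_response_removed(self):
        t = self.make_dqc(np.full((1, 10), 4e5))
        kept, report = linearity_filter(t)
        assert np.isnan(report["dilution_r"].iloc[0])
        assert kept.n_features == 0

    def test_noise_independent_of_dilution_removed(self):
        rng = np.random.default_rng(19)
        t = self.make_dqc(rng.lognormal(12, 0.5, size=(5, 10)))
        kept, report = linearity_filter(t)
        # oracle: same Pearson correlation computed directly
        x = t.manifest["dilution_percent"].to_numpy(float)
        for fid in t.areas.index:
            r = np.corrcoef(t.areas.loc[fid], x)[0, 1]
            assert report.loc[fid, "dilution_r"] == pytest.approx(r)
        assert kept.n_features == 0

    def test_missing_dqc_skips_with_warning(self):
        t = make_table(np.full((2, 4), 100.0), ["study"] * 4)
        with pytest.warns(UserWarning, match="linearity filter skipped"):
            kept, report = linearity_filter(t)
        assert kept.n_features == 2

    def test_missing_dqc_can_hard_fail(self):
        t = make_table(np.full((1, 3), 100.0), ["study"] * 3)
        with pytest.raises(ValueError, match="no dqc"):
            linearity_filter(t, on_missing_dqc="raise")


class TestRedundancyRemoval:
    def test_higher_abundance_polarity_wins(self):
        t = make_table([[1e6] * 4, [4e5] * 4], ["qc"] * 4,
                       names=["PC(34:1)", "PC(34:1)"],
                       polarity=["positive", "negative"])
        kept, report = remove_redundancies(t)
        assert list(kept.areas.index) == ["F0"]
        assert report.loc["F1", "removal_reason"] == "redundancy"

    def test_no_duplicates_table_unchanged(self):
        t = make_table([[1e6] * 3, [4e5] * 3], ["qc"] * 3,
                       names=["PC(34:1)", "PC(34:2)"])
        kept, _ = remove_redundancies(t)
        assert kept.n_features == 2

    def test_three_duplicates_one_survivor(self):
        t = make_table([[1.0] * 3, [2.0] * 3, [3.0] * 3], ["qc"] * 3,
                       names=["TG(52:2)"] * 3)
        kept, _ = remove_redundancies(t)
        assert kept.n_features == 1
        assert list(kept.areas.index) == ["F2"]


class TestPipelineReport:
    def test_every_feature_has_exactly_one_reason(self):
        from lwas.synthetic import simulate_study
        _, table, truth = simulate_study(
            seed=21, frac_bad_cv=0.1, frac_bad_linearity=0.1,
            redundant_fraction=0.05)
        clean, report = run_qc_pipeline(table)
        assert len(report) == table.n_features
        assert (report["kept"] == (report["removal_reason"] == "none")).all()
        assert clean.n_features + (~report["kept"]).sum() == table.n_features

    def test_planted_bad_features_are_caught(self):
        from lwas.synthetic import simulate_study
        _, table, truth = simulate_study(
            seed=22, frac_bad_cv=0.15, frac_bad_linearity=0.15)
        clean, report = run_qc_pipeline(table)
        sp = truth.species
        name_of = table.features["lipid_name"]
        reason = report["removal_reason"]
        reason.index = [name_of[i] for i in reason.index]
        bad = sp.index[sp["bad_cv"] | sp["bad_linearity"]]
        good = sp.index[~(sp["bad_cv"] | sp["bad_linearity"])]
        sensitivity = (reason.loc[bad] != "none").mean()
        specificity = (reason.loc[good] == "none").mean()
        assert sensitivity >= 0.95
        assert specificity >= 0.95
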