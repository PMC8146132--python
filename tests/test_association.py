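"""Per-lipid linear models, EMM contrasts, Eq.-style percentage effects, BH."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lwas.association import (ModelSpec, associate, bh_adjust, build_design,
                              emm_contrasts, fit_model, percent_difference,
                              percent_to_log2)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="module")
def toy():
    """12-sample toy design with factors and two covariates."""
    rng = np.random.default_rng(12)
    meta = pd.DataFrame({
        "age_group": ["young"] * 6 + ["aged"] * 6,
        "sex": ["female", "male"] * 6,
        "body_fat": rng.normal(25, 5, 12),
        "hba1c": rng.normal(5.2, 0.3, 12),
        "pa_total": rng.normal(250, 50, 12),
        "sampling_time": rng.choice([8, 10, 12, 14, 16], 12),
        "fasting_time": rng.normal(6, 2, 12),
        "statins": rng.integers(0, 2, 12),
    }, index=[f"s{i}" for i in range(12)])
    y = rng.normal(0, 1, 12)
    return meta, y


class TestOls:
    def test_coefficients_match_normal_equations(self, toy):
        meta, y = toy
        X = build_design(meta)
        fit = fit_model(y, X)
        Xv = X.to_numpy(float)
        beta_oracle = np.linalg.solve(Xv.T @ Xv, Xv.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta_oracle,
                                   atol=1e-10)
        # covariance oracle: sigma^2 (X'X)^-1
        resid = y - Xv @ beta_oracle
        sigma2 = resid @ resid / (len(y) - Xv.shape[1])
        cov_oracle = sigma2 * np.linalg.inv(Xv.T @ Xv)
        np.testing.assert_allclose(np.asarray(fit.cov_params()), cov_oracle,
                                   atol=1e-10)

    def test_balanced_groups_without_covariates(self):
        meta = pd.DataFrame({
            "age_group": ["young"] * 4 + ["aged"] * 4,
            "sex": ["female"] * 8,
        }, index=[f"s{i}" for i in range(8)])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        X = pd.DataFrame({"const": 1.0,
                          "aged": (meta["age_group"] == "aged").astype(float)},
                         index=meta.index)
        fit = fit_model(y, X)
        assert fit.params["aged"] == pytest.approx(
            y[4:].mean() - y[:4].mean())

    def test_exact_linear_response_has_zero_residual(self, toy):
        meta, _ = toy
        X = build_design(meta)
        y = X.to_numpy() @ np.arange(1.0, X.shape[1] + 1)
        fit = fit_model(y, X)
        assert fit.rsquared == pytest.approx(1.0)

    def test_rank_deficiency_names_columns(self, toy):
        meta, y = toy
        X = build_design(meta)
        X["dup"] = X["aged"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_model(y, X)


class TestEmm:
    def test_balanced_design_emm_equals_cell_means(self):
        meta = pd.DataFrame({
            "age_group": ["young", "young", "aged", "aged"] * 2,
            "sex": ["female", "male"] * 4,
        }, index=[f"s{i}" for i in range(8)])
        y = np.arange(8.0)
        X = build_design(meta, ModelSpec(continuous=(), binary=()))
        fit = fit_model(y, X)
        ct = emm_contrasts(fit, X)
        for label, (age, sex), (age0, sex0) in (
                (("aged-young | female"), ("aged", "female"),
                 ("young", "female")),):
            cell = y[(meta.age_group == age) & (meta.sex == sex)].mean()
            cell0 = y[(meta.age_group == age0) & (meta.sex == sex0)].mean()
            assert ct.loc[label, "emm_difference_log2"] == pytest.approx(
                cell - cell0)

    def test_contrasts_match_emmeans_oracle(self):
        """Frozen reference computed with the R emmeans package."""
        d = pd.read_csv(DATA / "emm_toy.csv", index_col=0)
        X = build_design(d)
        fit = fit_model(d["y"], X)
        ct = emm_contrasts(fit, X)
        oracle = pd.read_csv(DATA / "emmeans_out.csv").astype(
            {"estimate": float, "SE": float, "t.ratio": float,
             "p.value": float})
        np.testing.assert_allclose(
            ct[["emm_difference_log2", "se_log2", "t", "p"]].to_numpy(),
            oracle[["estimate", "SE", "t.ratio", "p.value"]].to_numpy(),
            atol=1e-10)

    def test_contrast_equals_prediction_difference(self, toy):
        meta, y = toy
        X = build_design(meta)
        fit = fit_model(y, X)
        ct = emm_contrasts(fit, X)
        # oracle: build the two reference-grid rows by hand and predict
        base = X.mean(axis=0)
        for cell, cell0, label in (
                ((1, 0), (0, 0), "aged-young | female"),
                ((1, 1), (0, 1), "aged-young | male")):
            rows = []
            for aged, male in (cell, cell0):
                r = base.copy()
                r["const"], r["aged"], r["male"] = 1.0, aged, male
                r["aged:male"] = aged * male
                rows.append(r.to_numpy() @ fit.params.to_numpy())
            assert ct.loc[label, "emm_difference_log2"] == pytest.approx(
                rows[0] - rows[1], abs=1e-10)

    def test_zero_interaction_gives_identical_age_contrasts(self, toy):
        meta, _ = toy
        X = build_design(meta)
        beta = np.zeros(X.shape[1])
        beta[list(X.columns).index("aged")] = 0.5  # no interaction term
        y = X.to_numpy() @ beta
        fit = fit_model(y, X)
        ct = emm_contrasts(fit, X)
        assert ct.loc["aged-young | female", "emm_difference_log2"] == \
            pytest.approx(ct.loc["aged-young | male", "emm_difference_log2"])


class TestPercentDifference:
    @pytest.mark.parametrize("beta,expected", [
        (0.0, 0.0), (1.0, 100.0), (-1.0, -50.0),
    ])
    def test_reference_points(self, beta, expected):
        assert percent_difference(beta) == pytest.approx(expected)

    def test_reported_maximum_effect_maps_back(self):
        # a 61.7% difference corresponds to a log2 contrast of log2(1.617)
        assert percent_difference(np.log2(1.617)) == pytest.approx(61.7)

    @given(st.floats(-3, 3))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_bijectivity(self, beta):
        assert percent_to_log2(percent_difference(beta)) == pytest.approx(
            beta, abs=1e-12)


class TestBh:
    def brute_force(self, p):
        # step-up from the largest p: adj(i) = min_{j>=i} p(j)*m/j, capped
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        sorted_p = p[order]
        adj_sorted = [min(min(sorted_p[j] * m / (j + 1)
                              for j in range(i, m)), 1.0) for i in range(m)]
        adj = np.empty(m)
        adj[order] = adj_sorted
        return adj

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_textbook_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(100)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 12))
            np.testing.assert_allclose(bh_adjust(p), self.brute_force(p),
                                       atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(101)
        p = rng.random(500)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(102)
        p = rng.random(200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestAssociate:
    def test_families_and_skipped_rows(self, small_cohort):
        from lwas.aggregation import aggregate, log2_and_standardise
        from conftest import make_table
        rng = np.random.default_rng(55)
        names = ["PC(34:1)", "PC(36:4)", "PE(36:2)", "LPC(18:1)"]
        areas = rng.lognormal(14, 0.5, size=(4, len(small_cohort)))
        t = make_table(areas, ["study"] * len(small_cohort), names=names)
        t.manifest["sample_id"] = list(small_cohort.index)
        matrix = log2_and_standardise(aggregate(t))
        res = associate(matrix, small_cohort)
        n_rows = len(matrix.modellable_rows())
        # one BH family per term and per contrast, across all rows
        for _, grp in res.coefficients.groupby("term"):
            assert len(grp) == n_rows
            np.testing.assert_allclose(
                grp["p_bh"], bh_adjust(grp["p"].to_numpy()))
        for _, grp in res.contrasts.groupby("contrast"):
            assert len(grp) == n_rows
        np.testing.assert_allclose(
            res.contrasts["percent_difference"],
            (2.0 ** res.contrasts["emm_difference_log2"] - 1) * 100,
            rtol=1e-12)
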