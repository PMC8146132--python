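"""Covariate-adjusted linear models, estimated-marginal-mean contrasts and
percentage-of-difference effect sizes.

Each lipid row (z-standardised log2 abundance) is regressed on age group,
sex, their interaction and six clinical covariates (body fat %, statins
intake, HbA1c %, daily total physical activity, blood sampling time,
fasting time).  Post-hoc group comparisons are estimated-marginal-mean
(EMM) contrasts: model predictions at a reference grid that fixes
continuous covariates at their grand means and binary covariates at their
observed proportions.  Contrasts are back-scaled from the z scale to log2
units with the response's stored SD and converted to a percentage of
difference, (2**beta - 1) * 100.  p-values are adjusted per family with the
Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .aggregation import LipidMatrix

__all__ = [
    "ModelSpec",
    "build_design",
    "fit_model",
    "emm_contrasts",
    "percent_difference",
    "percent_to_log2",
    "bh_adjust",
    "associate",
]

CONTINUOUS_COVARIATES = ("body_fat", "hba1c", "pa_total",
                         "sampling_time", "fasting_time")
BINARY_COVARIATES = ("statins",)

#: (label, within-factor, within-level, plus-cell, minus-cell)
CONTRASTS = (
    ("aged-young | female", ("aged", "female"), ("young", "female")),
    ("aged-young | male", ("aged", "male"), ("young", "male")),
    ("male-female | young", ("young", "male"), ("young", "female")),
    ("male-female | aged", ("aged", "male"), ("aged", "female")),
)


@dataclass(frozen=True)
class ModelSpec:
    """Design of the per-lipid regression.

    Reference levels are young / female.  ``sampling_time_categorical``
    switches the blood-sampling time slot from a continuous hour-of-day
    covariate (default) to dummy-coded categories.
    """

    continuous: tuple[str, ...] = CONTINUOUS_COVARIATES
    binary: tuple[str, ...] = BINARY_COVARIATES
    sampling_time_categorical: bool = False


def build_design(metadata: pd.DataFrame, spec: ModelSpec = ModelSpec()
                 ) -> pd.DataFrame:
    """Design matrix: intercept, age/sex factors, interaction, covariates.

    Continuous covariates are z-standardised (sample SD); binary covariates
    stay 0/1.
    """
    X = pd.DataFrame(index=metadata.index)
    X["const"] = 1.0
    X["aged"] = (metadata["age_group"] == "aged").astype(float)
    X["male"] = (metadata["sex"] == "male").astype(float)
    X["aged:male"] = X["aged"] * X["male"]
    continuous = list(spec.continuous)
    if spec.sampling_time_categorical and "sampling_time" in continuous:
        continuous.remove("sampling_time")
        dummies = pd.get_dummies(metadata["sampling_time"], prefix="slot",
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    for cov in continuous:
        x = metadata[cov].astype(float)
        sd = x.std(ddof=1)
        X[cov] = (x - x.mean()) / sd if sd > 0 else 0.0
    for cov in spec.binary:
        X[cov] = metadata[cov].astype(float)
    return X


def fit_model(y: pd.Series | np.ndarray, X: pd.DataFrame):
    """OLS fit via statsmodels (QR-based pseudoinverse, stable).

    Raises on rank deficiency, naming the collinear columns.
    """
    Xv = X.to_numpy(float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        _, R = np.linalg.qr(Xv)
        diag = np.abs(np.diag(R))
        bad = [X.columns[i] for i in range(len(diag))
               if diag[i] < 1e-8 * diag.max()]
        raise ValueError(f"design matrix is rank deficient "
                         f"(rank {rank} < {Xv.shape[1]}); "
                         f"suspect columns: {bad}")
    return sm.OLS(np.asarray(y, float), X).fit()


def _reference_grid(X: pd.DataFrame) -> dict[tuple[str, str], pd.Series]:
    """EMM reference rows for the four age x sex cells.

    All non-factor columns are fixed at their column means (continuous
    covariates are centred so this is ~0; binary covariates sit at their
    observed proportion); the factor columns take the cell's values.
    """
    base = X.mean(axis=0)
    grid = {}
    for age in ("young", "aged"):
        for sex in ("female", "male"):
            row = base.copy()
            row["const"] = 1.0
            row["aged"] = float(age == "aged")
            row["male"] = float(sex == "male")
            row["aged:male"] = row["aged"] * row["male"]
            grid[(age, sex)] = row
    return grid


def emm_contrasts(fit, X: pd.DataFrame, response_sd: float = 1.0
                  ) -> pd.DataFrame:
    """Estimated marginal means and within-factor contrasts.

    Returns one row per contrast (aged-young within each sex, male-female
    within each age group) with the difference on the log2 scale (z-scale
    difference times ``response_sd``), its SE, t, p and the percentage of
    difference.
    """
    grid = _reference_grid(X)
    beta = np.asarray(fit.params, float)
    cov = np.asarray(fit.cov_params(), float)
    df = fit.df_resid
    rows = []
    for label, plus, minus in CONTRASTS:
        c = (grid[plus] - grid[minus]).to_numpy(float)
        diff_z = float(c @ beta)
        se_z = float(np.sqrt(c @ cov @ c))
        t = diff_z / se_z if se_z > 0 else np.nan
        p = 2 * st.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        diff_log2 = diff_z * response_sd
        rows.append({
            "contrast": label,
            "emm_difference_log2": diff_log2,
            "se_log2": se_z * response_sd,
            "t": t, "df": df, "p": p,
            "percent_difference": percent_difference(diff_log2),
        })
    return pd.DataFrame(rows).set_index("contrast")


def percent_difference(beta_log2: float) -> float:
    """Percentage of difference implied by a log2-scale contrast:
    ``(2**beta - 1) * 100``."""
    return (np.exp2(beta_log2) - 1.0) * 100.0


def percent_to_log2(percent: float) -> float:
    """Inverse of :func:`percent_difference`."""
    return float(np.log2(1.0 + percent / 100.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Sorted p-values are scaled by m/rank, a cumulative minimum from the
    largest down enforces monotonicity, and results are capped at 1.
    """
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class AssociationResult:
    """Per-lipid coefficients and EMM contrasts with BH-adjusted p-values."""

    coefficients: pd.DataFrame  # row_id x term: beta, se, t, p, p_bh
    contrasts: pd.DataFrame     # row_id x contrast: log2 diff, se, p, p_bh, %
    skipped_rows: tuple[str, ...] = field(default_factory=tuple)


def associate(matrix: LipidMatrix, metadata: pd.DataFrame,
              spec: ModelSpec = ModelSpec(), rows=None) -> AssociationResult:
    """Fit the per-lipid model for every modellable row of the matrix.

    BH families follow the joint-adjustment rule: one family per model term
    across all lipid rows, and one family per contrast type across all
    lipid rows.  Constant rows are skipped and reported.
    """
    if matrix.scale != "log2_z":
        raise ValueError("associate expects a standardised (log2_z) matrix")
    samples = metadata.index
    X = build_design(metadata, spec)
    if rows is None:
        rows = matrix.modellable_rows()
    coef_rows, contrast_rows = [], []
    for rid in rows:
        y = matrix.values.loc[rid, samples]
        fit = fit_model(y, X)
        for term, b, se, t, p in zip(X.columns, fit.params, fit.bse,
                                     fit.tvalues, fit.pvalues):
            coef_rows.append({"row_id": rid, "term": term, "beta": b,
                              "se": se, "t": t, "p": p})
        cts = emm_contrasts(fit, X, response_sd=float(matrix.row_scale[rid]))
        cts = cts.reset_index()
        cts.insert(0, "row_id", rid)
        contrast_rows.append(cts)

    coefs = pd.DataFrame(coef_rows)
    coefs["p_bh"] = np.nan
    for term, idx in coefs.groupby("term").groups.items():
        coefs.loc[idx, "p_bh"] = bh_adjust(coefs.loc[idx, "p"].to_numpy())
    contrasts = pd.concat(contrast_rows, ignore_index=True)
    contrasts["p_bh"] = np.nan
    for label, idx in contrasts.groupby("contrast").groups.items():
        contrasts.loc[idx, "p_bh"] = bh_adjust(
            contrasts.loc[idx, "p"].to_numpy())
    return AssociationResult(
        coefficients=coefs, contrasts=contrasts,
        skipped_rows=tuple(r for r in matrix.constant_rows),
    )
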