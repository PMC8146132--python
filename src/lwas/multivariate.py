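"""Global structure: PCA and an empirical-Bayes moderated differential
analysis adjusted for blood sampling time.

The moderated analysis regresses each species' log2 abundance on group and
sampling time, then shrinks the per-species residual variances s^2 toward an
ensemble prior s0^2 estimated by method of moments on log s^2 (the scaled-F
model behind the standard moderated t): s~^2 = (d0*s0^2 + d*s^2) / (d0 + d),
with the moderated t referred to a t distribution on d0 + d degrees of
freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special as sp
import scipy.stats as st
from sklearn.decomposition import PCA

from .aggregation import LipidMatrix
from .association import bh_adjust

__all__ = ["run_pca", "moderated_differential", "DifferentialResult",
           "fit_variance_prior"]


@dataclass
class PcaResult:
    scores: pd.DataFrame      # samples x components
    loadings: pd.DataFrame    # variables x components
    explained_variance_ratio: np.ndarray


def run_pca(m: LipidMatrix, n_components: int = 2, rows=None,
            scale: bool = True) -> PcaResult:
    """PCA over study samples (observations) and lipid rows (variables).

    Variables are centred, and unit-variance scaled by default.  If
    ``n_components`` exceeds the matrix rank it is truncated with a
    warning.  Explained-variance fractions are non-increasing and sum to at
    most 1.
    """
    if rows is None:
        rows = m.rows_of_kind("species")
    X = m.values.loc[rows].to_numpy(float).T  # samples x variables
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        warnings.warn(f"n_components={n_components} exceeds rank "
                      f"{max_rank}; truncated")
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.values.columns,
                            columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=rows,
                              columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = sp.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / sp.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F variance prior (d0, s0^2).

    Matches the mean and variance of log s^2 to the digamma/trigamma
    moments of the scaled-F model.  A log-variance spread no larger than
    the sampling spread gives d0 = inf (complete shrinkage).
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - sp.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(sp.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(emean + sp.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # per species: coef, s2, s2_tilde, t_mod, p, p_bh
    d0: float
    s02: float
    df_residual: float


def moderated_differential(m: LipidMatrix, group: pd.Series,
                           sampling_time: pd.Series, rows=None,
                           reference: str | None = None
                           ) -> DifferentialResult:
    """Group difference per species with empirical-Bayes variance moderation.

    Per species, an OLS of log2 abundance (z-scale values are rescaled back
    to log2 units) on an intercept, a 0/1 group indicator and centred
    sampling time; the group coefficient is the adjusted log2 fold
    difference.  Requires at least 3 samples per group.
    """
    if rows is None:
        rows = [r for r in m.rows_of_kind("species")
                if r not in m.constant_rows]
    samples = m.values.columns
    g = pd.Series(group).loc[samples]
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"expected two groups, got {levels}")
    if (g.value_counts() < 3).any():
        raise ValueError("need at least 3 samples per group")
    if reference is None:
        reference = levels[0]
    elif reference not in levels:
        raise ValueError(f"reference {reference!r} not among groups {levels}")
    gv = (g != reference).to_numpy(float)  # coefficient: non-reference - ref
    tv = pd.Series(sampling_time).loc[samples].to_numpy(float)
    X = np.column_stack([np.ones_like(gv), gv, tv - tv.mean()])
    n, p = X.shape
    df = n - p

    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    Y = m.values.loc[rows].to_numpy(float)
    if m.scale == "log2_z":
        Y = (Y * m.row_scale.loc[rows].to_numpy()[:, None]
             + m.row_center.loc[rows].to_numpy()[:, None])
    B = Y @ H.T                       # species x coefficients
    resid = Y - B @ X.T
    s2 = (resid ** 2).sum(axis=1) / df
    d0, s02 = fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    unscaled = np.sqrt(XtX_inv[1, 1])
    se_mod = np.sqrt(s2_tilde) * unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = B[:, 1] / se_mod
    pvals = 2 * st.t.sf(np.abs(t_mod), df_total)
    table = pd.DataFrame({
        "coef_log2": B[:, 1],
        "s2": s2, "s2_tilde": s2_tilde,
        "t_mod": t_mod, "p": pvals,
        "p_bh": bh_adjust(pvals),
    }, index=pd.Index(rows, name="species"))
    table["neg_log10_p_bh"] = -np.log10(table["p_bh"].clip(lower=1e-300))
    return DifferentialResult(table=table, d0=d0, s02=s02, df_residual=df)
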