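"""Injection-order drift correction and feature-level quality filters.

Implements the standard pooled-QC workflow for untargeted LC-MS runs:

* QC-LOESS drift correction — per feature, a local linear regression of
  pooled-QC signal on injection order, interpolated to every injection with
  a natural cubic spline and divided out as a multiplicative factor;
* a reproducibility filter removing features whose QC coefficient of
  variation exceeds a threshold (default 20%, strict);
* a linearity filter removing features whose signal does not track a
  pooled-QC dilution series (Pearson r with dilution level < 0.8);
* redundancy removal collapsing features annotated as the same lipid
  species (e.g. detected in both ionisation polarities) to one feature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from statsmodels.nonparametric.smoothers_lowess import lowess

from .nomenclature import ParsedLipid, parse_lipid_name

__all__ = [
    "FeatureTable",
    "correct_drift",
    "qc_cv",
    "cv_filter",
    "linearity_filter",
    "remove_redundancies",
    "run_qc_pipeline",
]

log = logging.getLogger(__name__)

DILUTION_LEVELS = (100.0, 50.0, 25.0, 12.5, 6.25)


@dataclass
class FeatureTable:
    """Peak areas (features x injections) with an injection manifest.

    ``areas`` is indexed by feature id, columns are injection ids ordered by
    injection order. ``features`` (same index) carries ``lipid_name`` and
    ``polarity``. ``manifest`` is indexed by injection id with columns
    ``order`` (unique, strictly increasing), ``type`` in {study, qc, dqc},
    ``dilution_percent`` (dqc only) and ``sample_id`` (study only).
    """

    features: pd.DataFrame
    areas: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.areas.index.equals(self.features.index):
            raise ValueError("areas and features must share the same index")
        if not self.areas.columns.equals(self.manifest.index):
            raise ValueError("areas columns must match manifest index")
        order = self.manifest["order"].to_numpy()
        if len(np.unique(order)) != len(order) or np.any(np.diff(order) <= 0):
            raise ValueError("injection orders must be unique and increasing")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("peak areas must be non-negative")
        bad = self.manifest["type"].isin(["study", "qc", "dqc"])
        if not bad.all():
            raise ValueError(
                f"unknown injection types: {set(self.manifest['type'][~bad])}")
        dqc = self.manifest["type"] == "dqc"
        if dqc.any() and self.manifest.loc[dqc, "dilution_percent"].isna().any():
            raise ValueError("every dqc injection needs a dilution_percent")

    # -- convenience views -------------------------------------------------
    def injections_of(self, kind: str) -> pd.Index:
        return self.manifest.index[self.manifest["type"] == kind]

    def subset_features(self, ids) -> "FeatureTable":
        return replace(self, features=self.features.loc[ids],
                       areas=self.areas.loc[ids])

    def study_only(self) -> "FeatureTable":
        keep = self.injections_of("study")
        return replace(self, areas=self.areas[keep],
                       manifest=self.manifest.loc[keep])

    @property
    def n_features(self) -> int:
        return len(self.areas)


def qc_cv(t: FeatureTable) -> pd.Series:
    """Per-feature coefficient of variation over pooled-QC injections.

    Sample standard deviation (n-1 denominator) divided by the mean;
    NaN where the mean is not positive.
    """
    qc = t.areas[t.injections_of("qc")]
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    cv = sd / mean
    cv[mean <= 0] = np.nan
    return cv.rename("cv")


def correct_drift(t: FeatureTable, span: float = 0.75, min_qc: int = 5,
                  robust_iterations: int = 0,
                  ) -> tuple[FeatureTable, pd.DataFrame]:
    """Remove multiplicative injection-order drift using pooled QCs.

    Per feature, a local linear (LOESS, degree 1) curve is fitted to QC
    areas versus injection order, interpolated to all injection orders with
    a natural cubic spline, and each area is divided by the fitted value
    normalised to the median fitted value at the QC orders.  Features whose
    fitted curve is not strictly positive fall back to a straight-line
    trend; features that still fail are passed through unchanged and
    flagged.  Returns the corrected table (identical shape and manifest)
    and a per-feature flag frame with columns ``corrected`` and ``method``.
    """
    qc_cols = t.injections_of("qc")
    if len(qc_cols) < min_qc:
        raise ValueError(
            f"drift correction needs at least {min_qc} pooled QC "
            f"injections, found {len(qc_cols)}")

    all_orders = t.manifest["order"].to_numpy(float)
    qc_orders = t.manifest.loc[qc_cols, "order"].to_numpy(float)
    corrected = t.areas.to_numpy(float).copy()
    flags = pd.DataFrame(index=t.areas.index,
                         columns=["corrected", "method"])
    flags["corrected"] = True
    flags["method"] = "loess"

    for i, fid in enumerate(t.areas.index):
        y = t.areas.loc[fid, qc_cols].to_numpy(float)
        if np.any(y <= 0):
            flags.loc[fid] = [False, "skipped-nonpositive-qc"]
            continue
        fitted_qc = lowess(y, qc_orders, frac=span, it=robust_iterations,
                           return_sorted=False)
        method = "loess"
        if np.any(fitted_qc <= 0) or not np.all(np.isfinite(fitted_qc)):
            slope, intercept = np.polyfit(qc_orders, y, 1)
            fitted_qc = intercept + slope * qc_orders
            method = "linear-fallback"
        if np.any(fitted_qc <= 0):
            flags.loc[fid] = [False, "skipped-nonpositive-fit"]
            continue
        curve = CubicSpline(qc_orders, fitted_qc, bc_type="natural")
        fit_all = curve(all_orders)
        factors = fit_all / np.median(fitted_qc)
        if np.any(factors <= 0) or not np.all(np.isfinite(factors)):
            slope, intercept = np.polyfit(qc_orders, y, 1)
            fit_all = intercept + slope * all_orders
            factors = fit_all / np.median(intercept + slope * qc_orders)
            method = "linear-fallback"
            if np.any(factors <= 0):
                flags.loc[fid] = [False, "skipped-nonpositive-fit"]
                continue
        corrected[i] = corrected[i] / factors
        flags.loc[fid, "method"] = method

    out_areas = pd.DataFrame(corrected, index=t.areas.index,
                             columns=t.areas.columns)
    return replace(t, areas=out_areas), flags


def cv_filter(t: FeatureTable, threshold: float = 0.20,
              ) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop features with pooled-QC CV strictly above ``threshold``.

    A CV of exactly the threshold keeps the feature; an undefined CV
    (non-positive QC mean) removes it.
    """
    cv = qc_cv(t)
    removed = cv.isna() | (cv > threshold)
    report = pd.DataFrame({
        "cv_qc": cv,
        "kept": ~removed,
        "removal_reason": np.where(removed, "cv", "none"),
    })
    return t.subset_features(t.areas.index[~removed]), report


def dilution_correlation(t: FeatureTable) -> pd.Series:
    """Pearson correlation of each feature's area with the dQC dilution level.

    Both dilution series (start and end of run) are pooled. NaN where the
    correlation is undefined (zero variance) or no dQCs exist.
    """
    dqc_cols = t.injections_of("dqc")
    r = pd.Series(np.nan, index=t.areas.index, name="dilution_r")
    if len(dqc_cols) == 0:
        return r
    x = t.manifest.loc[dqc_cols, "dilution_percent"].to_numpy(float)
    y = t.areas[dqc_cols].to_numpy(float)
    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r[:] = (yc @ xc) / denom
    return r


def linearity_filter(t: FeatureTable, r_min: float = 0.8,
                     on_missing_dqc: str = "warn",
                     ) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop features whose signal response is not linear with dilution.

    Features with Pearson r < ``r_min`` against the dilution percentage
    (both dQC series pooled), or with undefined r, are removed. If the
    manifest has no dQC injections, the filter is skipped with a warning
    (``on_missing_dqc='warn'``) or raises (``'raise'``).
    """
    if len(t.injections_of("dqc")) == 0:
        if on_missing_dqc == "raise":
            raise ValueError("manifest has no dqc injections")
        warnings.warn("no dqc injections: linearity filter skipped")
        report = pd.DataFrame({
            "dilution_r": np.nan, "kept": True, "removal_reason": "none",
        }, index=t.areas.index)
        return t, report
    r = dilution_correlation(t)
    removed = r.isna() | (r < r_min)
    report = pd.DataFrame({
        "dilution_r": r,
        "kept": ~removed,
        "removal_reason": np.where(removed, "linearity", "none"),
    })
    return t.subset_features(t.areas.index[~removed]), report


def remove_redundancies(t: FeatureTable,
                        parsed: dict[str, ParsedLipid] | None = None,
                        ) -> tuple[FeatureTable, pd.DataFrame]:
    """Keep exactly one feature per unique lipid species.

    Among features that parse to the same structure (typically the same
    species detected in both polarities), the feature with the highest mean
    pooled-QC abundance wins; ties break to positive polarity, then feature
    id.
    """
    if parsed is None:
        parsed = {fid: parse_lipid_name(nm)
                  for fid, nm in t.features["lipid_name"].items()}
    qc_cols = t.injections_of("qc")
    ref_cols = qc_cols if len(qc_cols) else t.areas.columns
    mean_abund = t.areas[ref_cols].mean(axis=1)

    keep: list[str] = []
    groups: dict[tuple, list[str]] = {}
    for fid in t.areas.index:
        groups.setdefault(parsed[fid].key(), []).append(fid)
    for members in groups.values():
        winner = min(
            members,
            key=lambda f: (-mean_abund[f],
                           0 if t.features.loc[f, "polarity"] == "positive"
                           else 1,
                           str(f)),
        )
        keep.append(winner)
    keep_idx = t.areas.index[t.areas.index.isin(keep)]
    removed = ~t.areas.index.isin(keep)
    report = pd.DataFrame({
        "kept": ~removed,
        "removal_reason": np.where(removed, "redundancy", "none"),
    }, index=t.areas.index)
    return t.subset_features(keep_idx), report


def run_qc_pipeline(t: FeatureTable, span: float = 0.75,
                    cv_threshold: float = 0.20, r_min: float = 0.8,
                    min_qc: int = 5, on_missing_dqc: str = "warn",
                    ) -> tuple[FeatureTable, pd.DataFrame]:
    """Full QC chain: drift correction, CV, linearity, redundancy filters.

    Returns the cleaned table (study + QC injections retained, unique
    species) and a per-input-feature report with before/after QC CVs, the
    dilution correlation, the kept flag and a single removal reason.
    """
    cv_before = qc_cv(t)
    corrected, drift_flags = correct_drift(t, span=span, min_qc=min_qc)
    cv_after = qc_cv(corrected)

    t1, rep_cv = cv_filter(corrected, threshold=cv_threshold)
    t2, rep_lin = linearity_filter(t1, r_min=r_min,
                                   on_missing_dqc=on_missing_dqc)
    t3, rep_red = remove_redundancies(t2)

    report = pd.DataFrame(index=t.areas.index)
    report["cv_qc_before"] = cv_before
    report["cv_qc_after"] = cv_after
    report["dilution_r"] = dilution_correlation(corrected)
    report["drift_corrected"] = drift_flags["corrected"]
    reason = pd.Series("none", index=t.areas.index)
    reason[rep_cv.index[rep_cv["removal_reason"] == "cv"]] = "cv"
    reason[rep_lin.index[rep_lin["removal_reason"] == "linearity"]] = "linearity"
    reason[rep_red.index[rep_red["removal_reason"] == "redundancy"]] = "redundancy"
    report["removal_reason"] = reason
    report["kept"] = reason == "none"
    return t3, report
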