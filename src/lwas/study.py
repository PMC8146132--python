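"""Replicated simulation studies: parameter recovery, null calibration,
filter performance and drift-correction benefit.

These drive the package's own validation: each study regenerates synthetic
data under the default cohort conditions (published group sizes 32/41/37/40
and covariate distributions), pushes it through the full pipeline and
measures how well known planted quantities are recovered.  Panels are kept
small per replicate (the pipeline is exercised end to end either way) so
hundreds of replicates run in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import aggregation, association, qc
from .synthetic import (CohortConfig, generate_cohort, generate_panel,
                        generate_feature_table, make_truth)

__all__ = ["recovery_study", "null_study", "filter_performance_study",
           "drift_benefit_study"]

#: compact panel used inside replicated studies (one representative species
#: per major subclass; the planted species carries the effect of interest)
STUDY_COMPOSITION = {"PC": 6, "SM": 4, "TG": 4, "PE": 3, "LPC": 2,
                     "Cer": 2, "PI": 2, "CE": 1}
PLANTED_SPECIES = "SM(37:2;3)"


def _replicate(seed: int, delta_age: float, cohort_cfg: CohortConfig,
               drift_amplitude: float):
    """One full-pipeline run; returns (contrast table, matrix)."""
    rng = np.random.default_rng(seed)
    s1, s2, s3 = rng.integers(0, 2 ** 31 - 1, size=3)
    cohort = generate_cohort(cohort_cfg, seed=int(s1))
    panel = generate_panel(STUDY_COMPOSITION)
    truth = make_truth(panel, seed=int(s2),
                       delta_age={PLANTED_SPECIES: delta_age}
                       if delta_age else 0.0)
    table, _ = generate_feature_table(truth, cohort, seed=int(s3),
                                      drift_amplitude=drift_amplitude)
    clean, _ = qc.run_qc_pipeline(table)
    matrix = aggregation.log2_and_standardise(
        aggregation.aggregate(clean.study_only()))
    meta = cohort.loc[clean.study_only().manifest["sample_id"]]
    assoc = association.associate(matrix, meta)
    return assoc, matrix


@dataclass
class RecoveryResult:
    """Replicate-level percent differences for the planted species."""

    percent_female: np.ndarray
    percent_male: np.ndarray

    def summary(self) -> dict:
        out = {}
        for label, vals in (("female", self.percent_female),
                            ("male", self.percent_male)):
            out[label] = {
                "mean": float(vals.mean()),
                "mc_se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
                "n": len(vals),
            }
        return out


def recovery_study(n_replicates: int = 200, *, seed: int = 0,
                   delta_age: float = float(np.log2(1.617)),
                   cohort_cfg: CohortConfig = CohortConfig(),
                   drift_amplitude: float = 0.2) -> RecoveryResult:
    """Plant a log2 age effect on one species; recover it end to end.

    The default planted effect, log2(1.617), corresponds to a 61.7%
    percentage of difference between aged and young participants.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_replicates)
    pf, pm = [], []
    for s in seeds:
        assoc, _ = _replicate(int(s), delta_age, cohort_cfg, drift_amplitude)
        ct = assoc.contrasts
        row = ct[ct["row_id"] == PLANTED_SPECIES].set_index("contrast")
        pf.append(row.loc["aged-young | female", "percent_difference"])
        pm.append(row.loc["aged-young | male", "percent_difference"])
    return RecoveryResult(np.array(pf), np.array(pm))


def null_study(n_replicates: int = 200, *, seed: int = 0,
               cohort_cfg: CohortConfig = CohortConfig(),
               drift_amplitude: float = 0.2) -> dict:
    """All planted effects zero: measure the BH-positive rate.

    Covariate loadings are also disabled so that the age factor is truly
    null for every species.  Returns the replicate-wise fraction of species
    contrasts with BH-adjusted p <= 0.05 and its Monte-Carlo SE.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_replicates)
    rates = []
    for s in seeds:
        rr = np.random.default_rng(int(s))
        s1, s2, s3 = rr.integers(0, 2 ** 31 - 1, size=3)
        cohort = generate_cohort(cohort_cfg, seed=int(s1))
        panel = generate_panel(STUDY_COMPOSITION)
        truth = make_truth(panel, seed=int(s2), covariate_loadings={})
        table, _ = generate_feature_table(truth, cohort, seed=int(s3),
                                          drift_amplitude=drift_amplitude)
        clean, _ = qc.run_qc_pipeline(table)
        matrix = aggregation.log2_and_standardise(
            aggregation.aggregate(clean.study_only()))
        meta = cohort.loc[clean.study_only().manifest["sample_id"]]
        assoc = association.associate(matrix, meta)
        ct = assoc.contrasts
        species = matrix.rows_of_kind("species")
        age_ct = ct[ct["contrast"].str.startswith("aged-young")
                    & ct["row_id"].isin(species)]
        rates.append((age_ct["p_bh"] <= 0.05).mean())
    rates = np.asarray(rates)
    return {"rate": float(rates.mean()),
            "mc_se": float(rates.std(ddof=1) / np.sqrt(len(rates))),
            "n": int(len(rates))}


def filter_performance_study(n_replicates: int = 20, *, seed: int = 0,
                             frac_bad: float = 0.15) -> dict:
    """Sensitivity/specificity of the QC filters on planted bad features."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_replicates)
    sens, spec = [], []
    cohort_cfg = CohortConfig()
    for s in seeds:
        rr = np.random.default_rng(int(s))
        s1, s2, s3 = rr.integers(0, 2 ** 31 - 1, size=3)
        cohort = generate_cohort(cohort_cfg, seed=int(s1))
        panel = generate_panel(STUDY_COMPOSITION)
        truth = make_truth(panel, seed=int(s2), frac_bad_cv=frac_bad,
                           frac_bad_linearity=frac_bad)
        table, truth = generate_feature_table(truth, cohort, seed=int(s3))
        _, report = qc.run_qc_pipeline(table)
        reason = report["removal_reason"].copy()
        reason.index = table.features.loc[reason.index, "lipid_name"]
        sp = truth.species
        bad = sp.index[sp["bad_cv"] | sp["bad_linearity"]]
        good = sp.index[~(sp["bad_cv"] | sp["bad_linearity"])]
        if len(bad):
            sens.append((reason.loc[bad] != "none").mean())
        spec.append((reason.loc[good] == "none").mean())
    return {"sensitivity": float(np.mean(sens)),
            "specificity": float(np.mean(spec)),
            "n": int(n_replicates)}


def drift_benefit_study(n_replicates: int = 10, *, seed: int = 0,
                        drift_amplitude: float = 0.2) -> dict:
    """Fraction of features whose pooled-QC CV improves under correction."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_replicates)
    fracs = []
    cohort_cfg = CohortConfig()
    for s in seeds:
        rr = np.random.default_rng(int(s))
        s1, s2, s3 = rr.integers(0, 2 ** 31 - 1, size=3)
        cohort = generate_cohort(cohort_cfg, seed=int(s1))
        panel = generate_panel(STUDY_COMPOSITION)
        truth = make_truth(panel, seed=int(s2))
        table, _ = generate_feature_table(truth, cohort, seed=int(s3),
                                          drift_amplitude=drift_amplitude)
        before = qc.qc_cv(table)
        corrected, _ = qc.correct_drift(table)
        after = qc.qc_cv(corrected)
        fracs.append(float((after < before).mean()))
    return {"fraction_improved": float(np.mean(fracs)),
            "n": int(n_replicates)}
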