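"""Synthetic cohorts, lipid panels and feature tables with known truth.

The generator emulates the study conditions of a two-age-group,
sex-balanced serum lipidomics run: four age x sex groups with published
means/SDs for the clinical covariates, a 218-species panel with the
published subclass composition, multiplicative injection-order drift,
pooled-QC injections at every tenth position of the run, and a
100/50/25/12.5/6.25% pooled-QC dilution series at batch start and end.
Every stochastic choice flows from a single seed, and the planted
per-species effects are returned as a truth table for parameter-recovery
testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .nomenclature import parse_lipid_name, serialise
from .qc import FeatureTable

__all__ = [
    "GroupConfig", "CohortConfig", "TABLE_COMPOSITION",
    "generate_cohort", "generate_panel", "SyntheticTruth", "make_truth",
    "generate_feature_table", "simulate_study",
]


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupConfig:
    """Means/SDs of one age x sex group's clinical covariates."""

    n: int
    age: tuple[float, float]
    body_fat: tuple[float, float]
    hba1c: tuple[float, float]
    pa_total: tuple[float, float]
    fasting_time: tuple[float, float]
    statins_prevalence: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        for name in ("age", "body_fat", "hba1c", "pa_total", "fasting_time"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be non-negative")
        if not 0 <= self.statins_prevalence <= 1:
            raise ValueError("statins prevalence must be in [0, 1]")


#: plausible physiological bounds used to truncate the normal draws
COVARIATE_BOUNDS = {
    "age": (18.0, 95.0),
    "body_fat": (3.0, 60.0),
    "hba1c": (3.5, 9.0),
    "pa_total": (0.0, np.inf),
    "fasting_time": (1.0, 24.0),
}

#: blood-draw appointment slots (hour of day)
SAMPLING_SLOTS = (8, 10, 12, 14, 16)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator configuration.

    The default reproduces the published participants table: group sizes
    32/41/37/40 (young-F, young-M, aged-F, aged-M) and the per-group
    means/SDs for age, body fat %, HbA1c %, daily total physical activity
    (min/day), fasting time (h) and statins prevalence.
    """

    groups: dict = field(default_factory=lambda: {
        ("young", "female"): GroupConfig(
            32, (25.1, 2.3), (23.1, 6.9), (5.0, 0.2), (282.3, 56.1),
            (6.0, 1.6), 0.00),
        ("young", "male"): GroupConfig(
            41, (25.1, 2.8), (14.7, 5.3), (5.0, 0.2), (274.7, 69.3),
            (5.6, 2.0), 0.00),
        ("aged", "female"): GroupConfig(
            37, (74.0, 2.4), (30.4, 7.5), (5.4, 0.3), (257.2, 87.3),
            (6.6, 3.7), 0.08),
        ("aged", "male"): GroupConfig(
            40, (73.9, 2.5), (24.3, 6.1), (5.3, 0.3), (237.7, 75.2),
            (7.4, 4.5), 0.15),
    })
    sampling_slots: tuple[int, ...] = SAMPLING_SLOTS


def _truncated_normal(mean: float, sd: float, lo: float, hi: float,
                      size: int, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=rng)


def generate_cohort(cfg: CohortConfig = CohortConfig(), *,
                    seed: int = 0) -> pd.DataFrame:
    """Draw one participant record per row.

    Continuous covariates are truncated normals with per-group means/SDs,
    statins is Bernoulli, and sampling slots are assigned uniformly.
    """
    rng = np.random.default_rng(seed)
    frames = []
    counter = itertools.count(1)
    for (age_group, sex), g in cfg.groups.items():
        rec = pd.DataFrame({
            "sample_id": [f"S{next(counter):03d}" for _ in range(g.n)],
            "age_group": age_group,
            "sex": sex,
        })
        for cov in ("age", "body_fat", "hba1c", "pa_total", "fasting_time"):
            lo, hi = COVARIATE_BOUNDS[cov]
            mean, sd = getattr(g, cov)
            rec[cov] = _truncated_normal(mean, sd, lo, hi, g.n, rng)
        rec["statins"] = (rng.random(g.n) < g.statins_prevalence).astype(int)
        rec["sampling_time"] = rng.choice(cfg.sampling_slots, size=g.n)
        frames.append(rec)
    return pd.concat(frames, ignore_index=True).set_index("sample_id")


# --------------------------------------------------------------------------
# panel
# --------------------------------------------------------------------------

#: published per-subclass species counts of the serum panel (218 total)
TABLE_COMPOSITION: dict[str, int] = {
    "DG": 2, "TG": 58, "CE": 5, "PC": 42, "PC-O": 16, "LPC": 15,
    "PI": 7, "LPI": 2, "PE": 11, "PE-O": 15, "PE-P": 1, "LPE": 7,
    "LPE-O": 2, "Cer": 6, "SM": 24, "GSL": 5,
}

#: individually reported species, included verbatim in the generated panel
REPORTED_SPECIES: dict[str, tuple[str, ...]] = {
    "PC": ("PC(16:0_18:0)", "PC(16:0_16:1)", "PC(16:0/22:5)",
           "PC(16:0/16:0)", "PC(36:6)"),
    "SM": ("SM(37:2;3)", "SM(18:1;2/24:0)", "SM(32:2;2)", "SM(38:2;2)"),
    "Cer": ("Cer(18:1;2/24:0)", "Cer(18:2;2/24:0)", "Cer(18:1;2/16:0)",
            "Cer(18:1;2/24:1)"),
    "PC-O": ("PC(O-34:2)",),
    "PI": ("PI(18:0/20:4)", "PI(34:1)", "PI(36:2)", "PI(36:4)", "PI(34:2)"),
    "LPC": ("LPC(16:0)", "LPC(18:2)"),
    "PE": ("PE(16:0_22:6)",),
    "CE": ("CE(22:6)", "CE(20:5)"),
}

_COMMON_FA = ("16:0", "16:1", "18:0", "18:1", "18:2", "18:3",
              "20:3", "20:4", "20:5", "22:5", "22:6", "14:0")
_LYSO_FA = _COMMON_FA + ("15:0", "17:0", "17:1", "20:0", "20:1", "20:2",
                         "22:4", "24:0")


def _candidates(subclass: str):
    """Deterministic stream of plausible shorthand names per subclass."""
    if subclass == "TG":
        for d in range(9):
            for c in range(44, 62, 2):
                yield f"TG({c}:{d})"
    elif subclass == "DG":
        for name in ("DG(34:1)", "DG(36:2)", "DG(36:3)", "DG(38:5)"):
            yield name
    elif subclass == "CE":
        for fa in _COMMON_FA:
            yield f"CE({fa})"
    elif subclass in ("PC", "PE"):
        for a, b in itertools.combinations_with_replacement(_COMMON_FA, 2):
            yield f"{subclass}({a}_{b})"
    elif subclass == "PI":
        for a, b in itertools.combinations_with_replacement(_COMMON_FA, 2):
            yield f"PI({a}_{b})"
    elif subclass in ("PC-O", "PE-O"):
        base = subclass.split("-")[0]
        for d in range(6):
            for c in range(30, 42, 2):
                yield f"{base}(O-{c}:{d})"
    elif subclass == "PE-P":
        for d in range(1, 7):
            for c in range(34, 42, 2):
                yield f"PE(P-{c}:{d})"
    elif subclass in ("LPC", "LPE", "LPI"):
        for fa in _LYSO_FA:
            yield f"{subclass}({fa})"
    elif subclass == "LPE-O":
        for c in (16, 18, 20):
            yield f"LPE(O-{c}:0)"
    elif subclass == "Cer":
        for nacyl in ("16:0", "18:0", "20:0", "22:0", "23:0", "24:0", "24:1"):
            yield f"Cer(18:1;2/{nacyl})"
    elif subclass == "SM":
        for h in (2, 3):
            for d in (1, 2):
                for c in range(32, 44):
                    yield f"SM({c}:{d};{h})"
    elif subclass == "GSL":
        for glycan in ("Hex1", "Hex2"):
            for nacyl in ("16:0", "22:0", "24:0", "24:1"):
                yield f"{glycan}Cer(18:1;2/{nacyl})"
    else:  # pragma: no cover
        raise ValueError(f"no name generator for subclass {subclass}")


def generate_panel(composition: dict[str, int] | None = None) -> list[str]:
    """Generate a unique, parseable lipid panel with the requested
    per-subclass composition (default: the published 218-species table).

    Individually reported species are included verbatim; the remainder are
    filled deterministically from plausible chain compositions.  Names are
    de-duplicated on parsed structure, so no two names alias the same
    species.
    """
    composition = dict(TABLE_COMPOSITION if composition is None
                       else composition)
    names: list[str] = []
    seen_keys: set = set()
    for subclass, want in composition.items():
        if want < 0:
            raise ValueError("composition counts must be non-negative")
        got = 0
        for name in itertools.chain(REPORTED_SPECIES.get(subclass, ()),
                                    _candidates(subclass)):
            if got == want:
                break
            p = parse_lipid_name(name)
            if p.subclass != subclass:
                raise ValueError(
                    f"{name!r} parsed as {p.subclass}, wanted {subclass}")
            if p.key() in seen_keys:
                continue
            seen_keys.add(p.key())
            names.append(name)
            got += 1
        if got != want:
            raise ValueError(
                f"could not generate {want} unique {subclass} names")
    return names


# --------------------------------------------------------------------------
# feature table
# --------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Ground truth of a simulated run.

    ``species`` (indexed by shorthand name): baseline log2 abundance,
    planted log2 effects (age, sex, interaction), residual SD, bad-feature
    flags.  ``drift`` holds the per-feature x injection multiplicative
    drift factors actually applied. ``covariate_loadings`` are log2 units
    per z-scored covariate unit, identical for all species.
    """

    species: pd.DataFrame
    covariate_loadings: dict
    drift: pd.DataFrame | None = None
    seed: int | None = None


DEFAULT_LOADINGS = {"body_fat": 0.10, "hba1c": 0.05}


def make_truth(panel: list[str], *, seed: int = 0,
               delta_age: float | dict[str, float] = 0.0,
               delta_sex: float | dict[str, float] = 0.0,
               delta_interaction: float | dict[str, float] = 0.0,
               residual_sd: float = 0.25,
               frac_bad_cv: float = 0.0,
               frac_bad_linearity: float = 0.0,
               covariate_loadings: dict | None = None) -> SyntheticTruth:
    """Draw per-species baselines and plant effects / bad features.

    Baselines are lognormal around subclass-level means (log2 mean ~17,
    between-subclass SD 1.5, within-subclass SD 1.0), mimicking the wide
    dynamic range of serum lipid peak areas.  ``delta_*`` may be a scalar
    applied to every species or a {name: value} mapping.
    """
    rng = np.random.default_rng(seed)
    sub_of = {nm: parse_lipid_name(nm).subclass for nm in panel}
    subclasses = sorted(set(sub_of.values()))
    sub_mean = dict(zip(subclasses, 17.0 + 1.5 * rng.standard_normal(
        len(subclasses))))

    def expand(delta):
        if isinstance(delta, dict):
            return pd.Series({nm: delta.get(nm, 0.0) for nm in panel})
        return pd.Series(float(delta), index=panel)

    n = len(panel)
    species = pd.DataFrame({
        "baseline_log2": [sub_mean[sub_of[nm]] for nm in panel]
        + rng.standard_normal(n),
        "delta_age": expand(delta_age),
        "delta_sex": expand(delta_sex),
        "delta_interaction": expand(delta_interaction),
        "residual_sd": residual_sd,
    }, index=pd.Index(panel, name="species"))
    species["bad_cv"] = rng.random(n) < frac_bad_cv
    # keep the two planted failure modes disjoint so each filter's
    # sensitivity is attributable
    species["bad_linearity"] = ((rng.random(n) < frac_bad_linearity)
                                & ~species["bad_cv"])
    return SyntheticTruth(
        species=species,
        covariate_loadings=dict(DEFAULT_LOADINGS if covariate_loadings is None
                                else covariate_loadings),
        seed=seed,
    )


def _drift_shape(orders: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order polynomial drift shape, scaled to [-1, 1]."""
    x = (orders - orders.min()) / max(orders.max() - orders.min(), 1)
    coefs = rng.standard_normal(4)
    shape = np.polyval(coefs, x)
    shape -= shape.mean()
    peak = np.abs(shape).max()
    return shape / peak if peak > 0 else shape


def generate_feature_table(truth: SyntheticTruth, cohort: pd.DataFrame, *,
                           seed: int = 0, drift_amplitude: float = 0.2,
                           qc_noise_cv: float = 0.05,
                           bad_qc_noise_cv: float = 0.40,
                           dqc_noise_cv: float = 0.05,
                           qc_every: int = 10,
                           redundant_fraction: float = 0.0,
                           ) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate the analytical run for a cohort and truth table.

    Study samples are injected in randomised order with a pooled QC at
    every ``qc_every``-th position of the main run; the five-level dilution
    series (100/50/25/12.5/6.25%) brackets the run.  Study areas are
    2**(baseline + planted effects + covariate loadings + noise) times the
    feature's drift factor; pooled-QC areas follow the pooled mean of the
    study samples.  Features flagged ``bad_cv`` get irreproducible QC
    signal; ``bad_linearity`` features ignore the dilution level.  A
    ``redundant_fraction`` of species is additionally emitted in the
    opposite polarity at lower intensity to exercise redundancy removal.
    Returns the table and a truth copy carrying the realised drift field.
    """
    rng = np.random.default_rng(seed)
    panel = list(truth.species.index)
    samples = list(cohort.index)

    # --- injection schedule ------------------------------------------------
    study_order = [samples[i] for i in rng.permutation(len(samples))]
    main: list[tuple[str, float | None, str | None]] = []
    si = iter(study_order)
    pos, placed = 0, 0
    while placed < len(study_order):
        pos += 1
        if pos % qc_every == 0:
            main.append(("qc", None, None))
        else:
            main.append(("study", None, next(si)))
            placed += 1
    dqc = [("dqc", lvl, None) for lvl in (100.0, 50.0, 25.0, 12.5, 6.25)]
    schedule = dqc + main + dqc
    manifest = pd.DataFrame({
        "order": np.arange(1, len(schedule) + 1),
        "type": [s[0] for s in schedule],
        "dilution_percent": [s[1] for s in schedule],
        "sample_id": [s[2] for s in schedule],
    }, index=pd.Index([f"inj{i + 1:03d}" for i in range(len(schedule))],
                      name="injection"))

    # --- expected per-sample log2 levels ----------------------------------
    z = {}
    for cov in truth.covariate_loadings:
        x = cohort[cov].astype(float)
        sd = x.std(ddof=1)
        z[cov] = (x - x.mean()) / sd if sd > 0 else x * 0.0
    aged = (cohort["age_group"] == "aged").astype(float)
    male = (cohort["sex"] == "male").astype(float)
    sp = truth.species
    mu = (sp["baseline_log2"].to_numpy()[:, None]
          + np.outer(sp["delta_age"], aged)
          + np.outer(sp["delta_sex"], male)
          + np.outer(sp["delta_interaction"], aged * male))
    for cov, load in truth.covariate_loadings.items():
        mu = mu + load * z[cov].to_numpy()[None, :]
    mu = pd.DataFrame(mu, index=panel, columns=samples)
    qc_level = np.exp2(mu).mean(axis=1)  # pooled QC = mean of study samples

    # --- drift field -------------------------------------------------------
    orders = manifest["order"].to_numpy(float)
    shape = _drift_shape(orders, rng)
    amp = drift_amplitude * rng.uniform(0.5, 1.5, size=len(panel))
    drift = 1.0 + np.outer(amp, shape)
    drift = np.clip(drift, 0.05, None)

    # --- areas -------------------------------------------------------------
    def lognoise(cv: float, size) -> np.ndarray:
        sigma = np.sqrt(np.log1p(cv ** 2))
        return np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=size))

    n_feat, n_inj = len(panel), len(schedule)
    areas = np.zeros((n_feat, n_inj))
    types = manifest["type"].to_numpy()
    for j, (inj, row) in enumerate(manifest.iterrows()):
        if row["type"] == "study":
            eps = rng.normal(0.0, sp["residual_sd"].to_numpy())
            areas[:, j] = np.exp2(mu[row["sample_id"]].to_numpy() + eps)
        elif row["type"] == "qc":
            cvs = np.where(sp["bad_cv"], bad_qc_noise_cv, qc_noise_cv)
            sigma = np.sqrt(np.log1p(cvs ** 2))
            noise = np.exp(rng.normal(-sigma ** 2 / 2, sigma))
            areas[:, j] = qc_level.to_numpy() * noise
        else:  # dqc
            frac = row["dilution_percent"] / 100.0
            base = np.where(sp["bad_linearity"],
                            qc_level * lognoise(0.5, n_feat),
                            qc_level * frac)
            areas[:, j] = base * lognoise(dqc_noise_cv, n_feat)
    areas *= drift

    feature_ids = [f"F{i + 1:04d}" for i in range(n_feat)]
    polarity = ["positive" if parse_lipid_name(nm).category
                in ("glycerolipid", "sphingolipid", "sterol lipid")
                or nm.startswith(("PC", "LPC"))
                else "negative" for nm in panel]
    features = pd.DataFrame({"lipid_name": panel, "polarity": polarity},
                            index=pd.Index(feature_ids, name="feature_id"))
    areas_df = pd.DataFrame(areas, index=features.index,
                            columns=manifest.index)

    if redundant_fraction > 0:
        n_red = int(round(redundant_fraction * n_feat))
        picks = rng.choice(n_feat, size=n_red, replace=False)
        dup_ids = [f"F{i + 1:04d}dup" for i in picks]
        dup_feat = pd.DataFrame({
            "lipid_name": [panel[i] for i in picks],
            "polarity": ["negative" if polarity[i] == "positive"
                         else "positive" for i in picks],
        }, index=pd.Index(dup_ids, name="feature_id"))
        dup_areas = areas_df.iloc[picks] * rng.uniform(0.2, 0.6,
                                                       size=(n_red, 1))
        dup_areas.index = dup_feat.index
        features = pd.concat([features, dup_feat])
        areas_df = pd.concat([areas_df, dup_areas])

    table = FeatureTable(features=features, areas=areas_df,
                         manifest=manifest)
    truth_out = replace(
        truth,
        drift=pd.DataFrame(drift, index=panel, columns=manifest.index),
        seed=seed,
    )
    return table, truth_out


def simulate_study(*, seed: int = 0, composition: dict[str, int] | None = None,
                   cohort_cfg: CohortConfig = CohortConfig(),
                   **table_kwargs):
    """One-call simulation: cohort + panel + feature table + truth.

    ``table_kwargs`` are forwarded to :func:`make_truth` and
    :func:`generate_feature_table` (keys are routed by name).
    """
    rng = np.random.default_rng(seed)
    s_cohort, s_truth, s_table = rng.integers(0, 2 ** 31 - 1, size=3)
    cohort = generate_cohort(cohort_cfg, seed=int(s_cohort))
    panel = generate_panel(composition)
    truth_keys = {"delta_age", "delta_sex", "delta_interaction",
                  "residual_sd", "frac_bad_cv", "frac_bad_linearity",
                  "covariate_loadings"}
    truth = make_truth(panel, seed=int(s_truth),
                       **{k: v for k, v in table_kwargs.items()
                          if k in truth_keys})
    table, truth = generate_feature_table(
        truth, cohort, seed=int(s_table),
        **{k: v for k, v in table_kwargs.items() if k not in truth_keys})
    return cohort, table, truth
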