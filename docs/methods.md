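# Methods

This note documents the models, defaults and design choices behind `lwas`,
and what the synthetic-data generator does and does not emulate.

## Shorthand nomenclature

The parser accepts the community shorthand grammar for annotated lipid
species: `SUBCLASS(C:D)` sum compositions, `;H` hydroxyl counts on
sphingolipids, `_`-separated chains (composition known, sn positions not),
`/`-separated chains (sn-resolved), `O-`/`P-` ether prefixes, hyphenated
subclass spellings (`PE-P(...)` ≡ `PE(P-...)`) and glycan-prefixed ceramide
stems (`Hex1Cer(...)`, grouped as GSL). Sixteen subclasses are supported —
DG, TG, CE, PC, PC-O, LPC, PI, LPI, PE, PE-O, PE-P, LPE, LPE-O, Cer, SM,
GSL — mapped onto four categories (glycerolipids, glycerophospholipids,
sphingolipids, sterol lipids).

Decisions taken where the grammar leaves room:

* `_` and `/` are recorded as distinct annotation levels but treated
  identically downstream; sn position never enters any aggregation.
* Species-level saturation uses the total double-bond count with the usual
  0 / 1 / ≥2 → SFA / MUFA / PUFA rule. Per-chain classes are also reported
  when chains are resolved, but aggregation needs one class per species, so
  the total-count class is the one used for saturation sums. This also
  covers sum-composition names whose chains are unknown.
* Hydroxyl counts written before `/` attach to the sphingoid backbone;
  on sum compositions they are species totals.
* Any glycan prefix token (`Hex1`, `Hex2`, `Glc`, `Gal`, `Lac`) maps to the
  single GSL subclass; the prefix is retained so serialisation round-trips.
* Serialisation is canonical (ether bond inside the parentheses); the
  packaged panel is stored in canonical form, so parse∘serialise is the
  identity on it.

The packaged 218-name reference panel is a **reconstruction**: it matches
the published per-subclass composition, includes every species name printed
in the study narrative verbatim, and fills the remainder with generated,
chemically plausible names. It is a parser/aggregation fixture, not a claim
about which species the original cohort contained.

## Ontology

The enrichment ontology is derived from structure: subclass, category,
headgroup (choline/ethanolamine/inositol), ether-linkage terms (including
the LION-style `1-alkyl,2-acylglycerophosphoethanolamines` for PE-O),
species-level saturation, and a curated static table of cellular-component
terms per subclass (membrane component, plasma membrane, mitochondrion,
peroxisome, endoplasmic reticulum, lipid droplet). The table is versioned
with the package and deliberately small; it is a synthetic stand-in
reflecting textbook subclass localisation, not an export of any external
ontology service.

## QC processing

Pipeline order: drift correction → CV filter → linearity filter →
redundancy removal. CV is computed on drift-corrected data, the standard
pooled-QC regression convention.

* **Drift correction.** Per feature, LOESS (local linear, span 0.75,
  0 robustness iterations by default, ≥5 QC points required) of QC area on
  injection order, a natural cubic interpolating spline through the fitted
  QC values evaluated at all orders, and division by the fitted curve
  normalised to its median over QC orders. The correction is multiplicative
  and preserves each feature's scale and non-negativity. A non-positive
  fitted curve falls back to a straight-line trend; features that still
  fail are passed through unchanged and flagged. Local-linear fitting
  reproduces a noiseless linear trend exactly, which is the basis of the
  exactness test.
* **CV filter.** CV = sample SD (n−1) / mean over pooled QCs; removal on
  CV strictly greater than 0.20, so a CV of exactly the threshold is kept.
  An undefined CV (non-positive mean) removes the feature.
* **Linearity filter.** Pearson correlation between area and dilution
  percentage over all dilution-QC injections, both bracketing series
  pooled (10 points); removal below r = 0.8 or when undefined. A manifest
  without dilution QCs skips the filter with a warning by default
  (configurable to fail).
* **Redundancy removal.** Features parsing to the same structure collapse
  to the one with the highest mean pooled-QC abundance; ties break to
  positive polarity, then feature id — deterministic and abundance-driven.

## Aggregation and scaling

Subclass and (subclass × saturation) sums are plain additions of raw peak
areas, computed before any transformation; ratios are quotients of raw
sums. "PC to PE" ratios are expanded to the linkage-matched pairs PC/PE,
PC-O/PE-O and LPC/LPE (PE-P has no choline counterpart in the panel and is
skipped); a MUFA/PUFA ratio is emitted for every subclass whose two sums
are strictly positive in all samples. All rows are then log2-transformed
and z-standardised (mean 0, sample SD 1 across study samples); the
pre-standardisation mean and SD are stored per row, because contrasts must
be mapped back to log2 units before they can be expressed as fold changes.
Zero-variance rows are flagged and excluded from modelling rather than
imputed.

## Association model

Per lipid row: OLS of the standardised abundance on an intercept, aged
(0/1, reference young), male (0/1, reference female), their product, and
six covariates — body fat %, HbA1c %, daily total physical activity
(min/day), blood sampling time, fasting time (h) as z-standardised
continuous terms and statins intake as 0/1. The blood-sampling slot enters
as a continuous hour-of-day by default (five equispaced slots make this a
reasonable linear coding); a categorical option exists. Rank deficiency is
a hard error naming the collinear columns.

EMMs are model predictions at a reference grid: factor cells at their four
combinations, continuous covariates at grand means, binary covariates at
observed proportions. Contrasts (aged−young within each sex, male−female
within each age group) use SE = √(cᵀΣc) and the residual-df t
distribution. Because models are fitted on z-standardised responses but a
fold change is only meaningful on the log2 scale, each contrast is
multiplied by the response's stored log2-scale SD before conversion to the
percentage of difference (2^β − 1) × 100. Note that covariates fixed at
identical values in both cells cancel from every contrast, so the
reference-grid convention for binary covariates does not affect the
reported differences.

BH adjustment is step-up with enforced monotonicity, applied jointly per
family: one family per model term across all lipid rows, and one family per
contrast type across all lipid rows.

The implementation is cross-checked in the test suite against brute-force
normal-equation and prediction oracles and against frozen references
computed with the R `emmeans` package (contrasts) and the Bioconductor
`limma` package (moderated t), at 1e-10.

## PCA and moderated differential analysis

PCA treats samples as observations and lipid rows as variables, centred
and unit-variance scaled by default (lipid rows span orders of magnitude
even after log2). The moderated analysis fits, per species, OLS of log2
abundance on group and centred sampling time, then shrinks residual
variances via the scaled-F empirical-Bayes model: the prior (d₀, s₀²) is
estimated by method of moments on log s² (digamma/trigamma moment
matching, trigamma inverted by Newton iteration), s̃² = (d₀s₀² + d·s²) /
(d₀ + d), and the moderated t is referred to d₀ + d degrees of freedom.
A log-variance spread no larger than the sampling spread yields d₀ = ∞ and
complete shrinkage. Method of moments was chosen over full ML because it is
closed-form, deterministic and accurate at the panel sizes involved.

## Enrichment

The ranked test is a one-sided two-sample Mann–Whitney comparison of term
members' ranks against non-members', exact when the product of group sizes
is small (≤10⁴, always the case at panel scale) and normal-approximated
otherwise; it depends on the ordering only and is therefore invariant to
monotone transforms of the effect sizes. Degenerate terms (zero or full
overlap) get p = 1 and a flag. Over-representation analysis on a top-k cut
uses the hypergeometric upper tail. q-values are BH across terms. The
ranked test is the default because the workflow submits an ordered species
list; the statistic used by the original web tool is not documented, so the
package documents its own.

## Synthetic data

The generator emulates the study conditions:

* **Cohort.** Four age × sex groups of 32/41/37/40 (young-F, young-M,
  aged-F, aged-M); per-group means/SDs for age, body fat %, HbA1c %, daily
  total physical activity and fasting time taken from the published
  participants table; statins prevalence 0/0/8%/15%; five blood-draw slots
  (08:00–16:00) assigned uniformly. Continuous draws are truncated normals
  (body fat 3–60%, HbA1c 3.5–9%, activity ≥ 0, fasting 1–24 h) to avoid
  physiologically absurd values, since only means/SDs are published.
* **Panel.** Default is the 218-species composition above.
* **Run structure.** Study samples in randomised order; a pooled QC at
  every tenth position of the main run; the five-level dilution series at
  batch start and end.
* **Signal.** Study areas are 2^(baseline + δ_age·aged + δ_sex·male +
  δ_int·aged·male + Σ loadings·z(covariate) + ε) × drift(order). Baselines
  are lognormal around subclass-level means (log2 ≈ 17 ± 1.5 between
  subclasses, ±1 within), residual SD 0.25 log2 units by default. Pooled-QC
  levels are the pooled mean of the per-sample expected areas with 5%
  lognormal noise; dilution QCs scale that level by the dilution fraction.
  Default covariate loadings (body fat 0.10, HbA1c 0.05 log2 per z-unit)
  give the covariate adjustment something real to remove.
* **Drift.** A smooth random cubic shape common to the run, scaled per
  feature to a configurable amplitude (default ±20% with ±50% per-feature
  variation). Multiplicative, as pooled-QC workflows assume.
* **Planted failures.** A configurable fraction of features gets
  irreproducible QC signal (CV ≈ 40%) or dilution-independent dQC signal;
  the two sets are kept disjoint so each filter's sensitivity is
  attributable. A configurable fraction of species is duplicated in the
  opposite polarity at reduced intensity to exercise redundancy removal.

Everything flows from one integer seed (child seeds < 2³¹), and
regeneration is bit-reproducible on a given platform.

What the generator does **not** emulate: missing values, adducts/isotopes
and in-source fragments, retention-time structure, batch boundaries,
heavy-tailed residuals, and correlated species (each species' noise is
independent). Passing tests therefore demonstrate that the machinery is
correct and calibrated under these idealised conditions, not that the
original cohort's effect sizes are recoverable from real data.

## Validation studies and problem sizes

The replicated studies (`lwas.study`) use the full 150-participant cohort
with a compact 24-species panel per replicate — the pipeline is exercised
end to end either way, and hundreds of replicates then run in a few
minutes on one CPU. Parameter recovery plants log2(1.617) ≈ 0.693 on one
sphingomyelin and checks that the mean recovered percentage of difference
over 200 replicates is within 3 Monte-Carlo SEs of 61.7%; the null study
(all effects and covariate loadings zero) checks the BH-positive rate;
filter performance uses 15% planted bad features of each kind.

## Known limitations

* Single batch only; no batch-to-batch anchoring or gap filling.
* The moderated analysis supports exactly two groups plus one covariate.
* The cellular-component ontology is a small curated table; enrichment
  results over it are illustrative, not biologically exhaustive.
* No missing-value handling beyond the constant-row rule; inputs are
  assumed complete, as the synthetic generator produces them.
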