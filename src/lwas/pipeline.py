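"""End-to-end analysis: QC -> aggregation -> association -> enrichment.

Ties the modules together the way the study is run: drift-correct and
filter the feature table against the pooled-QC and dilution-QC injections,
build the raw analysis matrix (species, subclass and saturation sums,
ratios), log2-transform and standardise, fit the covariate-adjusted models
with EMM contrasts, and feed species ranked by decreasing percentage of
difference into the ontology enrichment.  PCA and the moderated
differential analysis provide the global views.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import aggregation, association, enrichment, multivariate, qc
from .nomenclature import build_ontology, parse_lipid_name

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    qc_report: pd.DataFrame
    matrix: aggregation.LipidMatrix
    association: association.AssociationResult
    pca: multivariate.PcaResult | None
    differential: multivariate.DifferentialResult | None
    enrichment: dict[str, pd.DataFrame]

    def contrasts_for(self, label: str, kind: str = "species"
                      ) -> pd.DataFrame:
        """Contrast table restricted to rows of one kind, sorted by
        decreasing percentage of difference."""
        rows = self.matrix.rows_of_kind(kind)
        ct = self.association.contrasts
        ct = ct[(ct["contrast"] == label) & ct["row_id"].isin(rows)]
        return ct.sort_values("percent_difference", ascending=False)


def run_pipeline(table: qc.FeatureTable, metadata: pd.DataFrame, *,
                 span: float = 0.75, cv_threshold: float = 0.20,
                 r_min: float = 0.8,
                 spec: association.ModelSpec = association.ModelSpec(),
                 run_multivariate: bool = True,
                 run_enrichment: bool = True) -> PipelineResult:
    """Run the full association study on a raw feature table."""
    clean, report = qc.run_qc_pipeline(table, span=span,
                                       cv_threshold=cv_threshold,
                                       r_min=r_min)
    study = clean.study_only()
    # metadata restricted/ordered to the samples actually injected
    meta = metadata.loc[study.manifest["sample_id"]]

    matrix = aggregation.aggregate(study)
    matrix = aggregation.compute_ratios(matrix)
    matrix = aggregation.log2_and_standardise(matrix)

    assoc = association.associate(matrix, meta, spec=spec)

    pca_res = diff_res = None
    if run_multivariate:
        pca_res = multivariate.run_pca(matrix, n_components=2)
        diff_res = multivariate.moderated_differential(
            matrix, group=meta["age_group"],
            sampling_time=meta["sampling_time"], reference="young")

    enrich: dict[str, pd.DataFrame] = {}
    if run_enrichment:
        parsed = [parse_lipid_name(nm)
                  for nm in matrix.rows_of_kind("species")]
        ontology = build_ontology(parsed)
        for label in ("aged-young | female", "aged-young | male"):
            ranked = list(contrasts_ranking(assoc, matrix, label))
            enrich[label] = enrichment.enrich_ranked(ranked, ontology)

    return PipelineResult(qc_report=report, matrix=matrix, association=assoc,
                          pca=pca_res, differential=diff_res,
                          enrichment=enrich)


def contrasts_ranking(assoc: association.AssociationResult,
                      matrix: aggregation.LipidMatrix, label: str):
    """Species ordered by decreasing percentage of difference for one
    contrast."""
    rows = matrix.rows_of_kind("species")
    ct = assoc.contrasts
    ct = ct[(ct["contrast"] == label) & ct["row_id"].isin(rows)]
    return ct.sort_values("percent_difference",
                          ascending=False)["row_id"].tolist()
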