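"""CSV/TSV readers and writers for feature tables, manifests and results.

Formats are plain text: a wide feature-table CSV whose first columns are
``feature_id``, ``lipid_name`` and ``polarity`` followed by one column per
injection; an injection-manifest CSV with ``injection``, ``order``,
``type``, ``dilution_percent`` and ``sample_id``; and a sample-metadata CSV
indexed by ``sample_id``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .qc import FeatureTable

__all__ = ["read_feature_table", "write_feature_table",
           "read_metadata", "write_metadata"]

_META_COLS = ["lipid_name", "polarity"]


def write_feature_table(t: FeatureTable, areas_path, manifest_path) -> None:
    wide = pd.concat([t.features[_META_COLS], t.areas], axis=1)
    wide.index.name = "feature_id"
    wide.to_csv(areas_path)
    t.manifest.to_csv(manifest_path)


def read_feature_table(areas_path, manifest_path) -> FeatureTable:
    wide = pd.read_csv(areas_path, index_col="feature_id")
    manifest = pd.read_csv(manifest_path, index_col="injection")
    features = wide[_META_COLS]
    areas = wide.drop(columns=_META_COLS)
    areas = areas[manifest.index]  # order columns by the manifest
    return FeatureTable(features=features, areas=areas, manifest=manifest)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_results(result, outdir) -> None:
    """Write the standard result set of a pipeline run to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.qc_report.to_csv(out / "qc_report.tsv", sep="\t")
    result.matrix.values.to_csv(out / "analysis_matrix.tsv", sep="\t")
    result.matrix.row_meta.to_csv(out / "analysis_matrix_rows.tsv", sep="\t")
    result.association.coefficients.to_csv(out / "coefficients.tsv",
                                           sep="\t", index=False)
    result.association.contrasts.to_csv(out / "contrasts.tsv", sep="\t",
                                        index=False)
    if result.pca is not None:
        result.pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pd.Series(result.pca.explained_variance_ratio,
                  index=result.pca.scores.columns,
                  name="explained_variance_ratio").to_csv(
            out / "pca_explained_variance.tsv", sep="\t")
    if result.differential is not None:
        result.differential.table.to_csv(out / "differential.tsv", sep="\t")
    for label, table in result.enrichment.items():
        safe = label.replace(" | ", "_").replace("-", "_vs_")
        table.to_csv(out / f"enrichment_{safe}.tsv", sep="\t")
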