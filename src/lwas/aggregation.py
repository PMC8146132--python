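"""Analysis-matrix construction: subclass/saturation sums, ratios, scaling.

Species abundances are summed on the raw scale into per-subclass and
per-(subclass x saturation-class) totals, subclass-level MUFA/PUFA and
choline/ethanolamine ratios are formed from those raw sums, and the whole
matrix is then log2-transformed and z-standardised row-wise for modelling.
The pre-standardisation mean and SD of every row are retained so that model
contrasts can be mapped back to the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nomenclature import ParsedLipid, classify_saturation, parse_lipid_name
from .qc import FeatureTable

__all__ = ["LipidMatrix", "aggregate", "compute_ratios",
           "log2_and_standardise"]

log = logging.getLogger(__name__)

#: choline/ethanolamine subclass pairs matched by linkage
PC_PE_PAIRS = (("PC", "PE"), ("PC-O", "PE-O"), ("LPC", "LPE"))


@dataclass
class LipidMatrix:
    """Rows (species, sums, ratios) by study samples, with scale bookkeeping.

    ``row_meta`` columns: ``row_kind`` in {species, subclass_sum,
    saturation_sum, ratio}, ``subclass``, ``saturation``, ``definition``
    (';'-joined contributing species, or the ratio formula).  After
    standardisation ``row_center``/``row_scale`` hold the log2-scale mean
    and sample SD per row and ``constant_rows`` the rows excluded from
    modelling for zero variance.
    """

    values: pd.DataFrame
    row_meta: pd.DataFrame
    scale: str = "raw"  # 'raw' | 'log2_z'
    row_center: pd.Series | None = None
    row_scale: pd.Series | None = None
    constant_rows: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.row_meta.index):
            raise ValueError("values and row_meta must share the same index")

    def rows_of_kind(self, kind: str) -> pd.Index:
        return self.row_meta.index[self.row_meta["row_kind"] == kind]

    def modellable_rows(self) -> pd.Index:
        return self.values.index[~self.values.index.isin(self.constant_rows)]

    def back_scale(self, row_id: str, z: float) -> float:
        """Map a z-scale value of ``row_id`` back to the log2 scale."""
        if self.scale != "log2_z":
            raise ValueError("matrix is not standardised")
        return z * self.row_scale[row_id] + self.row_center[row_id]


def aggregate(t: FeatureTable,
              parsed: dict[str, ParsedLipid] | None = None) -> LipidMatrix:
    """Build the raw analysis matrix from a cleaned study-only feature table.

    Adds one ``subclass_sum`` row per subclass present and one
    ``saturation_sum`` row per (subclass, species-level saturation class)
    present; all sums are plain additions of raw areas.  Row ids are the
    species shorthand names, ``<subclass>`` for subclass sums and
    ``<subclass> <class>`` for saturation sums.
    """
    if set(t.manifest["type"]) != {"study"}:
        raise ValueError("aggregate expects a study-only table "
                         "(use FeatureTable.study_only())")
    if parsed is None:
        parsed = {fid: parse_lipid_name(nm)
                  for fid, nm in t.features["lipid_name"].items()}

    names = [parsed[fid].raw_name for fid in t.areas.index]
    if len(set(names)) != len(names):
        raise ValueError("feature table still contains duplicate species")

    sample_ids = t.manifest["sample_id"]
    values = t.areas.copy()
    values.columns = [sample_ids[c] for c in values.columns]
    values.index = names

    meta_rows = {}
    for fid, name in zip(t.areas.index, names):
        p = parsed[fid]
        _, sat = classify_saturation(p)
        meta_rows[name] = ("species", p.subclass, sat, name)

    sub_groups: dict[str, list[str]] = {}
    sat_groups: dict[tuple[str, str], list[str]] = {}
    for name in names:
        _, sub, sat, _ = meta_rows[name]
        sub_groups.setdefault(sub, []).append(name)
        sat_groups.setdefault((sub, sat), []).append(name)

    extra = {}
    for sub, members in sorted(sub_groups.items()):
        extra[sub] = values.loc[members].sum(axis=0)
        meta_rows[sub] = ("subclass_sum", sub, None, ";".join(members))
    for (sub, sat), members in sorted(sat_groups.items()):
        rid = f"{sub} {sat}"
        extra[rid] = values.loc[members].sum(axis=0)
        meta_rows[rid] = ("saturation_sum", sub, sat, ";".join(members))

    values = pd.concat([values, pd.DataFrame(extra).T])
    meta = pd.DataFrame.from_dict(
        meta_rows, orient="index",
        columns=["row_kind", "subclass", "saturation", "definition"],
    ).loc[values.index]
    return LipidMatrix(values=values, row_meta=meta, scale="raw")


def compute_ratios(m: LipidMatrix) -> LipidMatrix:
    """Append subclass-level MUFA/PUFA and choline/ethanolamine ratio rows.

    A MUFA/PUFA ratio is added for every subclass whose MUFA and PUFA sums
    are both strictly positive in every sample ("if applicable"); the
    choline/ethanolamine ratios pair analogues by linkage (PC/PE,
    PC-O/PE-O, LPC/LPE).  Ratios are quotients of raw-scale sums; a missing
    or non-positive denominator omits the row with a log message.
    """
    if m.scale != "raw":
        raise ValueError("ratios must be computed on the raw scale")
    values, meta = m.values, m.row_meta
    extra, extra_meta = {}, {}

    subclasses = sorted(meta.loc[m.rows_of_kind("subclass_sum"), "subclass"])
    for sub in subclasses:
        num_id, den_id = f"{sub} MUFA", f"{sub} PUFA"
        if num_id not in values.index or den_id not in values.index:
            log.info("MUFA/PUFA ratio not applicable for %s", sub)
            continue
        num, den = values.loc[num_id], values.loc[den_id]
        if (num <= 0).any() or (den <= 0).any():
            log.info("MUFA/PUFA ratio for %s skipped: non-positive sum", sub)
            continue
        rid = f"{sub} MUFA/PUFA"
        extra[rid] = num / den
        extra_meta[rid] = ("ratio", sub, None, f"{num_id} / {den_id}")

    for cho, etn in PC_PE_PAIRS:
        if cho not in values.index or etn not in values.index:
            log.info("ratio %s/%s not applicable: subclass absent", cho, etn)
            continue
        num, den = values.loc[cho], values.loc[etn]
        if (num <= 0).any() or (den <= 0).any():
            log.info("ratio %s/%s skipped: non-positive sum", cho, etn)
            continue
        rid = f"{cho}/{etn}"
        extra[rid] = num / den
        extra_meta[rid] = ("ratio", cho, None, f"{cho} / {etn}")

    if not extra:
        return m
    values = pd.concat([values, pd.DataFrame(extra).T])
    meta = pd.concat([meta, pd.DataFrame.from_dict(
        extra_meta, orient="index", columns=meta.columns.tolist())])
    return LipidMatrix(values=values, row_meta=meta, scale="raw")


def log2_and_standardise(m: LipidMatrix) -> LipidMatrix:
    """log2-transform all rows, then z-standardise each row across samples.

    The pre-standardisation mean and sample SD (n-1) are stored per row so
    effects estimated on the z scale can be mapped back to log2 units.
    Rows with zero variance are flagged constant, left at zero after
    centring, and excluded from modelling.
    """
    if m.scale != "raw":
        raise ValueError(f"expected a raw-scale matrix, got {m.scale!r}")
    vals = m.values.to_numpy(float)
    bad = ~(vals > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "non-positive abundance at row "
            f"{m.values.index[i]!r}, sample {m.values.columns[j]!r}")
    logv = pd.DataFrame(np.log2(vals), index=m.values.index,
                        columns=m.values.columns)
    center = logv.mean(axis=1)
    scale = logv.std(axis=1, ddof=1)
    constant = scale.index[scale == 0]
    if len(constant):
        log.warning("%d constant rows excluded from modelling", len(constant))
    safe_scale = scale.replace(0, 1.0)
    z = logv.sub(center, axis=0).div(safe_scale, axis=0)
    return LipidMatrix(values=z, row_meta=m.row_meta, scale="log2_z",
                       row_center=center, row_scale=scale,
                       constant_rows=tuple(constant))
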