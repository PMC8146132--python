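"""Lipid-ontology term enrichment over a ranked species list.

Species are ranked by decreasing percentage of difference; for every
ontology term a one-sided two-sample rank test (Mann-Whitney / Wilcoxon
rank-sum of member ranks versus non-member ranks) asks whether the term's
members concentrate at the top of the list.  An over-representation mode
(hypergeometric test on a top-k cut) is available as an alternative.
q-values are Benjamini-Hochberg adjustments across terms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from .association import bh_adjust

__all__ = ["enrich_ranked", "enrich_ora"]

# exact null is cheap below this product of group sizes
_EXACT_LIMIT = 10_000


def _term_frame(rows: list[dict]) -> pd.DataFrame:
    out = pd.DataFrame(rows).set_index("term")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")


def enrich_ranked(ranked_species: list[str], ontology: dict[str, set[str]],
                  ) -> pd.DataFrame:
    """Rank-based term enrichment for a list ordered by decreasing effect.

    Per term the one-sided Mann-Whitney test compares the ranks of member
    species against non-members (alternative: members rank higher in the
    list, i.e. carry larger effects).  Degenerate terms (zero or full
    overlap with the panel) get p = 1 and are flagged.  The p-value depends
    on the ordering only, so it is invariant to monotone transforms of the
    underlying effect sizes.
    """
    n = len(ranked_species)
    if n != len(set(ranked_species)):
        raise ValueError("ranked species list contains duplicates")
    rank_of = {name: i + 1 for i, name in enumerate(ranked_species)}
    rows = []
    for term, members in ontology.items():
        members_in = [s for s in members if s in rank_of]
        m = len(members_in)
        if m == 0 or m == n:
            rows.append({"term": term, "matches": m, "statistic": np.nan,
                         "p": 1.0, "degenerate": True})
            continue
        member_ranks = np.array([rank_of[s] for s in members_in], float)
        other_ranks = np.array([r for s, r in rank_of.items()
                                if s not in members], float)
        method = "exact" if m * (n - m) <= _EXACT_LIMIT else "asymptotic"
        res = st.mannwhitneyu(member_ranks, other_ranks,
                              alternative="less", method=method)
        rows.append({"term": term, "matches": m,
                     "statistic": float(res.statistic),
                     "p": float(res.pvalue), "degenerate": False})
    return _term_frame(rows)


def enrich_ora(ranked_species: list[str], ontology: dict[str, set[str]],
               top_k: int) -> pd.DataFrame:
    """Over-representation (hypergeometric) enrichment on a top-k cut.

    p = P(overlap >= observed) drawing ``top_k`` species without
    replacement from a universe of size n containing the term's members.
    """
    n = len(ranked_species)
    if not 0 < top_k <= n:
        raise ValueError("top_k must be in (0, n]")
    top = set(ranked_species[:top_k])
    rows = []
    for term, members in ontology.items():
        members_in = set(members) & set(ranked_species)
        m = len(members_in)
        overlap = len(members_in & top)
        if m == 0 or m == n:
            rows.append({"term": term, "matches": m, "statistic": overlap,
                         "p": 1.0, "degenerate": True})
            continue
        p = float(st.hypergeom.sf(overlap - 1, n, m, top_k))
        rows.append({"term": term, "matches": m, "statistic": overlap,
                     "p": p, "degenerate": False})
    return _term_frame(rows)
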