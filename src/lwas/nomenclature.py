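"""Parsing and classification of lipid shorthand nomenclature.

Implements the community shorthand grammar used for annotated serum
lipidomics panels: ``SUBCLASS(C:D)``, ``SUBCLASS(C:D;H)`` for hydroxylated
sphingolipids, ``SUBCLASS(c1:d1_c2:d2)`` (chains known, sn positions not),
``SUBCLASS(c1:d1/c2:d2)`` (sn-resolved), ``SUBCLASS(O-C:D)`` /
``SUBCLASS(P-C:D)`` for alkyl- and alkenyl-ether lipids, and glycan-prefixed
sphingolipid names (``Hex1Cer(...)``) which are grouped as
glycosphingolipids (GSL).

A parsed name is decomposed into subclass, lipid category, ether/lyso
linkage, annotation level, per-chain (carbons, double bonds, hydroxyls) and
species totals, and can be serialised back to a canonical shorthand string.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "Chain",
    "ParsedLipid",
    "LipidNameError",
    "SUBCLASSES",
    "SUBCLASS_FULL_NAMES",
    "parse_lipid_name",
    "serialise",
    "classify_saturation",
    "chain_saturation",
    "count_by_subclass",
    "build_ontology",
    "load_reference_panel",
]


class LipidNameError(ValueError):
    """A lipid shorthand name could not be parsed."""


#: The 16 subclass abbreviations of the serum panel.
SUBCLASSES = (
    "DG", "TG", "CE",
    "PC", "PC-O", "LPC",
    "PI", "LPI",
    "PE", "PE-O", "PE-P", "LPE", "LPE-O",
    "Cer", "SM", "GSL",
)

SUBCLASS_FULL_NAMES: Mapping[str, str] = {
    "DG": "diglycerides",
    "TG": "triglycerides",
    "CE": "cholesterol esters",
    "PC": "glycerophosphocholines",
    "PC-O": "alkyl-glycerophosphocholines",
    "LPC": "lyso-glycerophosphocholines",
    "PI": "glycerophosphoinositols",
    "LPI": "lyso-glycerophosphoinositols",
    "PE": "glycerophosphoethanolamines",
    "PE-O": "alkyl-glycerophosphoethanolamines",
    "PE-P": "alkenyl-glycerophosphoethanolamines",
    "LPE": "lyso-glycerophosphoethanolamines",
    "LPE-O": "lyso-alkyl-glycerophosphoethanolamines",
    "Cer": "ceramides",
    "SM": "sphingomyelins",
    "GSL": "glycosphingolipids",
}

_CATEGORY = {
    "DG": "glycerolipid", "TG": "glycerolipid",
    "CE": "sterol lipid",
    "PC": "glycerophospholipid", "PC-O": "glycerophospholipid",
    "LPC": "glycerophospholipid", "PI": "glycerophospholipid",
    "LPI": "glycerophospholipid", "PE": "glycerophospholipid",
    "PE-O": "glycerophospholipid", "PE-P": "glycerophospholipid",
    "LPE": "glycerophospholipid", "LPE-O": "glycerophospholipid",
    "Cer": "sphingolipid", "SM": "sphingolipid", "GSL": "sphingolipid",
}

_LINKAGE = {
    "PC-O": "alkyl", "PE-O": "alkyl",
    "PE-P": "alkenyl",
    "LPC": "lyso-acyl", "LPE": "lyso-acyl", "LPI": "lyso-acyl",
    "LPE-O": "lyso-alkyl",
}

#: Number of chains a fully resolved name of each subclass must carry
#: (sphingolipids: sphingoid backbone + N-acyl).
_CHAIN_COUNT = {
    "DG": 2, "TG": 3, "CE": 1,
    "PC": 2, "PC-O": 2, "LPC": 1,
    "PI": 2, "LPI": 1,
    "PE": 2, "PE-O": 2, "PE-P": 2, "LPE": 1, "LPE-O": 1,
    "Cer": 2, "SM": 2, "GSL": 2,
}

_SPHINGO = {"Cer", "SM", "GSL"}

# ether prefix inside the parentheses promotes the base subclass
_ETHER_PROMOTION = {
    ("PC", "O"): "PC-O",
    ("PE", "O"): "PE-O",
    ("PE", "P"): "PE-P",
    ("LPE", "O"): "LPE-O",
}
# canonical serialisation renders the ether bond inside the parentheses
_ETHER_BASE = {"PC-O": ("PC", "O-"), "PE-O": ("PE", "O-"),
               "PE-P": ("PE", "P-"), "LPE-O": ("LPE", "O-")}

_GLYCAN_RE = re.compile(r"^(Hex\d?|Glc|Gal|Lac)Cer$")
_NAME_RE = re.compile(r"^(?P<head>[A-Za-z][A-Za-z0-9-]*)\((?P<body>[^()]+)\)$")
_CHAIN_RE = re.compile(
    r"^(?P<ether>[OP]-)?(?P<c>\d+):(?P<d>\d+)(?:;(?P<h>\d+))?$"
)


@dataclass(frozen=True)
class Chain:
    """A single aliphatic chain: carbons, double bonds, hydroxyl groups."""

    carbons: int
    double_bonds: int
    hydroxyls: int = 0

    def shorthand(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        if self.hydroxyls:
            s += f";{self.hydroxyls}"
        return s


@dataclass(frozen=True)
class ParsedLipid:
    raw_name: str
    subclass: str
    category: str
    linkage: str
    level: str  # 'sum-composition' | 'molecular-species' | 'sn-resolved'
    chains: tuple[Chain, ...]
    total_carbons: int
    total_double_bonds: int
    total_hydroxyls: int
    glycan: str | None = field(default=None)

    def key(self) -> tuple:
        """Identity used for redundancy detection (ignores the raw string)."""
        return (self.subclass, self.level, self.chains,
                self.total_carbons, self.total_double_bonds,
                self.total_hydroxyls, self.glycan)


def _parse_chain(token: str, name: str) -> tuple[Chain, str | None]:
    m = _CHAIN_RE.match(token)
    if m is None:
        raise LipidNameError(
            f"{name!r}: cannot parse chain token {token!r} "
            "(expected C:D, C:D;H, O-C:D or P-C:D)"
        )
    chain = Chain(int(m["c"]), int(m["d"]), int(m["h"] or 0))
    ether = m["ether"][0] if m["ether"] else None
    return chain, ether


def parse_lipid_name(name: str) -> ParsedLipid:
    """Parse a shorthand lipid name into its structural components.

    Raises
    ------
    LipidNameError
        If the name is malformed or the subclass token is not one of the
        16 supported abbreviations (or a glycan-prefixed ceramide).
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidNameError("empty lipid name")
    name = name.strip()
    m = _NAME_RE.match(name)
    if m is None:
        raise LipidNameError(
            f"{name!r}: expected 'SUBCLASS(...)' with parentheses"
        )
    head, body = m["head"], m["body"]

    glycan: str | None = None
    if head in SUBCLASSES:
        subclass = head
    elif _GLYCAN_RE.match(head):
        subclass = "GSL"
        glycan = head[:-3]
    else:
        raise LipidNameError(
            f"{name!r}: unknown subclass token {head!r}; supported: "
            + ", ".join(SUBCLASSES) + ", or a glycan-prefixed Cer (e.g. Hex1Cer)"
        )

    if "/" in body and "_" in body:
        raise LipidNameError(f"{name!r}: mixed '/' and '_' chain separators")
    if "/" in body:
        sep, level = "/", "sn-resolved"
    elif "_" in body:
        sep, level = "_", "molecular-species"
    else:
        sep, level = None, None  # single token; level decided below

    tokens = body.split(sep) if sep else [body]
    parsed = []
    for i, tok in enumerate(tokens):
        chain, ether = _parse_chain(tok, name)
        if ether is not None:
            if i != 0:
                raise LipidNameError(
                    f"{name!r}: ether prefix allowed on the first chain only"
                )
            promoted = _ETHER_PROMOTION.get((subclass, ether))
            if promoted is not None:
                subclass = promoted
            elif subclass not in _ETHER_BASE:
                raise LipidNameError(
                    f"{name!r}: ether prefix {ether}- not valid for subclass "
                    f"{subclass}"
                )
        parsed.append(chain)

    n_expected = _CHAIN_COUNT[subclass]
    if sep is None:
        if n_expected == 1:
            level = "molecular-species"
            chains: tuple[Chain, ...] = (parsed[0],)
        else:
            level = "sum-composition"
            chains = ()
    else:
        if len(parsed) != n_expected:
            raise LipidNameError(
                f"{name!r}: {subclass} requires {n_expected} chains, "
                f"got {len(parsed)}"
            )
        chains = tuple(parsed)

    if chains:
        total_c = sum(c.carbons for c in chains)
        total_d = sum(c.double_bonds for c in chains)
        total_h = sum(c.hydroxyls for c in chains)
    else:
        only = parsed[0]
        total_c, total_d, total_h = only.carbons, only.double_bonds, only.hydroxyls

    return ParsedLipid(
        raw_name=name,
        subclass=subclass,
        category=_CATEGORY[subclass],
        linkage=_LINKAGE.get(subclass, "acyl"),
        level=level,
        chains=chains,
        total_carbons=total_c,
        total_double_bonds=total_d,
        total_hydroxyls=total_h,
        glycan=glycan,
    )


def serialise(p: ParsedLipid) -> str:
    """Render a :class:`ParsedLipid` back to canonical shorthand.

    Ether bonds are written inside the parentheses (``PC(O-34:2)``), glycan
    prefixes before the ceramide stem (``Hex1Cer(...)``); re-parsing the
    result yields a structurally identical lipid.
    """
    if p.subclass == "GSL":
        head, ether = (p.glycan + "Cer" if p.glycan else "GSL"), ""
    elif p.subclass in _ETHER_BASE:
        head, ether = _ETHER_BASE[p.subclass]
    else:
        head, ether = p.subclass, ""

    if p.chains:
        sep = "/" if p.level == "sn-resolved" else "_"
        body = sep.join(c.shorthand() for c in p.chains)
    else:
        body = Chain(p.total_carbons, p.total_double_bonds,
                     p.total_hydroxyls).shorthand()
    return f"{head}({ether}{body})"


def chain_saturation(double_bonds: int) -> str:
    """SFA (0 double bonds), MUFA (1) or PUFA (>=2)."""
    if double_bonds < 0:
        raise ValueError("double bond count must be non-negative")
    if double_bonds == 0:
        return "SFA"
    return "MUFA" if double_bonds == 1 else "PUFA"


def classify_saturation(p: ParsedLipid) -> tuple[tuple[str, ...], str]:
    """Per-chain and species-level saturation classes.

    The species-level class is derived from the total double-bond count, so
    it is defined for sum-composition names whose individual chains are
    unknown.
    """
    per_chain = tuple(chain_saturation(c.double_bonds) for c in p.chains)
    return per_chain, chain_saturation(p.total_double_bonds)


def count_by_subclass(names: Iterable[str]) -> dict[str, int]:
    """Count parseable shorthand names per subclass.

    Parse failures propagate, naming the offending entry.
    """
    counts: Counter[str] = Counter()
    for name in names:
        counts[parse_lipid_name(name).subclass] += 1
    return dict(counts)


# Curated cellular-component annotation per subclass: a static, versioned
# stand-in for an external lipid-ontology library (synthetic, derived from
# textbook localisation of each subclass, not from any database export).
CELLULAR_COMPONENT_TERMS: Mapping[str, tuple[str, ...]] = {
    "PC": ("membrane component", "plasma membrane"),
    "PC-O": ("membrane component", "plasma membrane", "peroxisome"),
    "SM": ("membrane component", "plasma membrane"),
    "GSL": ("membrane component", "plasma membrane"),
    "Cer": ("membrane component", "plasma membrane", "endoplasmic reticulum"),
    "PE": ("membrane component", "mitochondrion", "endoplasmic reticulum"),
    "PE-O": ("membrane component", "mitochondrion", "peroxisome"),
    "PE-P": ("membrane component", "mitochondrion", "peroxisome"),
    "LPE-O": ("mitochondrion", "peroxisome"),
    "LPE": ("mitochondrion",),
    "PI": ("membrane component", "plasma membrane", "endoplasmic reticulum"),
    "LPI": (),
    "LPC": (),
    "DG": ("lipid droplet", "endoplasmic reticulum"),
    "TG": ("lipid droplet",),
    "CE": ("lipid droplet",),
}

# LION-style structural names for the ether subclasses
_LINKAGE_TERMS = {
    "PC-O": ("ether-glycerophospholipids",
             "1-alkyl,2-acylglycerophosphocholines"),
    "PE-O": ("ether-glycerophospholipids",
             "1-alkyl,2-acylglycerophosphoethanolamines"),
    "PE-P": ("ether-glycerophospholipids",
             "1-alkenyl,2-acylglycerophosphoethanolamines"),
    "LPE-O": ("ether-glycerophospholipids",
              "1-alkyl-glycerophosphoethanolamines"),
}

_HEADGROUP_TERMS = {
    "PC": "choline glycerophospholipids",
    "PC-O": "choline glycerophospholipids",
    "LPC": "choline glycerophospholipids",
    "PE": "ethanolamine glycerophospholipids",
    "PE-O": "ethanolamine glycerophospholipids",
    "PE-P": "ethanolamine glycerophospholipids",
    "LPE": "ethanolamine glycerophospholipids",
    "LPE-O": "ethanolamine glycerophospholipids",
    "PI": "inositol glycerophospholipids",
    "LPI": "inositol glycerophospholipids",
}

_SATURATION_TERMS = {"SFA": "saturated species",
                     "MUFA": "monounsaturated species",
                     "PUFA": "polyunsaturated species"}


def build_ontology(panel: Iterable[ParsedLipid]) -> dict[str, set[str]]:
    """Derive a structure-based mini-ontology over a lipid panel.

    Each species is annotated with its subclass, category, headgroup,
    linkage, species-level saturation and curated cellular-component terms;
    the result maps term -> set of member raw names.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    ontology: dict[str, set[str]] = {}

    def add(term: str, name: str) -> None:
        ontology.setdefault(term, set()).add(name)

    for p in panel:
        add(SUBCLASS_FULL_NAMES[p.subclass], p.raw_name)
        add(p.category + "s", p.raw_name)
        hg = _HEADGROUP_TERMS.get(p.subclass)
        if hg:
            add(hg, p.raw_name)
        for term in _LINKAGE_TERMS.get(p.subclass, ()):
            add(term, p.raw_name)
        if p.linkage.startswith("lyso"):
            add("lysoglycerophospholipids", p.raw_name)
        _, species_class = classify_saturation(p)
        add(_SATURATION_TERMS[species_class], p.raw_name)
        for term in CELLULAR_COMPONENT_TERMS[p.subclass]:
            add(term, p.raw_name)
    return ontology


def write_ontology_tsv(ontology: Mapping[str, set[str]], path) -> None:
    """Export an ontology as two-column TSV (term, species)."""
    with open(path, "w") as fh:
        fh.write("term\tspecies\n")
        for term in sorted(ontology):
            for name in sorted(ontology[term]):
                fh.write(f"{term}\t{name}\n")


def load_reference_panel() -> list[str]:
    """Load the packaged 218-name serum reference panel.

    The panel is a reconstruction: it reproduces the published per-subclass
    composition, contains the individually reported species verbatim, and
    fills the remainder with generated, parseable names.
    """
    text = (resources.files("lwas") / "data" / "panel_218.txt").read_text()
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
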