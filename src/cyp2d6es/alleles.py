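"""Star-allele definition table and single-haplotype assignment.

The definition table ships as a versioned YAML config covering the ten star
alleles resolvable from the 12-SNP panel plus the two regulatory-only SNPs.
Matching semantics: a definition matches a phased gene copy when all of its
``core`` variants are present; among matching definitions the most specific
one wins, where specificity counts the observed variants the definition
explains (core plus known co-occurring ``extras``). *1 is the empty
definition and matches everything with specificity 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Mapping, Optional, Tuple

import yaml

from .types import (
    PANEL_RSIDS,
    AmbiguousDefinitionError,
    Haplotype,
    RegTriple,
)


@dataclass(frozen=True)
class StarAlleleDefinition:
    label: str
    core: Mapping[str, str]    # rsID -> required allele symbol
    extras: Mapping[str, str]  # rsID -> allele symbol that may co-occur
    base_es_model1: float
    gene_deletion: bool = False

    @property
    def n_defining(self) -> int:
        return len(self.core)


@dataclass(frozen=True)
class AlleleTable:
    """Parsed allele-definition config: SNP allele symbols + definitions."""

    version: int
    snp_alleles: Mapping[str, Tuple[str, str]]  # rsID -> (ref, var)
    definitions: Mapping[str, StarAlleleDefinition]

    def ref_allele(self, rsid: str) -> str:
        return self.snp_alleles[rsid][0]

    def var_allele(self, rsid: str) -> str:
        return self.snp_alleles[rsid][1]

    def allowed_symbols(self, rsid: str) -> Tuple[str, str]:
        return self.snp_alleles[rsid]

    def reference_calls(self) -> Dict[str, str]:
        """One reference allele per panel rsID (a plain *1-like gene copy)."""
        return {r: self.ref_allele(r) for r in PANEL_RSIDS}


def load_allele_table(path: Optional[str] = None) -> AlleleTable:
    """Load the allele-definition config (packaged defaults if no path)."""
    if path is None:
        text = (
            resources.files("cyp2d6es.data").joinpath("alleles.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)

    snp_alleles: Dict[str, Tuple[str, str]] = {}
    for rsid, spec in raw["snps"].items():
        if rsid not in PANEL_RSIDS:
            raise ValueError(f"config SNP {rsid} is not in the 12-SNP panel")
        snp_alleles[rsid] = (str(spec["ref"]), str(spec["var"]))
    missing = set(PANEL_RSIDS) - set(snp_alleles)
    if missing:
        raise ValueError(f"config missing panel SNPs: {sorted(missing)}")

    def _resolve(reqs: Mapping[str, str]) -> Dict[str, str]:
        out = {}
        for rsid, which in reqs.items():
            if rsid not in snp_alleles:
                raise ValueError(f"definition references non-panel SNP {rsid}")
            ref, var = snp_alleles[rsid]
            out[rsid] = var if which == "var" else ref
        return out

    defs: Dict[str, StarAlleleDefinition] = {}
    for label, spec in raw["alleles"].items():
        defs[label] = StarAlleleDefinition(
            label=label,
            core=_resolve(spec.get("core", {})),
            extras=_resolve(spec.get("extras", {})),
            base_es_model1=float(spec["base_es_model1"]),
            gene_deletion=bool(spec.get("gene_deletion", False)),
        )
    if "*1" not in defs or defs["*1"].core:
        raise ValueError("config must define *1 as the empty default")
    return AlleleTable(int(raw["version"]), snp_alleles, defs)


def reg_triple_from_alleles(
    phased: Mapping[str, str], table: AlleleTable
) -> RegTriple:
    """Read the regulatory triple straight off a phased allele map."""
    return RegTriple(
        rs16947=phased.get("rs16947") == table.var_allele("rs16947"),
        rs5758550=phased.get("rs5758550") == table.var_allele("rs5758550"),
        rs1058164_g=phased.get("rs1058164") == "G",
    )


def assign_star_allele(
    phased: Mapping[str, str],
    table: Optional[AlleleTable] = None,
) -> Tuple[str, RegTriple, int]:
    """Assign the star label for one phased gene copy.

    Parameters
    ----------
    phased
        Map of rsID -> single allele symbol for one chromosome. Missing
        rsIDs are treated as reference.
    table
        Allele-definition table (packaged defaults if omitted).

    Returns
    -------
    (star_label, reg_triple, n_unexplained)
        ``n_unexplained`` counts observed variant alleles not accounted for
        by the winning definition (0 for canonical haplotypes); the phasing
        engine uses it to penalise variant-stranding phase assignments.

    Raises
    ------
    AmbiguousDefinitionError
        If two definitions both match fully and neither explains a superset
        of the observed variants explained by the other.
    """
    if table is None:
        table = _default_table()

    observed_vars = {
        rsid
        for rsid, allele in phased.items()
        if rsid in table.snp_alleles and allele == table.var_allele(rsid)
    }

    matches = []  # (definition, explained variant set)
    for d in table.definitions.values():
        if d.gene_deletion:
            continue  # *5 is called from copy number, never from the panel
        if any(phased.get(r, table.ref_allele(r)) != a for r, a in d.core.items()):
            continue
        explained = set(d.core) | {
            r for r, a in d.extras.items() if phased.get(r) == a
        }
        matches.append((d, explained & observed_vars))

    # keep only maximal matches under set inclusion of explained variants
    maximal = [
        (d, ex)
        for d, ex in matches
        if not any(ex < ex2 for _, ex2 in matches)
    ]
    best_n = max(len(ex) for _, ex in maximal)
    top = [(d, ex) for d, ex in maximal if len(ex) == best_n]
    if len(top) > 1 and len({frozenset(ex) for _, ex in top}) > 1:
        raise AmbiguousDefinitionError(sorted(d.label for d, _ in top))
    # identical explained sets: parsimony then lexicographic tie-break
    d, explained = min(top, key=lambda t: (t[0].n_defining, t[0].label))
    reg = reg_triple_from_alleles(phased, table)
    n_unexplained = len(observed_vars - explained)
    return d.label, reg, n_unexplained


def validate_haplotype(h: Haplotype, table: Optional[AlleleTable] = None) -> None:
    """Check star-label / regulatory-triple consistency.

    Stars defined on the rs16947 backbone (*2, *17, *29, *41) must carry the
    rs16947 flag; *5 carries no flags.
    """
    if table is None:
        table = _default_table()
    if h.star not in table.definitions:
        raise ValueError(f"unknown star allele {h.star}")
    d = table.definitions[h.star]
    if "rs16947" in d.core and not h.reg.rs16947:
        raise ValueError(f"{h.star} requires the rs16947 variant flag")
    if h.star == "*5" and any(h.reg.as_tuple()):
        raise ValueError("*5 carries no regulatory flags")


_TABLE_CACHE: Optional[AlleleTable] = None


def _default_table() -> AlleleTable:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = load_allele_table()
    return _TABLE_CACHE
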