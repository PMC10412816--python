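"""Expression-score (ES) models for CYP2D6 haplotypes and diplotypes.

Three scoring rulesets map a haplotype (star label, regulatory triple,
tandem copy count) to a non-negative score whose diplotype sum predicts
full-length CYP2D6 protein:

* **Model 1** — the accepted activity-score standard: 0 for null alleles
  (*3, *4, *5, *6), 0.5 for the reduced-expression *41, 1 for everything
  else; gene duplication multiplies the allele score by the copy number.
* **Model 2** — scores non-null haplotypes by the rs16947/rs5758550
  (enhancer) pair instead of the star label: both present -> 1, rs16947
  alone -> 0.5, enhancer alone -> 2, neither -> 1. This applies to every
  rs16947-bearing allele (*2, *17, *29, *41), superseding model 1's 0.5
  for *41. Each extra tandem copy adds only half the base score
  (duplicated *1 -> 1.5, duplicated rs16947-only -> 0.75), reflecting the
  shared, non-duplicated downstream enhancer.
* **Model 3** — model 2 with a 50% reduction for haplotypes carrying the
  exon-3-skipping rs1058164 G allele (so a plain *1, which carries G,
  scores 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

from .alleles import AlleleTable, _default_table
from .types import (
    Diplotype,
    Haplotype,
    RegTriple,
    UnscorableHaplotypeError,
)

MODEL_IDS = (1, 2, 3)


@dataclass(frozen=True)
class EsModel:
    """One ES scoring ruleset.

    ``cnv_increment`` is the fraction of the base score added per extra
    tandem copy (1.0 reproduces model 1's full-copy scaling, 0.5 the
    enhancer-saturated scaling of models 2-3). ``g_multiplier`` is the
    per-haplotype factor applied when rs1058164 G is present (model 3).
    """

    model_id: int
    null_alleles: FrozenSet[str] = frozenset({"*3", "*4", "*5", "*6"})
    reduced_alleles_model1: FrozenSet[str] = frozenset({"*41"})
    use_reg_triple: bool = False
    cnv_increment: float = 1.0
    g_multiplier: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.g_multiplier <= 1.0):
            raise ValueError("g_multiplier must be in (0, 1]")


def get_model(model_id: int) -> EsModel:
    """The three frozen default rulesets."""
    if model_id == 1:
        return EsModel(1)
    if model_id == 2:
        return EsModel(2, use_reg_triple=True, cnv_increment=0.5)
    if model_id == 3:
        return EsModel(
            3, use_reg_triple=True, cnv_increment=0.5, g_multiplier=0.5
        )
    raise ValueError(f"unknown ES model {model_id!r}")


#: Model-2 base score by (rs16947, rs5758550) presence.
_REG_BASE = {
    (True, True): 1.0,
    (True, False): 0.5,
    (False, True): 2.0,
    (False, False): 1.0,
}


def haplotype_es(
    h: Haplotype, m: EsModel, table: Optional[AlleleTable] = None
) -> float:
    """Score one haplotype under one model.

    Copy-number scaling: model 1 multiplies the base by the copy count;
    models 2-3 use base * (1 + cnv_increment * (copies - 1)). The model-3
    G reduction applies once per haplotype, after copy scaling (tandem
    copies share the haplotype's rs1058164 allele).
    """
    if table is None:
        table = _default_table()
    if h.star == "*5" or h.copies == 0:
        if h.star != "*5":
            raise ValueError(f"zero copies only valid for *5, got {h.star}")
        return 0.0
    if h.star in m.null_alleles:
        return 0.0

    if not m.use_reg_triple:
        if h.star in m.reduced_alleles_model1:
            base = 0.5
        else:
            d = table.definitions.get(h.star)
            base = d.base_es_model1 if d is not None else 1.0
        return base * h.copies

    if h.reg is None:
        raise UnscorableHaplotypeError(
            f"{h.star}: regulatory triple required under model {m.model_id}"
        )
    base = _REG_BASE[(h.reg.rs16947, h.reg.rs5758550)]
    score = base * (1.0 + m.cnv_increment * (h.copies - 1))
    if h.reg.rs1058164_g:
        score *= m.g_multiplier
    return score


@dataclass(frozen=True)
class EsResult:
    per_haplotype: Tuple[float, float]
    diplotype_es: float


def diplotype_es(
    d: Diplotype, m: EsModel, table: Optional[AlleleTable] = None
) -> EsResult:
    """Sum of the two haplotype scores; refuses hybrid-flagged samples."""
    if d.hybrid_flag:
        raise UnscorableHaplotypeError(
            "hybrid-flagged diplotype: excluded from ES scoring"
        )
    s1 = haplotype_es(d.hap1, m, table)
    s2 = haplotype_es(d.hap2, m, table)
    return EsResult((s1, s2), s1 + s2)


def haplotype_universe(
    table: Optional[AlleleTable] = None,
    copies: Iterable[int] = (1, 2, 3),
) -> List[Haplotype]:
    """Every (star, consistent regulatory triple, copy count) combination.

    Regulatory triples are constrained by the definitions: rs16947-backbone
    stars carry the rs16947 flag, others do not; rs5758550 and rs1058164 G
    vary freely. *5 appears once with zero copies.
    """
    if table is None:
        table = _default_table()
    universe = [Haplotype("*5", RegTriple(False, False, False), 0)]
    for label, d in sorted(table.definitions.items()):
        if d.gene_deletion:
            continue
        flag_16947 = "rs16947" in d.core
        for enh in (False, True):
            for g in (False, True):
                for c in copies:
                    universe.append(
                        Haplotype(label, RegTriple(flag_16947, enh, g), c)
                    )
    return universe


def es_table(
    m: EsModel,
    universe: Optional[Iterable[Haplotype]] = None,
    table: Optional[AlleleTable] = None,
) -> Dict[Haplotype, float]:
    """Deterministic exhaustive haplotype -> score mapping."""
    if universe is None:
        universe = haplotype_universe(table)
    return {h: haplotype_es(h, m, table) for h in universe}
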