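"""Diplotype calling: in-silico phasing, CNV handling, exclusion filters.

The wet-lab workflow phases gene copies physically (single-gene long PCR);
here phasing is statistical: all phase-consistent haplotype pairs are
enumerated and ranked by the product of their population haplotype
frequencies, with a parsimony-first tie-break. Duplicated-haplotype
assignment compares observed allelic ratios of >2-copy samples with the
expected variant-signal fractions under each copy-split hypothesis,
normalised to the average heterozygote ratio of 2-copy samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .alleles import AlleleTable, assign_star_allele, _default_table
from .population import PopulationModel, parse_diplotype_label
from .types import (
    PANEL_RSIDS,
    CnvCall,
    Cyp2d6Error,
    Diplotype,
    Haplotype,
    InvalidGenotypeError,
    RegTriple,
    SnpPanelGenotype,
    UnassignableDuplicationError,
    deletion_haplotype,
)
from .util import round_half_up

#: Frequency penalty per variant allele not explained by any definition.
UNEXPLAINED_PENALTY = 1e-3

#: Exclusion reason codes.
REASON_HYBRID = "hybrid_gene"
REASON_NULL = "null_allele"
REASON_CNV = "copy_number_not_2"
REASON_DUP_NULL_41 = "duplicated_null_or_star41"
REASON_COPIES_GT4 = "copy_number_gt_4"
REASON_MISSING_REG = "missing_regulatory_genotype"


@dataclass(frozen=True)
class DiplotypeCall:
    """A ranked phasing candidate: diplotype plus its phased allele maps."""

    diplotype: Diplotype
    score: float
    hap1_alleles: Mapping[str, str] = field(default_factory=dict)
    hap2_alleles: Mapping[str, str] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.diplotype.label()


def detect_hybrid(cnv: CnvCall) -> bool:
    """Flag a possible CYP2D6/CYP2D7 hybrid from discordant CNV probes.

    True iff the intron-6 and exon-9 probe copy estimates disagree; a
    missing probe raises (the caller excludes such samples conservatively).
    """
    if cnv.probe_intron6 is None or cnv.probe_exon9 is None:
        raise Cyp2d6Error("indeterminate CNV: missing probe estimate")
    return cnv.probe_intron6 != cnv.probe_exon9


def _phase_assignments(het_sites: Sequence[str]):
    """Yield phase splits; the first het site is fixed to haplotype 1."""
    if not het_sites:
        yield {}
        return
    first, rest = het_sites[0], het_sites[1:]
    for bits in itertools.product((0, 1), repeat=len(rest)):
        yield {first: 0, **dict(zip(rest, bits))}


def infer_diplotype(
    g: SnpPanelGenotype,
    cnv: CnvCall,
    model: PopulationModel,
    table: Optional[AlleleTable] = None,
) -> List[DiplotypeCall]:
    """Enumerate phase-consistent diplotypes, ranked by frequency product.

    The top candidate is the call. Haplotype frequencies come from the
    population model (star-label marginals times regulatory-triple
    conditionals); variant alleles stranded outside any definition multiply
    a candidate's score by ``UNEXPLAINED_PENALTY`` each. Ties are broken
    parsimony-first (fewer defining variants in total), then
    lexicographically by star label.

    For >2-copy samples the returned copy split is the uniform default
    (extra copies on the first haplotype); refine it with
    :func:`assign_duplicated_haplotype`.
    """
    if table is None:
        table = _default_table()
    hybrid = detect_hybrid(cnv)
    total = cnv.probe_intron6 if not hybrid else min(
        cnv.probe_intron6, cnv.probe_exon9
    )

    if total == 0:
        d = Diplotype(deletion_haplotype(), deletion_haplotype(), hybrid_flag=hybrid)
        return [DiplotypeCall(d, 1.0)]

    calls = {r: tuple(sorted(pair)) for r, pair in g.calls.items()}
    het_sites = [r for r in PANEL_RSIDS if r in calls and calls[r][0] != calls[r][1]]
    missing = list(g.missing())

    if total == 1:
        if het_sites:
            raise InvalidGenotypeError(
                f"{g.sample_id}: heterozygous sites {het_sites} with a single "
                "gene copy"
            )
        phased = {r: calls[r][0] for r in calls}
        star, reg, n_unexp = assign_star_allele(phased, table)
        hap = Haplotype(star, reg, copies=1)
        d = Diplotype(hap, deletion_haplotype(), hybrid_flag=hybrid)
        score = model.haplotype_frequency(hap) * model.deletion_freq
        return [DiplotypeCall(d, score * UNEXPLAINED_PENALTY**n_unexp, phased, {})]

    candidates: Dict[Tuple, DiplotypeCall] = {}
    for assignment in _phase_assignments(het_sites):
        phased1, phased2 = {}, {}
        for r in calls:
            a, b = calls[r]
            if r in assignment and a != b:
                if assignment[r] == 0:
                    phased1[r], phased2[r] = a, b
                else:
                    phased1[r], phased2[r] = b, a
            else:
                phased1[r] = phased2[r] = a
        try:
            star1, reg1, u1 = assign_star_allele(phased1, table)
            star2, reg2, u2 = assign_star_allele(phased2, table)
        except Cyp2d6Error:
            continue
        extra = total - 2
        h1 = Haplotype(star1, reg1, copies=1 + max(extra, 0))
        h2 = Haplotype(star2, reg2, copies=1)
        score = (
            model.haplotype_frequency(Haplotype(star1, reg1, 1))
            * model.haplotype_frequency(Haplotype(star2, reg2, 1))
            * UNEXPLAINED_PENALTY ** (u1 + u2)
        )
        d = Diplotype(h1, h2, hybrid_flag=hybrid)
        key = frozenset([(star1, reg1, h1.copies), (star2, reg2, h2.copies)])
        if key not in candidates or score > candidates[key].score:
            candidates[key] = DiplotypeCall(d, score, phased1, phased2)

    if not candidates:
        raise InvalidGenotypeError(
            f"{g.sample_id}: no phase-consistent haplotype pair"
        )

    def sort_key(c: DiplotypeCall):
        n_def = sum(
            table.definitions[s].n_defining for s in c.diplotype.stars()
        )
        return (-c.score, n_def, tuple(sorted(c.diplotype.stars())))

    ranked = sorted(candidates.values(), key=sort_key)
    relevant = _missing_discriminators(ranked[0], missing, table)
    if relevant:
        top = replace(
            ranked[0],
            diplotype=replace(
                ranked[0].diplotype,
                ambiguous=f"missing genotypes {relevant} may affect the call",
            ),
        )
        ranked[0] = top
    return ranked


def _missing_discriminators(
    call: DiplotypeCall, missing: Sequence[str], table: AlleleTable
) -> List[str]:
    """Missing rsIDs whose genotype could upgrade a called haplotype.

    A missing site matters when it belongs to the core of some definition
    whose remaining core requirements are already met by one of the two
    phased haplotypes (e.g. rs28371725 missing on an rs16947-bearing copy:
    *2 vs *41 cannot be discriminated).
    """
    relevant = []
    for m in missing:
        for d in table.definitions.values():
            if m not in d.core:
                continue
            for phased in (call.hap1_alleles, call.hap2_alleles):
                if not phased:
                    continue
                others = {r: a for r, a in d.core.items() if r != m}
                if all(phased.get(r, table.ref_allele(r)) == a
                       for r, a in others.items()):
                    relevant.append(m)
                    break
            if m in relevant:
                break
    return relevant


def assign_duplicated_haplotype(
    call: DiplotypeCall,
    ratios: Mapping[str, float],
    reference_ratios: Optional[Mapping[str, float]] = None,
    table: Optional[AlleleTable] = None,
    on_unassignable: str = "hap1",
) -> DiplotypeCall:
    """Decide which haplotype of a >2-copy sample carries the extra copies.

    For every rsID heterozygous between the two haplotypes, the expected
    variant-signal fraction under a (k, n-k) copy split is k/n for k copies
    of the variant-bearing haplotype out of n total. Observed ratios are
    rescaled by the 2-copy heterozygote reference ratio (theoretical 0.5)
    and the split minimising the summed absolute deviation wins.

    2-copy calls pass through unchanged. With no discriminating
    heterozygous rsID the behaviour follows ``on_unassignable``: ``hap1`` /
    ``hap2`` attribute the extra copies by default, ``error`` raises
    :class:`UnassignableDuplicationError`.
    """
    if table is None:
        table = _default_table()
    d = call.diplotype
    n = d.total_copies
    if n <= 2:
        return call

    var_side: Dict[str, int] = {}
    for r in set(call.hap1_alleles) | set(call.hap2_alleles):
        v = table.var_allele(r)
        a1 = call.hap1_alleles.get(r, table.ref_allele(r)) == v
        a2 = call.hap2_alleles.get(r, table.ref_allele(r)) == v
        if a1 != a2:
            var_side[r] = 0 if a1 else 1
    usable = [r for r in var_side if r in ratios]

    splits = [(k, n - k) for k in range(1, n)]
    if not usable:
        if on_unassignable == "error":
            raise UnassignableDuplicationError(
                "no heterozygous rsID discriminates the duplicated haplotype"
            )
        split = (n - 1, 1) if on_unassignable == "hap1" else (1, n - 1)
        warn = "duplication unassignable: copies attributed by default"
    else:
        def cost(split):
            c = 0.0
            for r in usable:
                ref = (reference_ratios or {}).get(r, 0.5)
                obs = ratios[r] * (0.5 / ref) if ref > 0 else ratios[r]
                obs = min(max(obs, 0.0), 1.0)
                k = split[0] if var_side[r] == 0 else split[1]
                c += abs(obs - k / n)
            return c

        split = min(splits, key=cost)
        warn = None

    h1 = replace(d.hap1, copies=split[0])
    h2 = replace(d.hap2, copies=split[1])
    new_d = Diplotype(
        h1, h2, hybrid_flag=d.hybrid_flag,
        ambiguous=warn or d.ambiguous,
    )
    return replace(call, diplotype=new_d)


def mean_het_ratios(
    samples: Iterable[Tuple[SnpPanelGenotype, CnvCall]],
    min_het: int = 5,
) -> Dict[str, float]:
    """Per-rsID mean heterozygote allelic ratio from 2-copy samples.

    Falls back to the theoretical 0.5 for any rsID with fewer than
    ``min_het`` informative heterozygotes.
    """
    acc: Dict[str, List[float]] = {}
    for g, cnv in samples:
        if cnv.probe_intron6 != 2 or cnv.probe_exon9 != 2:
            continue
        for r, pair in g.calls.items():
            if pair[0] != pair[1] and r in cnv.allelic_ratio:
                acc.setdefault(r, []).append(cnv.allelic_ratio[r])
    return {
        r: (sum(v) / len(v) if len(v) >= min_het else 0.5)
        for r, v in acc.items()
    }


# ---------------------------------------------------------------------------
# Exclusion filters and frequency tables
# ---------------------------------------------------------------------------

ANALYSES = ("protein_snp_regression", "cnv_protein", "none")


def apply_exclusion_filters(
    cohort: Sequence[Tuple[str, Diplotype]],
    analysis: str = "none",
) -> Tuple[List[Tuple[str, Diplotype]], pd.DataFrame]:
    """Apply the per-analysis sample exclusions; return (retained, log).

    * ``protein_snp_regression``: keep only 2-copy samples free of null
      alleles (*3, *4, *6; *5 is caught by the copy-number rule).
    * ``cnv_protein``: drop samples with a duplicated *3/*4/*6 or *41
      haplotype, or more than 4 total copies.
    * ``none``: drop only hybrid-flagged samples.

    The log has one row per excluded sample with a machine-readable reason.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}")
    retained, log = [], []

    for sample_id, d in cohort:
        reason = None
        if d.hybrid_flag:
            reason = REASON_HYBRID
        elif analysis == "protein_snp_regression":
            if d.carries(("*3", "*4", "*6")):
                reason = REASON_NULL
            elif d.total_copies != 2:
                reason = REASON_CNV
        elif analysis == "cnv_protein":
            dup_bad = any(
                h.copies >= 2 and h.star in ("*3", "*4", "*6", "*41")
                for h in (d.hap1, d.hap2)
            )
            if dup_bad:
                reason = REASON_DUP_NULL_41
            elif d.total_copies > 4:
                reason = REASON_COPIES_GT4
        if reason is None:
            retained.append((sample_id, d))
        else:
            log.append({"sample_id": sample_id, "reason": reason,
                        "diplotype": d.label()})
    return retained, pd.DataFrame(log, columns=["sample_id", "reason", "diplotype"])


def diplotype_frequency_table(
    cohort: Sequence[Tuple[str, Diplotype, str]],
    by_population: bool = False,
) -> pd.DataFrame:
    """Count and percentage per diplotype label (half-up, 2 decimals).

    ``cohort`` rows are (sample_id, diplotype, population). Percentages are
    100 * count / group total; groups are combined plus AA/EA when
    ``by_population``.
    """
    if not len(cohort):
        raise ValueError("empty cohort")
    rows = pd.DataFrame(
        {
            "diplotype": [d.label() for _, d, _ in cohort],
            "population": [p for _, _, p in cohort],
        }
    )
    return frequency_table_from_counts(
        rows.groupby(["diplotype", "population"]).size().unstack(fill_value=0),
        by_population=by_population,
    )


def frequency_table_from_counts(
    counts: pd.DataFrame, by_population: bool = False
) -> pd.DataFrame:
    """Percentage table from per-population count columns.

    Accepts either the packaged cohort table (columns ``count_aa`` /
    ``count_ea``) or any diplotype-indexed frame with one count column per
    population. Group percentages use each group's own total; half-up
    rounding at 2 decimals matches the printed cohort table.
    """
    df = counts.copy()
    if "count_aa" in df.columns:
        df = df.rename(columns={"count_aa": "AA", "count_ea": "EA"})
    df = df.drop(columns=[c for c in ("count_combined",) if c in df.columns])
    pops = list(df.columns)
    df.insert(0, "combined", df.sum(axis=1))
    groups = ["combined"] + (pops if by_population else [])
    out = pd.DataFrame(index=df.index)
    for grp in groups:
        total = df[grp].sum()
        if total == 0:
            raise ValueError(f"empty group {grp}")
        out[f"count_{grp}"] = df[grp]
        out[f"pct_{grp}"] = [
            round_half_up(100.0 * c / total, 2) for c in df[grp]
        ]
    return out
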