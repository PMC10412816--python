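"""Diplotype calling: phasing vs the exhaustive oracle, CNV, exclusions."""

import itertools

import pandas as pd
import pytest

from cyp2d6es.alleles import assign_star_allele
from cyp2d6es.haplotypes import (
    REASON_DUP_NULL_41,
    REASON_NULL,
    UNEXPLAINED_PENALTY,
    apply_exclusion_filters,
    assign_duplicated_haplotype,
    detect_hybrid,
    diplotype_frequency_table,
    frequency_table_from_counts,
    infer_diplotype,
)
from cyp2d6es.population import (
    PopulationModel,
    load_cohort_diplotype_counts,
    canonical_diplotype,
)
from cyp2d6es.types import (
    PANEL_RSIDS,
    CnvCall,
    Cyp2d6Error,
    Haplotype,
    InvalidGenotypeError,
    SnpPanelGenotype,
)


# ---------------------------------------------------------------------------
# Hybrid detection
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("i6,e9,expected", [(2, 2, False), (3, 2, True),
                                            (1, 1, False), (0, 0, False)])
def test_detect_hybrid_concordance(i6, e9, expected):
    assert detect_hybrid(CnvCall(i6, e9)) is expected
    assert detect_hybrid(CnvCall(e9, i6)) is expected  # symmetric


def test_detect_hybrid_missing_probe_is_error():
    with pytest.raises(Cyp2d6Error):
        detect_hybrid(CnvCall(2, None))


# ---------------------------------------------------------------------------
# Phasing against the exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_top(g, model, table):
    """Independent oracle: score all 2^het phase assignments directly."""
    calls = {r: tuple(sorted(p)) for r, p in g.calls.items()}
    het = [r for r in PANEL_RSIDS if calls[r][0] != calls[r][1]]
    best = None
    for bits in itertools.product((0, 1), repeat=len(het)):
        p1, p2 = {}, {}
        for r in calls:
            a, b = calls[r]
            if r in het:
                i = het.index(r)
                p1[r], p2[r] = (a, b) if bits[i] == 0 else (b, a)
            else:
                p1[r] = p2[r] = a
        try:
            s1, r1, u1 = assign_star_allele(p1, table)
            s2, r2, u2 = assign_star_allele(p2, table)
        except Cyp2d6Error:
            continue  # e.g. two incomparable definitions on one copy
        score = (
            model.haplotype_frequency(Haplotype(s1, r1, 1))
            * model.haplotype_frequency(Haplotype(s2, r2, 1))
            * UNEXPLAINED_PENALTY ** (u1 + u2)
        )
        ndef = (
            table.definitions[s1].n_defining + table.definitions[s2].n_defining
        )
        key = (-score, ndef, tuple(sorted((s1, s2))))
        if best is None or key < best[0]:
            best = (key, frozenset([(s1, r1), (s2, r2)]), score)
    return best


def test_phasing_matches_oracle_on_all_two_het_genotypes(
    table, pop, make_genotype, cnv2
):
    """Top call equals brute-force enumeration for every <=2-het genotype."""
    var = {r: table.var_allele(r) for r in PANEL_RSIDS}
    ref = {r: table.ref_allele(r) for r in PANEL_RSIDS}
    site_sets = (
        [()]
        + [(r,) for r in PANEL_RSIDS]
        + list(itertools.combinations(PANEL_RSIDS, 2))
    )
    for sites in site_sets:
        overrides = {r: tuple(sorted((ref[r], var[r]))) for r in sites}
        g = make_genotype("S", **overrides)
        top = infer_diplotype(g, cnv2, pop, table)[0]
        key, hapset, score = brute_force_top(g, pop, table)
        got = frozenset(
            [(h.star, h.reg) for h in (top.diplotype.hap1, top.diplotype.hap2)]
        )
        assert got == hapset, f"sites={sites}: {got} != {hapset}"
        assert top.score == pytest.approx(score)


def test_phasing_matches_oracle_with_homvar_background(
    table, pop, make_genotype, cnv2
):
    """Same equivalence when non-het sites can be homozygous variant."""
    var = {r: table.var_allele(r) for r in PANEL_RSIDS}
    ref = {r: table.ref_allele(r) for r in PANEL_RSIDS}
    cases = [
        # *2/*2 background with one het site
        {"rs16947": (var["rs16947"],) * 2, "rs28371725": (ref["rs28371725"], var["rs28371725"])},
        # hom *4 with het *10 SNP
        {"rs3892097": (var["rs3892097"],) * 2, "rs1065852": (ref["rs1065852"], var["rs1065852"])},
        # hom rs1058164 G with het rs16947
        {"rs1058164": ("G", "G"), "rs16947": (ref["rs16947"], var["rs16947"])},
    ]
    for overrides in cases:
        g = make_genotype("S", **{k: tuple(sorted(v)) for k, v in overrides.items()})
        top = infer_diplotype(g, cnv2, pop, table)[0]
        _, hapset, score = brute_force_top(g, pop, table)
        got = frozenset(
            [(h.star, h.reg) for h in (top.diplotype.hap1, top.diplotype.hap2)]
        )
        assert got == hapset
        assert top.score == pytest.approx(score)


@pytest.mark.parametrize(
    "overrides, expected",
    [
        ({}, "*1/*1"),
        ({"rs16947": ("C", "T")}, "*1/*2"),
        ({"rs1065852": ("C", "T"), "rs3892097": ("A", "G"),
          "rs1058164": ("C", "G")}, "*1/*4"),
        ({"rs16947": ("C", "T"), "rs28371725": ("C", "T")}, "*1/*41"),
    ],
)
def test_phasing_worked_examples(make_genotype, pop, cnv2, overrides, expected):
    top = infer_diplotype(make_genotype("S", **overrides), cnv2, pop)[0]
    assert top.label == expected


def test_round_trip_star_assignment_on_top_call(table, pop, make_genotype, cnv2):
    """Re-assigning each phased haplotype reproduces the call's labels."""
    g = make_genotype(
        "S", rs16947=("C", "T"), rs28371706=("C", "T"), rs1058164=("C", "G")
    )
    top = infer_diplotype(g, cnv2, pop, table)[0]
    s1, _, _ = assign_star_allele(top.hap1_alleles, table)
    s2, _, _ = assign_star_allele(top.hap2_alleles, table)
    assert {s1, s2} == set(top.diplotype.stars())


def test_single_copy_with_het_site_is_invalid(make_genotype, pop):
    g = make_genotype("S", rs16947=("C", "T"))
    with pytest.raises(InvalidGenotypeError):
        infer_diplotype(g, CnvCall(1, 1), pop)


def test_deletion_calls_from_cnv_totals(make_genotype, pop):
    top = infer_diplotype(make_genotype("S"), CnvCall(1, 1), pop)[0]
    assert top.label == "*1/*5"
    assert top.diplotype.total_copies == 1
    top = infer_diplotype(make_genotype("S"), CnvCall(0, 0), pop)[0]
    assert top.label == "*5/*5"


def test_missing_discriminating_site_flags_ambiguity(table, pop, cnv2):
    calls = {r: (a, a) for r, a in table.reference_calls().items()}
    calls["rs16947"] = ("C", "T")
    del calls["rs28371725"]  # cannot distinguish *2 from *41
    g = SnpPanelGenotype("S", calls)
    top = infer_diplotype(g, cnv2, pop, table)[0]
    assert top.diplotype.ambiguous and "rs28371725" in top.diplotype.ambiguous


# ---------------------------------------------------------------------------
# Duplicated-haplotype assignment from allelic ratios
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ratio, dup_label", [(0.67, "*1/*2x2"),
                                              (0.33, "*1x2/*2")])
def test_duplication_follows_allelic_ratio(make_genotype, pop, ratio, dup_label):
    """With 3 copies, variant fraction 2/3 vs 1/3 picks the duplicated side."""
    g = make_genotype("S", rs16947=("C", "T"))
    cnv = CnvCall(3, 3, {"rs16947": ratio})
    top = infer_diplotype(g, cnv, pop)[0]
    refined = assign_duplicated_haplotype(top, cnv.allelic_ratio)
    assert refined.label == dup_label


def test_duplication_uses_reference_ratio_normalisation(make_genotype, pop):
    # probe bias: 2-copy hets average 0.6; an observed 0.4 rescales to ~1/3
    g = make_genotype("S", rs16947=("C", "T"))
    cnv = CnvCall(3, 3, {"rs16947": 0.4})
    top = infer_diplotype(g, cnv, pop)[0]
    refined = assign_duplicated_haplotype(
        top, cnv.allelic_ratio, reference_ratios={"rs16947": 0.6}
    )
    assert refined.label == "*1x2/*2"


def test_duplication_noop_on_two_copies(make_genotype, pop, cnv2):
    g = make_genotype("S", rs16947=("C", "T"))
    top = infer_diplotype(g, cnv2, pop)[0]
    assert assign_duplicated_haplotype(top, {}) is top


def test_unassignable_duplication_default_and_error(make_genotype, pop):
    g = make_genotype("S")  # *1/*1, no discriminating het
    cnv = CnvCall(3, 3)
    top = infer_diplotype(g, cnv, pop)[0]
    refined = assign_duplicated_haplotype(top, {})
    assert refined.diplotype.total_copies == 3
    assert "unassignable" in refined.diplotype.ambiguous
    from cyp2d6es.types import UnassignableDuplicationError

    with pytest.raises(UnassignableDuplicationError):
        assign_duplicated_haplotype(top, {}, on_unassignable="error")


# ---------------------------------------------------------------------------
# Exclusion filters
# ---------------------------------------------------------------------------

def _sample(pop, label, sid="S"):
    from cyp2d6es.population import parse_diplotype_label

    (s1, c1), (s2, c2) = parse_diplotype_label(label)
    return (sid, canonical_diplotype(s1, c1, s2, c2, pop))


def test_protein_regression_filter(pop):
    cohort = [
        _sample(pop, "*4/*10", "a"),   # null allele -> out
        _sample(pop, "*1/*1x2", "b"),  # 3 copies -> out
        _sample(pop, "*1/*41", "c"),   # retained
        _sample(pop, "*1/*5", "d"),    # 1 copy -> out
    ]
    retained, log = apply_exclusion_filters(cohort, "protein_snp_regression")
    assert [s for s, _ in retained] == ["c"]
    assert dict(zip(log.sample_id, log.reason))["a"] == REASON_NULL
    assert len(log) == 3


def test_cnv_protein_filter(pop):
    cohort = [
        _sample(pop, "*1/*1x2", "a"),   # duplicated normal -> retained
        _sample(pop, "*41/*4x2", "b"),  # duplicated null -> out
        _sample(pop, "*2x2/*2x2", "c"), # 4 copies -> retained
        _sample(pop, "*1x4/*2x5", "d"), # 9 copies -> out
        _sample(pop, "*1/*4", "e"),     # single null copy -> retained
    ]
    retained, log = apply_exclusion_filters(cohort, "cnv_protein")
    assert [s for s, _ in retained] == ["a", "c", "e"]
    assert dict(zip(log.sample_id, log.reason))["b"] == REASON_DUP_NULL_41


def test_unknown_analysis_label(pop):
    with pytest.raises(ValueError):
        apply_exclusion_filters([_sample(pop, "*1/*1")], "wat")


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------

def test_cohort_table_percentages_reproduce_printed_values():
    counts = load_cohort_diplotype_counts()
    ft = frequency_table_from_counts(counts, by_population=True)
    assert ft["count_combined"].sum() == 244
    assert ft["count_AA"].sum() == 123
    assert ft["count_EA"].sum() == 121
    assert ft.loc["*1/*1", "pct_combined"] == 10.25
    assert ft.loc["*1/*1", "pct_AA"] == 4.07
    assert ft.loc["*1/*1", "pct_EA"] == 16.53
    assert ft.loc["*1/*2", "pct_combined"] == 17.21


def test_percentages_sum_within_rounding_slack():
    """Each group's rounded percentages sum to 100 within half-up slack."""
    counts = load_cohort_diplotype_counts()
    ft = frequency_table_from_counts(counts, by_population=True)
    for grp in ("combined", "AA", "EA"):
        slack = 0.005 * (ft[f"pct_{grp}"] > 0).sum()
        assert abs(ft[f"pct_{grp}"].sum() - 100.0) <= slack


def test_single_sample_cohort_is_100_percent(pop):
    ft = diplotype_frequency_table([("a", _sample(pop, "*1/*2")[1], "EA")])
    assert ft["pct_combined"].tolist() == [100.0]


def test_empty_cohort_is_error():
    with pytest.raises(ValueError):
        diplotype_frequency_table([])
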