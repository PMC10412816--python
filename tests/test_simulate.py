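"""Synthetic-cohort generator: determinism, frequencies, LD, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from cyp2d6es.alleles import validate_haplotype
from cyp2d6es.haplotypes import detect_hybrid
from cyp2d6es.population import PopulationModel
from cyp2d6es.simulate import (
    EffectSizes,
    calibrate_de3_baseline,
    cohort_frame,
    dosages,
    protein_expectation,
    restrict_model,
    sample_cohort,
    simulate_protein,
    simulate_splice,
    write_fixture,
)
from cyp2d6es.types import CnvCall


def test_same_seed_byte_identical_fixtures(tmp_path, pop):
    eff = EffectSizes()
    outs = []
    for sub in ("a", "b"):
        cohort = sample_cohort(60, pop, seed=5)
        simulate_protein(cohort, eff, seed=6)
        simulate_splice(cohort, eff, seed=7, model=pop)
        paths = write_fixture(cohort, tmp_path / sub, seed=8)
        outs.append(paths)
    for key in outs[0]:
        assert outs[0][key].read_bytes() == outs[1][key].read_bytes()


def test_different_seed_changes_cohort(pop):
    a = sample_cohort(50, pop, seed=1)
    b = sample_cohort(50, pop, seed=2)
    assert [s.diplotype.label() for s in a] != [s.diplotype.label() for s in b]


def test_degenerate_one_diplotype_table(pop):
    m = pop.with_overrides(diplotype_freqs={"*1/*2": 1.0})
    cohort = sample_cohort(20, m, seed=3)
    assert {s.diplotype.label() for s in cohort} == {"*1/*2"}


def test_marginal_frequencies_converge(pop):
    """Law of large numbers: sampled star marginals match the table's."""
    cohort = sample_cohort(10_000, pop, seed=42)
    tallies = {}
    for s in cohort:
        for h in (s.diplotype.hap1, s.diplotype.hap2):
            tallies[h.star] = tallies.get(h.star, 0) + 1
    total = sum(tallies.values())
    expected = pop.star_frequencies()
    for star, f in expected.items():
        assert tallies.get(star, 0) / total == pytest.approx(f, abs=0.015)


def test_star1_count_near_table_expectation(pop):
    """Expected *1/*1 count in an n=244 cohort within the binomial 99% CI."""
    from scipy.stats import binom

    p = pop.diplotype_freqs["*1/*1"]
    lo, hi = binom.ppf([0.005, 0.995], 244, p)
    counts = []
    for seed in range(10):
        cohort = sample_cohort(244, pop, seed=seed)
        counts.append(
            sum(s.diplotype.label() == "*1/*1" for s in cohort)
        )
    assert lo <= np.mean(counts) <= hi


def test_ld_constraints_hold(pop):
    """rs16947/rs1058164-G near-exclusivity and hard star constraints."""
    cohort = sample_cohort(4000, pop, seed=9)
    n16947 = n_g16947 = 0
    for s in cohort:
        for h in (s.diplotype.hap1, s.diplotype.hap2):
            if h.star == "*5":
                continue
            validate_haplotype(h)  # no hard-constraint violations
            if h.star == "*1":
                assert h.reg.rs1058164_g  # every *1 carries G
            if h.reg.rs16947:
                n16947 += 1
                n_g16947 += h.reg.rs1058164_g
    assert n_g16947 / n16947 == pytest.approx(0.03, abs=0.015)


def test_cnv_probes_match_labels_and_hybrid_injection(pop):
    cohort = sample_cohort(200, pop, seed=21, hybrid_rate=0.2)
    n_hybrid = sum(s.diplotype.hybrid_flag for s in cohort)
    assert 10 <= n_hybrid <= 80
    import tempfile

    with tempfile.TemporaryDirectory() as td:
        paths = write_fixture(cohort, td, seed=22)
        geno = pd.read_csv(paths["genotypes"], sep="\t")
    for s, (_, row) in zip(cohort, geno.iterrows()):
        cnv = CnvCall(int(row.cnv_intron6), int(row.cnv_exon9))
        assert detect_hybrid(cnv) == s.diplotype.hybrid_flag
        if not s.diplotype.hybrid_flag:
            assert row.cnv_intron6 == s.diplotype.total_copies


def test_protein_noise_free_dosage_differences(pop):
    """In the sd->0 limit the enhancer adds exactly its beta per allele."""
    eff = EffectSizes()
    m = restrict_model(pop)
    cohort = sample_cohort(500, m, seed=33)
    df = cohort_frame(cohort)
    df["protein0"] = [
        protein_expectation(s.diplotype, eff) for s in cohort
    ]
    from cyp2d6es.assoc import ols_fit

    fit = ols_fit(df, "protein0", ["rs1058164G", "rs5758550", "rs16947"])
    assert fit.coef("rs5758550") == pytest.approx(72.3, abs=1e-8)
    assert fit.coef("rs16947") == pytest.approx(-44.5, abs=1e-8)
    assert fit.coef("rs1058164G") == pytest.approx(-41.8, abs=1e-8)
    assert fit.r_squared == pytest.approx(1.0)


def test_protein_all_reference_cohort_is_constant(pop):
    m = pop.with_overrides(diplotype_freqs={"*1/*1": 1.0})
    cohort = sample_cohort(20, m, seed=2)
    vals = [protein_expectation(s.diplotype, EffectSizes()) for s in cohort]
    assert len(set(vals)) == 1


def test_protein_truncation_logged(pop):
    eff = EffectSizes(protein_noise_sd=500.0)
    cohort = sample_cohort(200, pop, seed=4)
    vals, truncated = simulate_protein(cohort, eff, seed=5)
    assert truncated > 0
    assert (vals >= 0).all()


def test_sd_validation():
    with pytest.raises(ValueError):
        EffectSizes(protein_noise_sd=0.0)
    with pytest.raises(ValueError):
        EffectSizes(splice_noise_sd=-1.0)


def test_de3_baseline_calibration_hits_target_mean(pop):
    eff = EffectSizes()
    base = calibrate_de3_baseline(pop, eff)
    cohort = sample_cohort(8000, pop, seed=50)
    sp = simulate_splice(cohort, eff, seed=51, baseline=base)
    assert sp.deltaE3_fraction.mean() == pytest.approx(
        eff.dE3_mean_fraction, abs=0.02
    )


def test_de3_ratio_ordering_by_genotype(pop):
    """Geometric-mean deltaE3 ratio ordering GG > CG > CC."""
    cohort = sample_cohort(4000, pop, seed=60)
    sp = simulate_splice(cohort, EffectSizes(), seed=61, model=pop)
    df = cohort_frame(cohort)
    logr = np.log(sp.deltaE3_ratio.to_numpy())
    g = df["rs1058164G"].to_numpy()
    gm = {k: np.exp(logr[g == k].mean()) for k in (0, 1, 2)}
    assert gm[2] > gm[1] > gm[0]


def test_zero_effect_configuration_is_null(pop):
    eff = EffectSizes(
        dE3_log10_beta_rs1058164G=0.0,
        dE3_log10_beta_rs16947=0.0,
        dE3_log10_beta_rs3892097=0.0,
        frag_log10_beta_rs1058164G=0.0,
        frag_log10_beta_rs16947=0.0,
        frag_log10_beta_rs3892097=0.0,
    )
    from cyp2d6es.assoc import group_compare

    pvals = []
    for seed in range(40):
        cohort = sample_cohort(150, pop, seed=100 + seed)
        sp = simulate_splice(cohort, eff, seed=200 + seed, baseline=-0.6)
        df = cohort_frame(cohort)
        g = df["rs1058164G"].to_numpy()
        if len(set(g)) < 2 or min(np.bincount(g)) < 2:
            continue
        pvals.append(
            group_compare(np.log10(sp.deltaE3_ratio.to_numpy()), g)
        )
    # p-values roughly uniform under the null: mean near 0.5
    assert 0.3 < np.mean(pvals) < 0.7


def test_empty_restriction_error(pop):
    with pytest.raises(ValueError):
        restrict_model(pop.with_overrides(diplotype_freqs={"*4/*4": 1.0}))


def test_dosages_counting(pop):
    from cyp2d6es.population import canonical_diplotype

    d = canonical_diplotype("*1", 1, "*41", 1, pop)
    dos = dosages(d)
    assert dos["rs1058164G"] == 1  # only the *1 side carries G (modal)
    assert dos["rs16947"] == 1
    assert dos["rs28371725"] == 1
    d = canonical_diplotype("*1", 2, "*1", 1, pop)
    assert dosages(d)["rs1058164G"] == 2  # per side, not per tandem copy
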