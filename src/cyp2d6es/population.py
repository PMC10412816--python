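"""Population structure: cohort diplotype frequencies and regulatory-SNP LD.

The packaged diplotype table reproduces the published liver-cohort counts
(121 EA + 123 AA donors, 244 total; two AA samples are carried as an
explicit ``unlisted`` remainder row so group totals match the cohort size).
Haplotype-level frequencies for phasing and simulation are derived from the
star-label marginals of that table, combined with the cohort's LD
statements for the three regulatory SNPs:

* rs16947 T and rs1058164 G are nearly mutually exclusive (about 3% of
  rs16947-bearing haplotypes carry G); every *1 haplotype carries G.
* *41 sits on the enhancer-less H3 haplotype class always in EA and 81% of
  the time in AA; conversely 6.5% (EA) / 18.1% (AA) of H3 haplotypes lack
  the *41 SNP, which pins down the enhancer probability for the other
  rs16947-bearing stars (*2, *17, *29).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from .types import Diplotype, Haplotype, RegTriple, deletion_haplotype

POPULATIONS = ("combined", "AA", "EA")

#: Stars that sit on the rs16947 backbone.
RS16947_STARS = frozenset({"*2", "*17", "*29", "*41"})

_HAP_RE = re.compile(r"^(\*\d+)(?:x(\d+))?$")


def parse_diplotype_label(label: str) -> Tuple[Tuple[str, int], Tuple[str, int]]:
    """Parse ``*1/*2x2`` into ((star, copies), (star, copies))."""
    parts = label.replace(" ", "").replace("×", "x").split("/")
    if len(parts) != 2:
        raise ValueError(f"malformed diplotype label {label!r}")
    out = []
    for p in parts:
        m = _HAP_RE.match(p)
        if not m:
            raise ValueError(f"malformed haplotype label {p!r} in {label!r}")
        star, mult = m.group(1), int(m.group(2) or 1)
        out.append((star, 0 if star == "*5" else mult))
    return tuple(out)  # type: ignore[return-value]


def load_cohort_diplotype_counts(path: Optional[str] = None) -> pd.DataFrame:
    """Load the packaged liver-cohort diplotype counts.

    Returns a DataFrame indexed by diplotype label with columns
    ``count_aa``, ``count_ea``, ``count_combined``.
    """
    if path is None:
        src = resources.files("cyp2d6es.data").joinpath(
            "liver_cohort_diplotypes.tsv"
        )
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    df = df.set_index("diplotype")
    df["count_combined"] = df["count_aa"] + df["count_ea"]
    return df


def star_haplotype_frequencies(
    counts: pd.DataFrame, population: str = "combined"
) -> Dict[str, float]:
    """Star-label marginal haplotype frequencies implied by diplotype counts.

    Each diplotype contributes one chromosome per haplotype side regardless
    of tandem copy number. The ``unlisted`` placeholder row is skipped.
    """
    col = {"combined": "count_combined", "AA": "count_aa", "EA": "count_ea"}[
        population
    ]
    tallies: Dict[str, float] = {}
    total = 0
    for label, row in counts.iterrows():
        if label == "unlisted" or row[col] == 0:
            continue
        (s1, _), (s2, _) = parse_diplotype_label(str(label))
        tallies[s1] = tallies.get(s1, 0) + row[col]
        tallies[s2] = tallies.get(s2, 0) + row[col]
        total += 2 * row[col]
    return {s: c / total for s, c in sorted(tallies.items())}


@dataclass(frozen=True)
class PopulationModel:
    """Frequencies and LD constraints for one population.

    Parameters
    ----------
    population
        ``combined``, ``AA`` or ``EA``.
    diplotype_freqs
        Diplotype label -> probability (normalized cohort frequencies).
    deletion_freq
        Marginal *5 frequency (~5% in both populations).
    multicopy_freq
        Fraction of samples with >2 gene copies (EA 0.06, AA 0.20).
    reg_concordance
        P(rs1058164 G | haplotype carries rs16947 T) — the ~3% exception
        to the mutual-exclusivity rule.
    star41_on_H3
        P(no enhancer | *41 haplotype): EA 1.00, AA 0.81.
    h3_lacking_41
        Fraction of enhancer-less rs16947 (H3) haplotypes without the *41
        SNP: EA 0.065, AA 0.181. Used to back out the enhancer probability
        for non-*41 rs16947 stars.
    enhancer_on_non16947
        P(rs5758550 | haplotype without rs16947): none observed in the
        cohort, default 0.
    """

    population: str = "combined"
    diplotype_freqs: Mapping[str, float] = field(default_factory=dict)
    deletion_freq: float = 0.05
    multicopy_freq: float = 0.13
    reg_concordance: float = 0.03
    star41_on_H3: float = 0.905
    h3_lacking_41: float = 0.123
    enhancer_on_non16947: float = 0.0

    def __post_init__(self):
        for name in (
            "deletion_freq",
            "multicopy_freq",
            "reg_concordance",
            "star41_on_H3",
            "h3_lacking_41",
            "enhancer_on_non16947",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.diplotype_freqs:
            s = sum(self.diplotype_freqs.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"diplotype_freqs sum to {s}, not 1")

    # -- construction -------------------------------------------------

    @classmethod
    def from_cohort_table(
        cls,
        population: str = "combined",
        counts: Optional[pd.DataFrame] = None,
        **overrides,
    ) -> "PopulationModel":
        """Build the model for one population from the packaged cohort table."""
        if population not in POPULATIONS:
            raise ValueError(f"unknown population {population!r}")
        if counts is None:
            counts = load_cohort_diplotype_counts()
        col = {
            "combined": "count_combined",
            "AA": "count_aa",
            "EA": "count_ea",
        }[population]
        rows = counts[(counts.index != "unlisted") & (counts[col] > 0)]
        total = rows[col].sum()
        freqs = {str(k): v / total for k, v in rows[col].items()}
        params = dict(
            EA=dict(multicopy_freq=0.06, star41_on_H3=1.00, h3_lacking_41=0.065),
            AA=dict(multicopy_freq=0.20, star41_on_H3=0.81, h3_lacking_41=0.181),
            combined=dict(
                multicopy_freq=0.13, star41_on_H3=0.905, h3_lacking_41=0.123
            ),
        )[population]
        params.update(overrides)
        return cls(population=population, diplotype_freqs=freqs, **params)

    def with_overrides(self, **kw) -> "PopulationModel":
        return replace(self, **kw)

    # -- derived regulatory-triple probabilities ----------------------

    def star_frequencies(self) -> Dict[str, float]:
        """Star marginals implied by ``diplotype_freqs``."""
        tallies: Dict[str, float] = {}
        for label, f in self.diplotype_freqs.items():
            (s1, _), (s2, _) = parse_diplotype_label(label)
            tallies[s1] = tallies.get(s1, 0.0) + f / 2
            tallies[s2] = tallies.get(s2, 0.0) + f / 2
        return tallies

    def enhancer_prob_non41(self) -> float:
        """P(rs5758550 | rs16947-bearing haplotype that is not *41).

        Solved from the H3 composition constraint: with expected haplotype
        counts n41 (for *41) and nO (for *2/*17/*29), the fraction of H3
        haplotypes lacking *41 equals
        ``nO*(1-p) / (nO*(1-p) + n41*star41_on_H3)`` = ``h3_lacking_41``.
        """
        stars = self.star_frequencies()
        n41 = stars.get("*41", 0.0)
        n_other = sum(stars.get(s, 0.0) for s in ("*2", "*17", "*29"))
        h = self.h3_lacking_41
        if n_other <= 0 or h >= 1.0:
            return 0.0
        p_h3_other = h * n41 * self.star41_on_H3 / ((1.0 - h) * n_other)
        return float(min(1.0, max(0.0, 1.0 - p_h3_other)))

    def reg_probs(self, star: str) -> Dict[str, float]:
        """Per-star Bernoulli probabilities for the regulatory flags."""
        if star == "*5":
            return {"rs16947": 0.0, "rs5758550": 0.0, "rs1058164_g": 0.0}
        on_16947 = star in RS16947_STARS
        if star == "*41":
            p_enh = 1.0 - self.star41_on_H3
        elif on_16947:
            p_enh = self.enhancer_prob_non41()
        else:
            p_enh = self.enhancer_on_non16947
        p_g = (
            1.0
            if star == "*1"
            else (self.reg_concordance if on_16947 else 0.0)
        )
        return {
            "rs16947": 1.0 if on_16947 else 0.0,
            "rs5758550": p_enh,
            "rs1058164_g": p_g,
        }

    def haplotype_frequency(self, h: Haplotype) -> float:
        """Joint frequency of (star label, regulatory triple).

        Conditional flag probabilities are clamped away from 0 and 1 so the
        phasing prior never assigns zero mass to a triple unobserved in the
        cohort (hard constraints are enforced by validation, not the prior).
        """
        stars = self.star_frequencies()
        f = stars.get(h.star, 0.0)
        p = self.reg_probs(h.star)
        for flag, name in zip(
            h.reg.as_tuple(), ("rs16947", "rs5758550", "rs1058164_g")
        ):
            q = min(max(p[name], 0.01), 0.99)
            f *= q if flag else 1.0 - q
        return f


def canonical_diplotype(
    star1: str, copies1: int, star2: str, copies2: int, model: PopulationModel,
    rng=None,
) -> Diplotype:
    """Build a diplotype with deterministic (modal) regulatory triples.

    With ``rng`` given, regulatory flags are sampled from the population
    model instead of taking the most probable value.
    """
    def make(star, copies):
        if star == "*5":
            return deletion_haplotype()
        p = model.reg_probs(star)
        if rng is None:
            flags = {k: v >= 0.5 for k, v in p.items()}
        else:
            flags = {k: bool(rng.random() < v) for k, v in p.items()}
        return Haplotype(
            star,
            RegTriple(flags["rs16947"], flags["rs5758550"], flags["rs1058164_g"]),
            copies=copies,
        )

    return Diplotype(make(star1, copies1), make(star2, copies2))
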