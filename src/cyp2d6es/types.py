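"""Core value objects shared across the pipeline.

All types are small frozen dataclasses; validation that needs the allele
definition table lives in :mod:`cyp2d6es.alleles`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

#: The 12 genotyped panel SNPs, in panel (documentation) order.
PANEL_RSIDS: Tuple[str, ...] = (
    "rs1065852",   # *10
    "rs28371706",  # *17
    "rs5030655",   # *6
    "rs3892097",   # *4
    "rs35742686",  # *3
    "rs5030656",   # *9
    "rs16947",     # *2
    "rs1135840",   # *39
    "rs28371725",  # *41
    "rs59421388",  # *29
    "rs5758550",   # enhancer
    "rs1058164",   # exon-3 G/C
)

#: The three regulatory SNPs that form the 3-SNP haplotype.
REG_RSIDS: Tuple[str, str, str] = ("rs16947", "rs5758550", "rs1058164")

#: Star labels with no functional gene copy.
NULL_STARS = frozenset({"*3", "*4", "*5", "*6"})


class Cyp2d6Error(Exception):
    """Base class for all package errors."""


class InvalidGenotypeError(Cyp2d6Error):
    """No phase-consistent haplotype pair exists for a genotype."""


class AmbiguousDefinitionError(Cyp2d6Error):
    """Two star-allele definitions match fully and neither subsumes the other."""

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            "ambiguous star-allele match: " + ", ".join(self.candidates)
        )


class UnassignableDuplicationError(Cyp2d6Error):
    """A >2-copy sample has no heterozygous site discriminating its haplotypes."""


class UnscorableHaplotypeError(Cyp2d6Error):
    """A haplotype cannot be scored under the requested ES model."""


@dataclass(frozen=True)
class RegTriple:
    """Presence flags for the three regulatory SNPs on one haplotype.

    ``rs16947`` / ``rs5758550`` flag the variant allele; ``rs1058164_g``
    flags the G allele (carried by *1, promoting exon-3 skipping).
    """

    rs16947: bool
    rs5758550: bool
    rs1058164_g: bool

    def as_tuple(self) -> Tuple[bool, bool, bool]:
        return (self.rs16947, self.rs5758550, self.rs1058164_g)

    def __str__(self) -> str:  # e.g. "T-E-G" / "---"
        return "".join(
            sym if flag else "-"
            for sym, flag in zip("TEG", self.as_tuple())
        )


@dataclass(frozen=True)
class Haplotype:
    """One chromosome's CYP2D6 content: star label, regulatory triple, copies.

    ``copies`` counts tandem copies of this haplotype on one chromosome
    (1 for a normal gene, 2+ for duplications, 0 only for the *5 whole-gene
    deletion).
    """

    star: str
    reg: RegTriple
    copies: int = 1

    def __post_init__(self):
        if self.star == "*5":
            if self.copies != 0:
                raise ValueError("*5 (gene deletion) must carry copies=0")
        elif self.copies < 1:
            raise ValueError(f"{self.star} haplotype requires copies >= 1")

    @property
    def is_null(self) -> bool:
        return self.star in NULL_STARS

    def label(self) -> str:
        return self.star if self.copies <= 1 else f"{self.star}x{self.copies}"


#: The regulatory triple used for *5 (no gene, flags vacuously false).
DELETED_REG = RegTriple(False, False, False)


def deletion_haplotype() -> Haplotype:
    return Haplotype("*5", DELETED_REG, copies=0)


@dataclass(frozen=True)
class Diplotype:
    """An ordered pair of haplotypes plus total gene copy number."""

    hap1: Haplotype
    hap2: Haplotype
    hybrid_flag: bool = False
    ambiguous: Optional[str] = None  # warning text, if any

    @property
    def total_copies(self) -> int:
        return self.hap1.copies + self.hap2.copies

    def stars(self) -> Tuple[str, str]:
        return (self.hap1.star, self.hap2.star)

    def label(self) -> str:
        """Canonical label, e.g. ``*1/*2x2``; haplotypes sorted."""
        a, b = sorted(
            (self.hap1, self.hap2),
            key=lambda h: (_star_sort_key(h.star), h.copies),
        )
        return f"{a.label()}/{b.label()}"

    def carries(self, stars) -> bool:
        wanted = {stars} if isinstance(stars, str) else set(stars)
        return bool({self.hap1.star, self.hap2.star} & wanted)


def _star_sort_key(star: str):
    num = star.lstrip("*")
    try:
        return (0, int(num), star)
    except ValueError:
        return (1, 0, star)


@dataclass(frozen=True)
class SnpPanelGenotype:
    """Unphased biallelic calls for one sample over the 12-SNP panel.

    ``calls`` maps rsID to an unordered pair of allele symbols; an rsID may
    be absent (missing call). Symbols must come from the per-SNP allowed
    set in the allele-definition config.
    """

    sample_id: str
    calls: Mapping[str, Tuple[str, str]]

    def __post_init__(self):
        unknown = set(self.calls) - set(PANEL_RSIDS)
        if unknown:
            raise ValueError(f"unknown panel rsIDs: {sorted(unknown)}")
        for rsid, pair in self.calls.items():
            if len(pair) != 2:
                raise ValueError(f"{rsid}: call must have exactly 2 alleles")

    def missing(self) -> Tuple[str, ...]:
        return tuple(r for r in PANEL_RSIDS if r not in self.calls)


@dataclass(frozen=True)
class CnvCall:
    """TaqMan-style copy estimates from the intron-6 and exon-9 probes."""

    probe_intron6: Optional[int]
    probe_exon9: Optional[int]
    allelic_ratio: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for p in (self.probe_intron6, self.probe_exon9):
            if p is not None and p < 0:
                raise ValueError("copy estimates must be >= 0")
        for rsid, r in self.allelic_ratio.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"allelic ratio for {rsid} outside [0,1]")
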