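"""Splice-isoform quantification.

Covers the three measurement paths used for the exon-skipping isoforms
(the in-frame exon-3 deletion, 153 bp shorter, and the frameshifted
exon-6 skip): fragment-analysis peak areas, delta-Ct qPCR relative
quantities against a beta-actin reference, isoform/total ratios with their
log10 transform, and conversion of log10-scale regression coefficients to
fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .types import Cyp2d6Error
from .util import round_half_up

QPCR_ASSAYS = ("total_exon9", "deltaE3_specific", "exon6_junction")


class UndefinedMeasurementError(Cyp2d6Error):
    pass


@dataclass(frozen=True)
class FragmentPeaks:
    """Capillary-electrophoresis peak areas for one sample.

    ``area_full`` is the full-length amplicon signal; ``area_deltaE3`` the
    signal of the 153-bp-shorter exon-3-skipped amplicon.
    """

    area_full: float
    area_deltaE3: float

    def __post_init__(self):
        if self.area_full < 0 or self.area_deltaE3 < 0:
            raise ValueError("peak areas must be non-negative")


@dataclass(frozen=True)
class QpcrMeasurement:
    ct_target: float
    ct_reference: float
    assay_id: str = "total_exon9"

    def __post_init__(self):
        for ct in (self.ct_target, self.ct_reference):
            if not (0.0 < ct < 45.0):
                raise ValueError(f"Ct {ct} outside (0, 45)")
        if self.assay_id not in QPCR_ASSAYS:
            raise ValueError(f"unknown assay {self.assay_id!r}")


def deltaE3_fraction(p: FragmentPeaks) -> float:
    """Fraction of the exon-3-skipped isoform in the total transcript pool."""
    total = p.area_full + p.area_deltaE3
    if total <= 0:
        raise UndefinedMeasurementError("both peak areas are zero")
    return p.area_deltaE3 / total


def relative_quantity(
    m: QpcrMeasurement,
    efficiency: float = 2.0,
    ct_ceiling: float = 40.0,
) -> Tuple[float, bool]:
    """Reference-normalised relative expression, efficiency^-(dCt).

    Returns (quantity, below_detection); the flag is set when the target
    Ct is at or above the instrument ceiling (default 40 cycles).
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    below = m.ct_target >= ct_ceiling
    return efficiency ** -(m.ct_target - m.ct_reference), below


def isoform_ratio(isoform_q: float, total_q: float) -> Tuple[float, float]:
    """Isoform/total ratio and its log10 (for downstream regression).

    Raises on non-positive totals rather than imputing a pseudo-count;
    zero or undetected measurements are excluded upstream with a logged
    reason.
    """
    if total_q <= 0:
        raise UndefinedMeasurementError("total quantity must be positive")
    if isoform_q <= 0:
        raise UndefinedMeasurementError("isoform quantity must be positive")
    ratio = isoform_q / total_q
    return ratio, math.log10(ratio)


def fold_change_from_log10_coef(coef: float, ndigits: Optional[int] = 2) -> float:
    """10**coef, reported half-up at 2 decimals (pass ndigits=None for raw)."""
    if not math.isfinite(coef):
        raise ValueError("coefficient must be finite")
    fc = 10.0 ** coef
    return fc if ndigits is None else round_half_up(fc, ndigits)


@dataclass(frozen=True)
class IsoformProfile:
    """Per-sample isoform summary on the qPCR path."""

    total_cyp2d6: float
    deltaE3: float
    with_e6: float

    def __post_init__(self):
        for q in (self.total_cyp2d6, self.deltaE3, self.with_e6):
            if q <= 0:
                raise ValueError("quantities must be positive before log")

    @property
    def deltaE3_ratio(self) -> float:
        return isoform_ratio(self.deltaE3, self.total_cyp2d6)[0]

    @property
    def with_e6_ratio(self) -> float:
        return isoform_ratio(self.with_e6, self.total_cyp2d6)[0]

    @property
    def log10_deltaE3_ratio(self) -> float:
        return isoform_ratio(self.deltaE3, self.total_cyp2d6)[1]

    @property
    def log10_with_e6_ratio(self) -> float:
        return isoform_ratio(self.with_e6, self.total_cyp2d6)[1]
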