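"""Transformation/conjugation efficiency statistics and the false-positive correction.

Conjugation efficiency is the ratio of exconjugant colonies to the
estimated number of recipient *Streptomyces* CFU in the mating (estimated
by serial dilution).  Because antibiotic selection admits false positives
(satellite colonies, spontaneous resistance), a colony-PCR screen of
selected colonies yields a false-positive percentage, and the corrected
("true") efficiency down-weights the apparent one:

    true = apparent * (1 - FP/100)

False-positive percentages are *truncated* (not rounded) to two decimals —
6/11 reports as 54.54 %, not 54.55 % — and efficiencies are reported to
three significant figures.  All operations are pure and exact on rational
inputs up to those stated rounding rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .errors import StatsError

__all__ = [
    "PcrScreen",
    "EfficiencyResult",
    "transformation_efficiency",
    "conjugation_efficiency",
    "cfu_from_dilution",
    "false_positive_rate",
    "true_efficiency",
    "round_sig",
]


@dataclass(frozen=True)
class PcrScreen:
    """A colony-PCR screen: colonies tested and negatives among them."""

    n_tested: int
    n_negative: int

    def __post_init__(self) -> None:
        if self.n_tested <= 0:
            raise StatsError("screen", "n_tested must be > 0")
        if not (0 <= self.n_negative <= self.n_tested):
            raise StatsError("screen", "n_negative must be within 0..n_tested")


@dataclass(frozen=True)
class EfficiencyResult:
    """Apparent efficiency, false-positive %, and the corrected efficiency."""

    apparent: float
    fp_percent: float
    true_efficiency: float


def round_sig(x: float, sig: int = 3) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def transformation_efficiency(colonies: int, dna_ng: float, fraction_plated: float) -> float:
    """Heat-shock transformation efficiency in CFU per ug of plasmid DNA.

    ``fraction_plated`` is the share of the recovery culture spread on the
    plate; colonies are scaled back to the whole transformation.
    """
    if dna_ng <= 0:
        raise StatsError("dna", "dna_ng must be > 0")
    if not (0 < fraction_plated <= 1):
        raise StatsError("fraction", "fraction_plated must be in (0, 1]")
    if colonies < 0:
        raise StatsError("count", "colonies must be >= 0")
    return colonies / fraction_plated / (dna_ng / 1000.0)


def conjugation_efficiency(exconjugant_cfu: float, spore_cfu: float) -> float:
    """Apparent conjugation efficiency: exconjugant CFU per recipient CFU."""
    if spore_cfu <= 0:
        raise StatsError("spores", "spore_cfu must be > 0")
    if exconjugant_cfu < 0:
        raise StatsError("count", "exconjugant_cfu must be >= 0")
    return exconjugant_cfu / spore_cfu


def cfu_from_dilution(colony_count: float, dilution_factor: float, plated_volume_uL: float) -> float:
    """Back-calculate CFU/mL from a serial-dilution plate count."""
    if dilution_factor <= 0 or plated_volume_uL <= 0:
        raise StatsError("dilution", "dilution_factor and plated_volume_uL must be > 0")
    if colony_count < 0:
        raise StatsError("count", "colony_count must be >= 0")
    return colony_count * dilution_factor * (1000.0 / plated_volume_uL)


def false_positive_rate(screen: PcrScreen) -> float:
    """PCR false-positive percentage, truncated to two decimals.

    Truncation (floor at the second decimal) is the convention that makes
    6/11 report as 54.54 %.
    """
    frac = Fraction(100 * screen.n_negative, screen.n_tested)
    return math.floor(frac * 100) / 100.0


def true_efficiency(apparent: float, fp_percent: float) -> float:
    """Apparent efficiency corrected for false positives, to 3 significant figures."""
    if not (0 <= fp_percent <= 100):
        raise StatsError("fp", "fp_percent must be within 0..100")
    if apparent < 0:
        raise StatsError("count", "apparent efficiency must be >= 0")
    return round_sig(apparent * (1.0 - fp_percent / 100.0), 3)


def efficiency_result(
    exconjugant_cfu: float, spore_cfu: float, screen: PcrScreen
) -> EfficiencyResult:
    """Bundle the apparent efficiency, FP rate and corrected efficiency."""
    apparent = conjugation_efficiency(exconjugant_cfu, spore_cfu)
    fp = false_positive_rate(screen)
    return EfficiencyResult(
        apparent=apparent, fp_percent=fp, true_efficiency=true_efficiency(apparent, fp)
    )
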