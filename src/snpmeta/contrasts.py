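"""Genetic-model 2x2 tables and per-study odds ratios.

Five contrasts are derived from the genotype counts of each study (effect
allele M, other allele W):

========== =======================================
allele      M vs W, counted over alleles (2n per study)
heterozygous MW vs WW persons (MM excluded)
homozygous  MM vs WW persons (MW excluded)
dominant    MM+MW vs WW persons
recessive   MM vs MW+WW persons
========== =======================================

Per-study effects are Woolf log odds ratios with the Haldane-Anscombe 0.5
continuity correction applied to all four cells when any cell is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .study_data import StudyRecord

__all__ = ["GeneticModel", "TwoByTwo", "EffectEstimate", "build_table", "odds_ratio", "Z95"]

#: normal quantile for two-sided 95% confidence intervals
Z95 = 1.959964


class GeneticModel(str, Enum):
    ALLELE = "allele"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure 2x2 table: a/b case exposed/unexposed, c/d control likewise."""

    a: float
    b: float
    c: float
    d: float
    unit: str = "persons"          # "alleles" for the allele contrast
    corrected: bool = False
    study_id: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def is_degenerate(self) -> bool:
        """True when an exposure or outcome margin is empty (OR undefined)."""
        return (
            self.a + self.c == 0 or self.b + self.d == 0
            or self.a + self.b == 0 or self.c + self.d == 0
        )


@dataclass(frozen=True)
class EffectEstimate:
    log_or: float
    se: float
    study_id: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be positive")

    @property
    def or_(self) -> float:
        return float(np.exp(self.log_or))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.log_or - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.log_or + Z95 * self.se))


def build_table(record: StudyRecord, model: GeneticModel) -> TwoByTwo:
    """Build the contrast-specific 2x2 table for one study."""
    model = GeneticModel(model)
    ca, co = record.cases, record.controls
    if model is GeneticModel.ALLELE:
        return TwoByTwo(
            ca.effect_allele_count(), 2 * ca.total() - ca.effect_allele_count(),
            co.effect_allele_count(), 2 * co.total() - co.effect_allele_count(),
            unit="alleles", study_id=record.study_id,
        )
    if model is GeneticModel.HETEROZYGOUS:
        cells = (ca.het, ca.hom_other, co.het, co.hom_other)
    elif model is GeneticModel.HOMOZYGOUS:
        cells = (ca.hom_effect, ca.hom_other, co.hom_effect, co.hom_other)
    elif model is GeneticModel.DOMINANT:
        cells = (ca.hom_effect + ca.het, ca.hom_other, co.hom_effect + co.het, co.hom_other)
    else:  # recessive
        cells = (ca.hom_effect, ca.het + ca.hom_other, co.hom_effect, co.het + co.hom_other)
    return TwoByTwo(*cells, unit="persons", study_id=record.study_id)


def odds_ratio(table: TwoByTwo) -> EffectEstimate:
    """Woolf odds ratio with 0.5-if-any-zero continuity correction.

    Raises ``ValueError`` for degenerate tables (an empty exposure or outcome
    margin), for which no finite odds ratio exists even after correction.
    """
    if table.is_degenerate():
        raise ValueError(
            f"degenerate 2x2 table for {table.study_id or 'study'}: "
            f"({table.a}, {table.b}, {table.c}, {table.d})"
        )
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = float(np.log(a * d) - np.log(b * c))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return EffectEstimate(log_or=log_or, se=se, study_id=table.study_id)


def corrected_cells(table: TwoByTwo) -> tuple[float, float, float, float]:
    """Cells after the same correction policy odds_ratio applies."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d
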