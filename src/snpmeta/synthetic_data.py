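"""Synthetic case-control genotype-count study sets.

The generator emulates the structure of the real input table: for each study,
control genotypes are multinomial draws from Hardy-Weinberg proportions at a
chosen effect-allele frequency (optionally distorted by an inbreeding-style
coefficient F), and case genotypes follow the multiplicative per-allele odds
model -- the case probability of carrying g copies of the effect allele is
proportional to the control probability times exp(g * log OR). The study-level
true log OR is Normal(log or_allelic, tau2), so between-study heterogeneity is
tunable; tau2 = 0 gives a common-effect world. Sampling is count-conditioned
(fixed n per arm), mirroring case-control ascertainment.

A single integer seed fully determines a simulated set; per-study substreams
come from indexed spawning of the seed sequence, so study i is reproducible
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .study_data import (
    CONTROL_SOURCES,
    ETHNICITIES,
    PHENOTYPES,
    GenotypeCounts,
    StudyRecord,
    StudySet,
)

__all__ = ["SimScenario", "simulate_study", "simulate_set", "genotype_probs"]


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one synthetic study set.

    Defaults mimic the real rs1333049 panel: ~33 studies, control effect-allele
    frequency near 0.49, a modest per-allele effect, and per-arm sizes spanning
    small clinic series to multi-thousand population samples.
    """

    k: int = 33
    maf_control: float = 0.49
    or_allelic: float = 1.13
    tau2: float = 0.0
    n_case_range: tuple[int, int] = (50, 2500)
    n_ctrl_range: tuple[int, int] = (50, 2500)
    hwe_fis: float = 0.0
    variant: str = "rs1333049"
    ethnicity_probs: tuple[float, ...] = (0.25, 0.40, 0.30, 0.05)   # ETHNICITIES order
    source_probs: tuple[float, ...] = (0.45, 0.50, 0.05)            # CONTROL_SOURCES order
    phenotype_probs: tuple[float, ...] = (0.65, 0.35)               # PHENOTYPES order
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_control < 1.0:
            raise ValueError("maf_control must lie in (0, 1)")
        if self.or_allelic <= 0:
            raise ValueError("or_allelic must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if self.k < 1:
            raise ValueError("k must be at least 1")
        for name in ("n_case_range", "n_ctrl_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a positive non-empty range")
        for name in ("ethnicity_probs", "source_probs", "phenotype_probs"):
            p = np.asarray(getattr(self, name))
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{name} must be a probability vector")
        if min(_control_probs(self.maf_control, self.hwe_fis)) < 0:
            raise ValueError("hwe_fis produces negative genotype probabilities")


def _control_probs(p: float, fis: float) -> tuple[float, float, float]:
    q = 1.0 - p
    return (p * p + fis * p * q, 2 * p * q * (1 - fis), q * q + fis * p * q)


def genotype_probs(
    maf_control: float, log_or: float, hwe_fis: float = 0.0
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """(case, control) genotype probability triples, ordered
    (effect-hom, het, other-hom), under the multiplicative odds model."""
    ctrl = np.asarray(_control_probs(maf_control, hwe_fis))
    dose = np.array([2.0, 1.0, 0.0])
    case = ctrl * np.exp(dose * log_or)
    case = case / case.sum()
    return tuple(case), tuple(ctrl)


def _study_rng(seed: int, draw_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(draw_index + 1)[draw_index])


def simulate_study(scenario: SimScenario, draw_index: int) -> StudyRecord:
    """Simulate study number ``draw_index`` of the scenario (reproducible on
    its own: the substream depends only on (seed, draw_index))."""
    rng = _study_rng(scenario.seed, draw_index)
    true_log_or = rng.normal(np.log(scenario.or_allelic), np.sqrt(scenario.tau2))
    case_p, ctrl_p = genotype_probs(scenario.maf_control, true_log_or, scenario.hwe_fis)
    n_case = int(rng.integers(scenario.n_case_range[0], scenario.n_case_range[1] + 1))
    n_ctrl = int(rng.integers(scenario.n_ctrl_range[0], scenario.n_ctrl_range[1] + 1))
    case_counts = rng.multinomial(n_case, case_p)
    ctrl_counts = rng.multinomial(n_ctrl, ctrl_p)
    ethnicity = ETHNICITIES[rng.choice(len(ETHNICITIES), p=scenario.ethnicity_probs)]
    source = CONTROL_SOURCES[rng.choice(len(CONTROL_SOURCES), p=scenario.source_probs)]
    phenotype = PHENOTYPES[rng.choice(len(PHENOTYPES), p=scenario.phenotype_probs)]
    return StudyRecord(
        study_id=f"sim{draw_index:03d}_{scenario.variant}",
        author=f"Sim{draw_index:03d}",
        year=2020,
        origin="synthetic",
        variant=scenario.variant,
        phenotype=phenotype,
        ethnicity=ethnicity,
        control_source=source,
        cases=GenotypeCounts(*(int(c) for c in case_counts)),
        controls=GenotypeCounts(*(int(c) for c in ctrl_counts)),
        method="simulated",
    )


def simulate_set(scenario: SimScenario) -> StudySet:
    """Simulate the full k-study set; deterministic under a fixed seed."""
    records = tuple(simulate_study(scenario, i) for i in range(scenario.k))
    return StudySet(records, variant=scenario.variant)
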