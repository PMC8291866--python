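"""Heterogeneity assessment, fixed/random-effects pooling, stratification,
and leave-one-out sensitivity analysis.

The pooling rule mirrors standard meta-analytic practice for genotype-count
data: Cochran's Q is computed on the inverse-variance scale from the per-study
Woolf log odds ratios; when its p-value falls below ``alpha_het`` (default
0.05) the DerSimonian-Laird random-effects estimator is used, otherwise a
fixed-effects estimator (Mantel-Haenszel by default, inverse-variance
selectable). The Mantel-Haenszel standard error is the
Robins-Breslow-Greenland variance, which reduces exactly to the Woolf
variance for a single table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .contrasts import (
    EffectEstimate,
    GeneticModel,
    TwoByTwo,
    Z95,
    build_table,
    corrected_cells,
    odds_ratio,
)
from .genotype_stats import hwe_chisq
from .study_data import (
    CONTROL_SOURCES,
    ETHNICITIES,
    PHENOTYPES,
    StudyRecord,
    StudySet,
)

__all__ = [
    "HeterogeneityResult",
    "PooledResult",
    "StratificationPlan",
    "LeaveOneOutResult",
    "study_effects",
    "cochran_q",
    "pool_fixed_mh",
    "pool_fixed_iv",
    "pool_random_dl",
    "pool_auto",
    "stratify",
    "leave_one_out",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    p_q: float
    i2: float          # percent in [0, 100]
    tau2: float        # DerSimonian-Laird between-study variance (log-OR^2)


@dataclass(frozen=True)
class PooledResult:
    log_or: float
    se: float
    model_used: str                       # fixed_mh | fixed_iv | random_dl | single
    k: int
    het: Optional[HeterogeneityResult] = None
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    contrast: Optional[GeneticModel] = None
    stratum: str = ""

    @property
    def or_(self) -> float:
        return float(math.exp(self.log_or))

    @property
    def ci_low(self) -> float:
        return float(math.exp(self.log_or - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(math.exp(self.log_or + Z95 * self.se))

    @property
    def p_assoc(self) -> float:
        """Two-sided normal test of pooled log OR = 0."""
        return float(2 * stats.norm.sf(abs(self.log_or) / self.se))


@dataclass(frozen=True)
class StratificationPlan:
    """Which label partitions the studies: ethnicity, control_source,
    phenotype, or none (single overall stratum)."""

    by: str = "none"

    def __post_init__(self) -> None:
        if self.by not in ("ethnicity", "control_source", "phenotype", "none"):
            raise ValueError(f"unknown stratification variable {self.by!r}")

    def strata(self) -> tuple[str, ...]:
        return {
            "ethnicity": ETHNICITIES,
            "control_source": CONTROL_SOURCES,
            "phenotype": PHENOTYPES,
            "none": ("Total",),
        }[self.by]


@dataclass(frozen=True)
class LeaveOneOutResult:
    results: tuple[tuple[str, PooledResult], ...]
    full: PooledResult

    @property
    def significance_stable(self) -> bool:
        """True iff every re-pooled CI agrees with the full-set CI on
        whether the null value 1 is excluded."""
        def excludes_one(r: PooledResult) -> bool:
            return r.ci_low > 1.0 or r.ci_high < 1.0

        ref = excludes_one(self.full)
        return all(excludes_one(r) == ref for _, r in self.results)


def study_effects(
    studies: StudySet, model: GeneticModel
) -> tuple[list[EffectEstimate], list[TwoByTwo]]:
    """Per-study effects and tables for one contrast.

    Studies whose table is degenerate for this contrast (an all-zero margin)
    are excluded with a warning; no such study exists in the packaged data.
    """
    effects: list[EffectEstimate] = []
    tables: list[TwoByTwo] = []
    for record in studies:
        table = build_table(record, model)
        if table.is_degenerate():
            warnings.warn(
                f"{record.study_id}: degenerate {GeneticModel(model).value} table, "
                "excluded from this contrast"
            )
            continue
        tables.append(table)
        effects.append(odds_ratio(table))
    return effects, tables


def cochran_q(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q on inverse-variance weights, with DL tau^2 and I^2."""
    k = len(effects)
    if k < 2:
        raise ValueError(f"heterogeneity needs at least 2 studies, got {k}")
    theta = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    theta_iv = float((w * theta).sum() / w.sum())
    q = float((w * (theta - theta_iv) ** 2).sum())
    df = k - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p_q=p_q, i2=i2, tau2=tau2)


def _persons(tables: Sequence[TwoByTwo]) -> tuple[int, int]:
    scale = 2 if tables and tables[0].unit == "alleles" else 1
    n_cases = round(sum((t.a + t.b) for t in tables) / scale)
    n_controls = round(sum((t.c + t.d) for t in tables) / scale)
    return n_cases, n_controls


def pool_fixed_mh(
    tables: Sequence[TwoByTwo], het: Optional[HeterogeneityResult] = None
) -> PooledResult:
    """Mantel-Haenszel pooled odds ratio with Robins-Breslow-Greenland SE.

    The MH estimator itself tolerates single zero cells, so uncorrected
    cells are used unless a table has a zero that would zero out both the
    R and S sums (then the 0.5 policy applies to that table).
    """
    if not tables:
        raise ValueError("no tables to pool")
    usable = [t for t in tables if not t.is_degenerate()]
    if not usable:
        raise ValueError("all tables degenerate; Mantel-Haenszel OR non-estimable")
    R = S = sPR = sPS_QR = sQS = 0.0
    for t in usable:
        a, b, c, d = t.a, t.b, t.c, t.d
        n = a + b + c + d
        P, Q = (a + d) / n, (b + c) / n
        Ri, Si = a * d / n, b * c / n
        R += Ri
        S += Si
        sPR += P * Ri
        sPS_QR += P * Si + Q * Ri
        sQS += Q * Si
    if R == 0 or S == 0:
        # every usable table has the same zero cell pattern; fall back to
        # corrected cells so the estimate stays finite
        R = S = sPR = sPS_QR = sQS = 0.0
        for t in usable:
            a, b, c, d = corrected_cells(t)
            n = a + b + c + d
            P, Q = (a + d) / n, (b + c) / n
            Ri, Si = a * d / n, b * c / n
            R += Ri
            S += Si
            sPR += P * Ri
            sPS_QR += P * Si + Q * Ri
            sQS += Q * Si
    log_or = math.log(R / S)
    var = sPR / (2 * R * R) + sPS_QR / (2 * R * S) + sQS / (2 * S * S)
    n_cases, n_controls = _persons(usable)
    return PooledResult(
        log_or=log_or, se=math.sqrt(var), model_used="fixed_mh",
        k=len(usable), het=het, n_cases=n_cases, n_controls=n_controls,
    )


def _iv_pool(effects: Sequence[EffectEstimate], tau2: float) -> tuple[float, float]:
    theta = np.array([e.log_or for e in effects])
    w = 1.0 / (np.array([e.se for e in effects]) ** 2 + tau2)
    return float((w * theta).sum() / w.sum()), float(1.0 / math.sqrt(w.sum()))


def pool_fixed_iv(
    effects: Sequence[EffectEstimate], het: Optional[HeterogeneityResult] = None
) -> PooledResult:
    """Inverse-variance fixed-effect pooled log odds ratio."""
    if not effects:
        raise ValueError("no effects to pool")
    log_or, se = _iv_pool(effects, 0.0)
    return PooledResult(log_or=log_or, se=se, model_used="fixed_iv",
                        k=len(effects), het=het)


def pool_random_dl(
    effects: Sequence[EffectEstimate], het: Optional[HeterogeneityResult] = None
) -> PooledResult:
    """DerSimonian-Laird random-effects pooled log odds ratio.

    tau^2 comes from the supplied heterogeneity result (or is computed here);
    with tau^2 = 0 this is identical to the inverse-variance fixed pool.
    """
    if not effects:
        raise ValueError("no effects to pool")
    if het is None:
        het = cochran_q(effects) if len(effects) >= 2 else None
    tau2 = het.tau2 if het is not None else 0.0
    log_or, se = _iv_pool(effects, tau2)
    return PooledResult(log_or=log_or, se=se, model_used="random_dl",
                        k=len(effects), het=het)


def _with_context(r: PooledResult, studies: StudySet, model: GeneticModel,
                  stratum: str = "") -> PooledResult:
    n_cases = sum(rec.cases.total() for rec in studies)
    n_controls = sum(rec.controls.total() for rec in studies)
    return PooledResult(
        log_or=r.log_or, se=r.se, model_used=r.model_used, k=r.k, het=r.het,
        n_cases=n_cases, n_controls=n_controls,
        contrast=GeneticModel(model), stratum=stratum,
    )


def pool_auto(
    studies: StudySet,
    model: GeneticModel,
    alpha_het: float = 0.05,
    fixed: str = "mh",
    exclude_hwe_violations: bool = False,
    hwe_alpha: float = 0.05,
) -> PooledResult:
    """Pool one contrast with the heterogeneity-driven model choice.

    Random-effects (DerSimonian-Laird) is selected when the Q-test p-value is
    below ``alpha_het``; otherwise the fixed-effects estimator named by
    ``fixed`` ("mh" or "iv"). ``exclude_hwe_violations`` optionally drops
    studies whose control arm fails the HWE chi-square at ``hwe_alpha``
    (retained by default: the published analysis keeps them).
    """
    if fixed not in ("mh", "iv"):
        raise ValueError(f"fixed must be 'mh' or 'iv', got {fixed!r}")
    if exclude_hwe_violations:
        keep = tuple(
            r for r in studies if hwe_chisq(r.controls).p_chisq >= hwe_alpha
        )
        studies = StudySet(keep, variant=studies.variant)
    if len(studies) < 2:
        raise ValueError(f"pool_auto needs at least 2 studies, got {len(studies)}")
    effects, tables = study_effects(studies, model)
    if len(effects) < 2:
        raise ValueError("fewer than 2 estimable studies for this contrast")
    het = cochran_q(effects)
    if het.p_q < alpha_het:
        pooled = pool_random_dl(effects, het=het)
    elif fixed == "mh":
        pooled = pool_fixed_mh(tables, het=het)
    else:
        pooled = pool_fixed_iv(effects, het=het)
    return _with_context(pooled, studies, model)


def _single_study_result(record: StudyRecord, model: GeneticModel,
                         stratum: str) -> PooledResult:
    effect = odds_ratio(build_table(record, model))
    return PooledResult(
        log_or=effect.log_or, se=effect.se, model_used="single", k=1,
        n_cases=record.cases.total(), n_controls=record.controls.total(),
        contrast=GeneticModel(model), stratum=stratum,
    )


def stratify(
    studies: StudySet,
    plan: StratificationPlan,
    model: GeneticModel,
    **pool_kwargs,
) -> dict[str, PooledResult]:
    """Pooled results per stratum of the plan (insertion-ordered, only
    non-empty strata). Single-study strata carry that study's own estimate
    with ``model_used='single'`` and ``k=1``."""
    out: dict[str, PooledResult] = {}
    for stratum in plan.strata():
        subset = studies if plan.by == "none" else studies.filter(**{plan.by: stratum})
        if len(subset) == 0:
            continue
        if len(subset) == 1:
            out[stratum] = _single_study_result(subset[0], model, stratum)
        else:
            r = pool_auto(subset, model, **pool_kwargs)
            out[stratum] = _with_context(r, subset, model, stratum)
    return out


def leave_one_out(
    studies: StudySet, model: GeneticModel, **pool_kwargs
) -> LeaveOneOutResult:
    """Re-pool with each study omitted in turn (auto model choice each time)."""
    if len(studies) < 3:
        raise ValueError(f"leave-one-out needs at least 3 studies, got {len(studies)}")
    full = pool_auto(studies, model, **pool_kwargs)
    results = tuple(
        (r.study_id, pool_auto(studies.drop(r.study_id), model, **pool_kwargs))
        for r in studies
    )
    return LeaveOneOutResult(results=results, full=full)
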