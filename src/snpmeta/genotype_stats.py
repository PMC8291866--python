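"""Hardy-Weinberg equilibrium tests and pooled allele-frequency summaries.

Control-arm HWE is the standard genotyping-quality screen in case-control
association work: under random mating the genotype proportions at a biallelic
locus are (p**2, 2pq, q**2) for allele frequency p. Two tests are provided:

* :func:`hwe_chisq` -- the 1-df goodness-of-fit chi-square against expected
  counts computed from the sample allele frequency, without continuity
  correction (this reproduces the published per-study HWE column).
* :func:`hwe_exact` -- the exact conditional test that enumerates every
  heterozygote count compatible with the observed allele counts and sums the
  probabilities of configurations no more probable than the observed one
  (the Wigginton/Cutler/Abecasis formulation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .study_data import GenotypeCounts, StudySet

__all__ = ["HweResult", "AlleleFrequency", "hwe_chisq", "hwe_exact", "pooled_allele_freq"]


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p_chisq: float
    expected: tuple[float, float, float]
    p_exact: Optional[float] = None
    monomorphic: bool = False

    @property
    def p(self) -> float:
        """p-value of whichever test produced this result (exact if present)."""
        return self.p_exact if self.p_exact is not None else self.p_chisq


@dataclass(frozen=True)
class AlleleFrequency:
    effect_count: int
    total_alleles: int

    @property
    def freq(self) -> float:
        return self.effect_count / self.total_alleles


def _expected_counts(g: GenotypeCounts) -> tuple[float, tuple[float, float, float]]:
    n = g.total()
    p = g.effect_allele_count() / (2 * n)
    return p, (p * p * n, 2 * p * (1 - p) * n, (1 - p) * (1 - p) * n)


def hwe_chisq(g: GenotypeCounts) -> HweResult:
    """1-df chi-square goodness-of-fit test of HWE for one arm's counts."""
    n = g.total()
    if n == 0:
        raise ValueError("cannot test HWE on an empty arm")
    p, expected = _expected_counts(g)
    if p in (0.0, 1.0):
        return HweResult(0.0, 1, 1.0, expected, monomorphic=True)
    obs = np.asarray(g.as_tuple(), dtype=float)
    exp = np.asarray(expected)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return HweResult(chi2, 1, float(stats.chi2.sf(chi2, 1)), expected)


def hwe_exact(g: GenotypeCounts) -> HweResult:
    """Exact conditional HWE test (sum of probabilities <= observed's).

    Conditions on the observed allele counts; the heterozygote count ranges
    over all values with the observed parity. Probabilities are computed in
    log space so large arms stay stable.
    """
    n = g.total()
    if n == 0:
        raise ValueError("cannot test HWE on an empty arm")
    p, expected = _expected_counts(g)
    chisq = hwe_chisq(g)
    if p in (0.0, 1.0):
        return HweResult(0.0, 1, 1.0, expected, p_exact=1.0, monomorphic=True)

    n_eff = g.effect_allele_count()        # rarer-vs-commoner symmetry is automatic
    n_oth = 2 * n - n_eff
    n_minor = min(n_eff, n_oth)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # P(het | n, n_eff) = n! / (hom_eff! het! hom_oth!) * 2^het * n_eff! n_oth! / (2n)!
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hom_minor + 1) - gammaln(hets + 1) - gammaln(hom_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_eff + 1) + gammaln(n_oth + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed_het = g.het
    p_obs = probs[hets == observed_het][0]
    p_exact = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return HweResult(chisq.chi2, 1, chisq.p_chisq, expected, p_exact=min(1.0, p_exact))


def pooled_allele_freq(studies: StudySet, arm: str) -> AlleleFrequency:
    """Effect-allele frequency from allele counts summed over all studies' arm.

    ``arm`` is ``"cases"`` or ``"controls"``. This is the count-level pooled
    frequency, not a mean of per-study frequencies.
    """
    if arm not in ("cases", "controls"):
        raise ValueError(f"arm must be 'cases' or 'controls', got {arm!r}")
    if len(studies) == 0:
        raise ValueError("cannot compute pooled allele frequency of an empty study set")
    variants = {r.variant for r in studies}
    if len(variants) > 1:
        raise ValueError(f"study set mixes variants: {sorted(variants)}")
    effect = sum(getattr(r, arm).effect_allele_count() for r in studies)
    total = sum(2 * getattr(r, arm).total() for r in studies)
    return AlleleFrequency(effect, total)
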