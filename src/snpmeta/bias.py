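"""Publication-bias assessment: Begg-Mazumdar rank correlation and
funnel-plot coordinates.

The Begg-Mazumdar test rank-correlates variance-standardized effect
deviations with the effect variances: with the inverse-variance pooled mean
removed, each deviation is divided by the square root of its variance minus
the pooled-mean variance, and the Kendall score between these standardized
deviations and the raw variances is referred to the exact null variance
k(k-1)(2k+5)/18 with a continuity correction. A significant positive
correlation is the classic small-study asymmetry signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .contrasts import EffectEstimate, Z95

__all__ = ["BeggResult", "FunnelPoint", "FunnelData", "begg_test", "funnel_data"]


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    score: int          # concordant minus discordant pairs
    z: float
    p: float
    k: int


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    x: float            # log OR
    y: float            # SE of log OR (conventionally plotted inverted)


@dataclass(frozen=True)
class FunnelData:
    points: tuple[FunnelPoint, ...]
    center: Optional[float] = None      # pooled log OR
    #: (se, lower, upper) pseudo 95% guide lines over the observed SE range
    guides: tuple[tuple[float, float, float], ...] = ()


def kendall_score(x: Sequence[float], y: Sequence[float]) -> int:
    """Kendall score sum_{i<j} sign((x_j-x_i)(y_j-y_i)); ties contribute 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    return int(np.triu(dx * dy, k=1).sum())


def begg_test(effects: Sequence[EffectEstimate]) -> BeggResult:
    """Begg-Mazumdar rank-correlation test for small-study effects."""
    k = len(effects)
    if k < 3:
        raise ValueError(f"Begg's test needs at least 3 studies, got {k}")
    theta = np.array([e.log_or for e in effects])
    v = np.array([e.se**2 for e in effects])
    w = 1.0 / v
    theta_bar = float((w * theta).sum() / w.sum())
    v_star = v - 1.0 / w.sum()
    # v_star is strictly positive unless one study carries all the weight
    v_star = np.maximum(v_star, np.finfo(float).tiny)
    t = (theta - theta_bar) / np.sqrt(v_star)
    score = kendall_score(t, v)
    n_pairs = k * (k - 1) // 2
    tau = score / n_pairs
    var = k * (k - 1) * (2 * k + 5) / 18.0
    z = max(0.0, (abs(score) - 1.0)) / math.sqrt(var)
    p = float(2 * stats.norm.sf(z))
    return BeggResult(kendall_tau=tau, score=score, z=z, p=min(1.0, p), k=k)


def funnel_data(effects: Sequence[EffectEstimate], n_guide: int = 25) -> FunnelData:
    """Plot-ready funnel coordinates: one point per study plus the pooled
    center line and 95% pseudo-confidence guides over the SE range."""
    points = tuple(
        FunnelPoint(study_id=e.study_id, x=e.log_or, y=e.se) for e in effects
    )
    if not effects:
        return FunnelData(points=points)
    w = np.array([1.0 / e.se**2 for e in effects])
    theta = np.array([e.log_or for e in effects])
    center = float((w * theta).sum() / w.sum())
    ses = np.linspace(0.0, max(e.se for e in effects), n_guide)
    guides = tuple(
        (float(s), center - Z95 * float(s), center + Z95 * float(s)) for s in ses
    )
    return FunnelData(points=points, center=center, guides=guides)
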