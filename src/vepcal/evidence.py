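"""ACMG/AMP Bayesian evidence engine.

Converts likelihood ratios and posterior probabilities of pathogenicity into
evidence points on the additive ACMG/AMP point scale. An :class:`EvidenceScale`
is a pure function of the prior probability of pathogenicity: the very-strong
odds constant ``C`` is solved so that the posterior at the minimal Pathogenic
point total equals a target posterior (0.99 by default), point-level LR
thresholds scale exponentially as ``LR_x = C**(x/8)``, and ``LR1 = C**(1/8)``
is the +1 (supporting) threshold used to express log-LRs in evidence points.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EvidenceScale",
    "EvidencePoints",
    "ClassificationResult",
    "posterior_from_lr",
    "lr_from_posterior",
    "build_evidence_scale",
    "evidence_points",
    "continuous_points",
    "score_intervals",
    "classify_from_points",
    "TIER_PATHOGENIC",
    "TIER_LIKELY_PATHOGENIC",
    "TIER_VUS",
    "TIER_LIKELY_BENIGN",
    "TIER_BENIGN",
]

#: clamp applied to posteriors before odds conversion
EPS = 1e-9

TIER_PATHOGENIC = "Pathogenic"
TIER_LIKELY_PATHOGENIC = "Likely pathogenic"
TIER_VUS = "VUS"
TIER_LIKELY_BENIGN = "Likely benign"
TIER_BENIGN = "Benign"

POINT_LEVELS = (-4, -3, -2, -1, 1, 2, 3, 4)


def posterior_from_lr(lr, prior):
    """Posterior probability of pathogenicity from a likelihood ratio.

    ``post = a*LR / (a*LR + 1 - a)`` with prior ``a``. Vectorized over ``lr``.
    """
    lr = np.asarray(lr, dtype=float)
    if np.any(~np.isfinite(lr) & ~np.isposinf(lr)) or np.any(lr <= 0):
        raise ValueError("lr must be positive (or +inf)")
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0, 1)")
    with np.errstate(invalid="ignore"):
        out = np.where(
            np.isposinf(lr), 1.0, prior * lr / (prior * lr + (1.0 - prior))
        )
    return float(out) if out.ndim == 0 else out


def lr_from_posterior(post, prior, clamp=True):
    """Likelihood ratio implied by a posterior at a given prior.

    Exact inverse of :func:`posterior_from_lr`. Saturated posteriors (0 or 1)
    are clamped to ``[EPS, 1-EPS]`` when ``clamp`` is true, otherwise raise.
    """
    post = np.asarray(post, dtype=float)
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0, 1)")
    if clamp:
        post = np.clip(post, EPS, 1.0 - EPS)
    elif np.any((post <= 0) | (post >= 1)):
        raise ValueError("saturated posterior; enable clamping")
    prior_odds = prior / (1.0 - prior)
    out = (post / (1.0 - post)) / prior_odds
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EvidenceScale:
    """Prior-specific likelihood-ratio thresholds for the point scale.

    ``lr_thresholds[x] == lr1 ** x`` for x in ±1..±4; posterior thresholds
    follow through Bayes' rule at the scale's prior.
    """

    prior: float
    lr1: float
    clip_min: int = -8
    clip_max: int = 8
    lr_thresholds: dict = field(default_factory=dict)
    posterior_thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lr1 <= 1:
            raise ValueError("lr1 must exceed 1 for a valid scale")
        if not self.lr_thresholds:
            object.__setattr__(
                self, "lr_thresholds", {x: self.lr1 ** x for x in POINT_LEVELS}
            )
        if not self.posterior_thresholds:
            object.__setattr__(
                self,
                "posterior_thresholds",
                {
                    x: posterior_from_lr(lr, self.prior)
                    for x, lr in self.lr_thresholds.items()
                },
            )

    def to_json(self):
        return json.dumps(
            {
                "prior": self.prior,
                "lr1": self.lr1,
                "lr_thresholds": {str(k): v for k, v in self.lr_thresholds.items()},
                "posterior_thresholds": {
                    str(k): v for k, v in self.posterior_thresholds.items()
                },
                "clip": [self.clip_min, self.clip_max],
            }
        )

    @classmethod
    def from_json(cls, s):
        d = json.loads(s)
        return cls(
            prior=d["prior"],
            lr1=d["lr1"],
            clip_min=d["clip"][0],
            clip_max=d["clip"][1],
        )


@dataclass(frozen=True)
class EvidencePoints:
    ep_continuous: float
    ep_integer: int


@dataclass(frozen=True)
class ClassificationResult:
    point_total: int
    tier: str


def build_evidence_scale(
    prior,
    clip=(-8, 8),
    pathogenic_point_total=10,
    target_posterior=0.99,
):
    """Solve the evidence scale from the prior.

    The very-strong odds constant ``C`` satisfies
    ``posterior_from_lr(C**(pathogenic_point_total/8), prior) == target_posterior``:
    a variant at the minimal Pathogenic point sum reaches the target posterior.
    Solved by root bracketing on log C over [1, 1e12].
    """
    if not 0 < prior < 1:
        raise ValueError("prior must be in (0, 1)")

    exponent = pathogenic_point_total / 8.0

    def residual(log_c):
        return (
            posterior_from_lr(math.exp(log_c * exponent), prior) - target_posterior
        )

    lo, hi = 0.0, math.log(1e12)
    if residual(lo) > 0 or residual(hi) < 0:
        raise ArithmeticError(
            f"no root for C in [1, 1e12] at prior={prior}: "
            f"residual({lo})={residual(lo):.3g}, residual({hi})={residual(hi):.3g}"
        )
    log_c = brentq(residual, lo, hi, xtol=1e-13, rtol=1e-15)
    lr1 = math.exp(log_c / 8.0)
    return EvidenceScale(prior=prior, lr1=lr1, clip_min=clip[0], clip_max=clip[1])


def continuous_points(lr, scale):
    """Continuous evidence points ``clip(log LR / log LR1, EPmin, EPmax)``.

    Vectorized over ``lr``; +inf LRs clip to the maximum.
    """
    if scale.lr1 <= 1:
        raise ValueError("invalid scale: lr1 <= 1")
    lr = np.asarray(lr, dtype=float)
    if np.any(lr <= 0):
        raise ValueError("lr must be positive")
    with np.errstate(divide="ignore"):
        ep = np.log(lr) / np.log(scale.lr1)
    ep = np.clip(ep, scale.clip_min, scale.clip_max)
    return float(ep) if ep.ndim == 0 else ep


def evidence_points(lr, scale):
    """Continuous and integer (truncated toward zero) evidence points."""
    ep = continuous_points(lr, scale)
    return EvidencePoints(ep_continuous=ep, ep_integer=int(math.trunc(ep)))


def score_intervals(grid, posterior, scale, max_level=4):
    """Extract per-level score intervals from a posterior curve.

    For each point level x in ±1..±max_level, returns the list of maximal
    contiguous score intervals whose posterior earns exactly x integer points
    (capped at ±max_level); level 0 holds the indeterminate region.
    """
    grid = np.asarray(grid, dtype=float)
    posterior = np.asarray(posterior, dtype=float)
    if grid.size == 0:
        raise ValueError("empty score grid")
    if grid.shape != posterior.shape:
        raise ValueError("grid and posterior must have identical shape")

    lr = lr_from_posterior(posterior, scale.prior)
    ep = continuous_points(lr, scale)
    level = np.trunc(ep).astype(int)
    level = np.clip(level, -max_level, max_level)

    intervals = {x: [] for x in range(-max_level, max_level + 1)}
    start = 0
    for i in range(1, grid.size + 1):
        if i == grid.size or level[i] != level[start]:
            intervals[int(level[start])].append((float(grid[start]), float(grid[i - 1])))
            start = i
    return intervals


def classify_from_points(point_total):
    """Five-tier classification from an integer evidence-point sum.

    Published point-based cut-points: Pathogenic >= 10, Likely pathogenic
    6..9, VUS 0..5, Likely benign -6..-1, Benign <= -7.
    """
    point_total = int(point_total)
    if point_total >= 10:
        tier = TIER_PATHOGENIC
    elif point_total >= 6:
        tier = TIER_LIKELY_PATHOGENIC
    elif point_total >= 0:
        tier = TIER_VUS
    elif point_total >= -6:
        tier = TIER_LIKELY_BENIGN
    else:
        tier = TIER_BENIGN
    return ClassificationResult(point_total=point_total, tier=tier)
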