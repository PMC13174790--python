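"""Evidence-point miscalibration metrics and evaluation statistics.

Miscalibration is expressed on the ACMG/AMP point scale: the difference
``dEP(s) = EP_est(s) - EP_true(s)`` between the continuous evidence points
implied by the estimated and true posteriors (clipped to [-8, +8] so that
overconfident assignments beyond the clinically usable +/-4 range still count
as errors). The interval likelihood ratio evaluates score intervals model-free
from control-variant counts, with conservative win rules and an exact
one-sided binomial test over units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evidence import continuous_points, lr_from_posterior

__all__ = [
    "MiscalibrationSummary",
    "IntervalLRReport",
    "miscalibration",
    "interval_lr",
    "win_compare",
    "binomial_win_test",
    "classification_metrics",
    "evidence_heatmap",
]

PATHOGENIC_LEVELS = (1, 2, 3, 4)
BENIGN_LEVELS = (-1, -2, -3, -4)


@dataclass
class MiscalibrationSummary:
    mape: float
    pfraction: float | None
    bfraction: float | None
    per_score_delta: np.ndarray = field(repr=False)
    pct75_err_P: float
    max_err_P: float
    pct75_err_B: float
    max_err_B: float


def miscalibration(est_posteriors, true_posteriors, scale, strict_regions=True):
    """Point-scale miscalibration summary of an estimated posterior vector.

    ``PFraction`` is the share of scores with dEP > 1 among scores in the
    pathogenic region, ``BFraction`` the share with dEP < -1 in the benign
    region. ``strict_regions`` keeps the literal region definitions
    (EP_true > 1 / < -1); the relaxed reading uses >= 1 / <= -1. Region-wise
    75th-percentile and maximum errors use +dEP (pathogenic) and -dEP
    (benign), the overconfidence directions.
    """
    est = np.asarray(est_posteriors, dtype=float)
    true = np.asarray(true_posteriors, dtype=float)
    if est.shape != true.shape:
        raise ValueError("posterior vectors must have equal length")

    ep_est = continuous_points(lr_from_posterior(est, scale.prior), scale)
    ep_true = continuous_points(lr_from_posterior(true, scale.prior), scale)
    delta = ep_est - ep_true

    if strict_regions:
        in_p = ep_true > 1
        in_b = ep_true < -1
    else:
        in_p = ep_true >= 1
        in_b = ep_true <= -1

    pfraction = float(np.mean(delta[in_p] > 1)) if in_p.any() else None
    bfraction = float(np.mean(delta[in_b] < -1)) if in_b.any() else None

    err_p = delta[in_p]
    err_b = -delta[in_b]
    return MiscalibrationSummary(
        mape=float(np.mean(np.abs(delta))),
        pfraction=pfraction,
        bfraction=bfraction,
        per_score_delta=delta,
        pct75_err_P=float(np.percentile(err_p, 75)) if err_p.size else 0.0,
        max_err_P=float(err_p.max()) if err_p.size else 0.0,
        pct75_err_B=float(np.percentile(err_b, 75)) if err_b.size else 0.0,
        max_err_B=float(err_b.max()) if err_b.size else 0.0,
    )


@dataclass
class IntervalLRReport:
    """Per-level empirical interval LRs against the scale's thresholds."""

    lr: dict
    threshold: dict
    defined: dict

    def win_count(self, other, **kw):
        wins, _, _ = win_compare(self, other, **kw)
        return wins


def _in_intervals(scores, intervals):
    scores = np.asarray(scores, dtype=float)
    mask = np.zeros(scores.shape, dtype=bool)
    for lo, hi in intervals:
        mask |= (scores >= lo) & (scores <= hi)
    return mask


def interval_lr(intervals, pathogenic_scores, benign_scores, scale):
    """Empirical LR of each evidence-level score interval.

    ``LR = (nP_in/N_P) / (nB_in/N_B)``; intervals holding pathogenic but no
    benign controls report +inf, intervals with no controls at all are flagged
    undefined.
    """
    path = np.asarray(pathogenic_scores, dtype=float)
    ben = np.asarray(benign_scores, dtype=float)
    if len(path) == 0 or len(ben) == 0:
        raise ValueError("need at least one control of each class")
    lrs, thresholds, defined = {}, {}, {}
    for level in PATHOGENIC_LEVELS + BENIGN_LEVELS:
        ivs = intervals.get(level, [])
        n_p = int(_in_intervals(path, ivs).sum())
        n_b = int(_in_intervals(ben, ivs).sum())
        thresholds[level] = scale.lr_thresholds[level]
        if n_p == 0 and n_b == 0:
            lrs[level] = np.nan
            defined[level] = False
            continue
        defined[level] = True
        frac_p = n_p / len(path)
        frac_b = n_b / len(ben)
        lrs[level] = float(np.inf) if frac_b == 0 else frac_p / frac_b
    return IntervalLRReport(lr=lrs, threshold=thresholds, defined=defined)


def win_compare(report_a, report_b, names=("A", "B")):
    """Per-level winner between two interval-LR reports on a shared scale.

    If both LRs sit on the preferred side of the threshold (>= for pathogenic
    levels, <= for benign) the one closest to the threshold wins; on opposite
    sides the conservative one wins (higher LR for pathogenic, lower for
    benign); equality is a tie. Undefined levels are skipped.
    """
    if report_a.threshold != report_b.threshold:
        raise ValueError("reports must share an evidence scale")
    per_level = {}
    wins = {names[0]: 0, names[1]: 0, "tie": 0, "skipped": 0}
    for level, thr in report_a.threshold.items():
        if not (report_a.defined.get(level) and report_b.defined.get(level)):
            per_level[level] = "skipped"
            wins["skipped"] += 1
            continue
        a, b = report_a.lr[level], report_b.lr[level]
        pathogenic = level > 0
        on_side = (lambda v: v >= thr) if pathogenic else (lambda v: v <= thr)
        if a == b:
            winner = "tie"
        elif on_side(a) and on_side(b):
            da = abs(np.log(a) - np.log(thr)) if np.isfinite(a) else np.inf
            db = abs(np.log(b) - np.log(thr)) if np.isfinite(b) else np.inf
            winner = "tie" if da == db else (names[0] if da < db else names[1])
        elif on_side(a) != on_side(b):
            # conservative preference: the side that under-calls evidence
            winner = names[0] if on_side(a) else names[1]
        else:  # both off-side
            da, db = abs(np.log(max(a, 1e-300)) - np.log(thr)), abs(
                np.log(max(b, 1e-300)) - np.log(thr)
            )
            winner = "tie" if da == db else (names[0] if da < db else names[1])
        per_level[level] = winner
        wins[winner] += 1
    return wins, per_level, names


def binomial_win_test(wins, ties, n_total):
    """Exact one-sided binomial tail P(X >= wins | n_total - ties, p=0.5)."""
    n = n_total - ties
    if n <= 0:
        raise ValueError("no untied comparisons")
    if wins > n:
        raise ValueError("wins exceed untied comparisons")
    return float(stats.binom.sf(wins - 1, n, 0.5))


def classification_metrics(points_per_variant, labels):
    """Two-sided evidence-assignment metrics from integer points and labels.

    The pathogenic side calls >= +1 point positive, the benign side <= -1;
    per-side TPR/FPR/MCC and their means, plus the determinate rate (fraction
    of variants with nonzero points).
    """
    points = np.asarray(points_per_variant)
    labels = np.asarray(labels)
    is_p = labels == "P"
    is_b = labels == "B"
    out = {"determinate_rate": float(np.mean(points != 0)) if points.size else np.nan}

    def side(call_mask, pos_mask, neg_mask):
        tp = int(np.sum(call_mask & pos_mask))
        fn = int(np.sum(~call_mask & pos_mask))
        fp = int(np.sum(call_mask & neg_mask))
        tn = int(np.sum(~call_mask & neg_mask))
        tpr = tp / (tp + fn) if (tp + fn) else np.nan
        fpr = fp / (fp + tn) if (fp + tn) else np.nan
        denom = np.sqrt(
            float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
        )
        mcc = (tp * tn - fp * fn) / denom if denom else np.nan
        return tpr, fpr, mcc

    out["TPR_P"], out["FPR_P"], out["MCC_P"] = side(points >= 1, is_p, is_b)
    out["TPR_B"], out["FPR_B"], out["MCC_B"] = side(points <= -1, is_b, is_p)
    out["AvgTPR"] = np.nanmean([out["TPR_P"], out["TPR_B"]])
    out["AvgFPR"] = np.nanmean([out["FPR_P"], out["FPR_B"]])
    out["MCC"] = np.nanmean([out["MCC_P"], out["MCC_B"]])
    return out


def evidence_heatmap(points_per_variant, strata, levels=range(-4, 5)):
    """Percentage of each stratum's variants at each point level.

    Rows are strata, columns the point levels (points beyond +/-4 are capped
    into the terminal columns); each defined row sums to 100.
    """
    points = np.clip(np.asarray(points_per_variant), min(levels), max(levels))
    strata = np.asarray(strata)
    rows = {}
    for name in pd.unique(strata):
        mask = strata == name
        n = int(mask.sum())
        if n == 0:
            rows[name] = {lv: np.nan for lv in levels}
            continue
        rows[name] = {
            lv: 100.0 * float(np.sum(points[mask] == lv)) / n for lv in levels
        }
    return pd.DataFrame(rows).T[list(levels)]
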