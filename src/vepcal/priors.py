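"""Positive-unlabeled prior estimation (adapted DistCurve).

The prior probability of pathogenicity of a gene or domain cluster is the
fraction of positives hidden in its unlabeled population variants. It is
estimated from feature vectors of labeled pathogenic (P) and unlabeled (U)
variants in three steps: (1) an out-of-bag ensemble of logistic classifiers on
z-scored, PCA-reduced features scores every variant P-vs-U without
self-prediction, using a unique bootstrap that keeps duplicate variants
(present in both P and U) on one side of each split and random under-sampling
to balance classes; (2) a distance-removal curve repeatedly draws a labeled
positive and removes the closest unlabeled variant, recording the score
distance — distances stay small until the unlabeled positives are exhausted;
(3) the elbow of that curve, located by a two-segment piecewise-linear fit to
the cumulative curve, gives the number of unlabeled positives and hence the
prior. Bootstrapping the curve yields a median prior with an interquartile
range, gated by the PU-AUC separability criterion (> 0.75).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler

__all__ = [
    "PULabeledData",
    "PriorEstimate",
    "unique_bootstrap_split",
    "oob_ensemble_scores",
    "distance_curve",
    "estimate_prior_from_curve",
    "bootstrap_prior",
]

PU_AUC_THRESHOLD = 0.75


@dataclass
class PULabeledData:
    features_P: np.ndarray
    features_U: np.ndarray
    ids_P: np.ndarray | None = None
    ids_U: np.ndarray | None = None

    def __post_init__(self):
        self.features_P = np.atleast_2d(np.asarray(self.features_P, dtype=float))
        self.features_U = np.atleast_2d(np.asarray(self.features_U, dtype=float))
        if self.features_P.shape[1] != self.features_U.shape[1]:
            raise ValueError("P and U feature matrices must share dimensionality")
        if self.ids_P is None:
            self.ids_P = np.array([f"P{i}" for i in range(len(self.features_P))])
        if self.ids_U is None:
            self.ids_U = np.array([f"U{i}" for i in range(len(self.features_U))])
        self.ids_P = np.asarray(self.ids_P)
        self.ids_U = np.asarray(self.ids_U)


@dataclass
class PriorEstimate:
    prior_median: float
    iqr: tuple
    n_bootstrap: int
    pu_auc: float
    retained: bool
    flag: str = ""


def unique_bootstrap_split(data, seed):
    """Bootstrap P and U with duplicate co-location.

    Ordinary per-set bootstrap, then repair: a variant id duplicated across P
    and U that was sampled on either side has both of its copies placed in the
    training sample; out-of-bag records are those whose id was never sampled.
    Returns ``(train_P, train_U, oob_P, oob_U)`` index arrays into each set.
    """
    rng = np.random.default_rng(seed)
    n_p, n_u = len(data.ids_P), len(data.ids_U)
    take_p = rng.integers(0, n_p, size=n_p)
    take_u = rng.integers(0, n_u, size=n_u)

    dup_ids = set(data.ids_P) & set(data.ids_U)
    pos_in_u = {i: j for j, i in enumerate(data.ids_U) if i in dup_ids}
    pos_in_p = {i: j for j, i in enumerate(data.ids_P) if i in dup_ids}

    sampled_ids = set(data.ids_P[take_p]) | set(data.ids_U[take_u])
    extra_p, extra_u = [], []
    for vid in dup_ids & sampled_ids:
        if pos_in_p[vid] not in take_p:
            extra_p.append(pos_in_p[vid])
        if pos_in_u[vid] not in take_u:
            extra_u.append(pos_in_u[vid])
    train_p = np.concatenate([take_p, np.array(extra_p, dtype=int)])
    train_u = np.concatenate([take_u, np.array(extra_u, dtype=int)])

    oob_p = np.array(
        [j for j in range(n_p) if data.ids_P[j] not in sampled_ids], dtype=int
    )
    oob_u = np.array(
        [j for j in range(n_u) if data.ids_U[j] not in sampled_ids], dtype=int
    )
    return train_p, train_u, oob_p, oob_u


def oob_ensemble_scores(data, n_members=100, seed=0, min_positives=10):
    """Per-variant out-of-bag P-vs-U score from a balanced PCA+logistic ensemble.

    Each member trains on a unique-bootstrap sample, balanced by random
    under-sampling of the larger class, z-scored and PCA-projected to the
    components explaining 95% of variance (statistics from the training
    sample only). A variant's score is the mean over members where it was
    out-of-bag. Returns ``(scores_P, scores_U)``; never-out-of-bag variants
    carry NaN.
    """
    if len(data.features_P) < min_positives:
        raise ValueError(
            f"need at least {min_positives} labeled positives "
            f"(got {len(data.features_P)})"
        )
    n_p, n_u = len(data.features_P), len(data.features_U)
    sums = np.zeros(n_p + n_u)
    counts = np.zeros(n_p + n_u, dtype=int)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_members)

    for m in range(n_members):
        rng = np.random.default_rng(child_seeds[2 * m])
        train_p, train_u, oob_p, oob_u = unique_bootstrap_split(
            data, child_seeds[2 * m + 1]
        )
        if len(oob_p) + len(oob_u) == 0:
            continue
        # random under-sampling of the larger class
        k = min(len(train_p), len(train_u))
        if k < 2:
            continue
        if len(train_p) > k:
            train_p = rng.choice(train_p, size=k, replace=False)
        if len(train_u) > k:
            train_u = rng.choice(train_u, size=k, replace=False)
        x = np.vstack(
            [data.features_P[train_p], data.features_U[train_u]]
        )
        y = np.concatenate([np.ones(len(train_p)), np.zeros(len(train_u))])
        scaler = StandardScaler().fit(x)
        xs = scaler.transform(x)
        n_comp = min(0.95 if min(xs.shape) > 1 else 1, min(xs.shape) - 1) or 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pca = PCA(n_components=n_comp, svd_solver="full").fit(xs)
        clf = LogisticRegression(max_iter=1000).fit(pca.transform(xs), y)

        x_oob = np.vstack(
            [data.features_P[oob_p], data.features_U[oob_u]]
        ) if len(oob_p) + len(oob_u) else None
        est = clf.predict_proba(pca.transform(scaler.transform(x_oob)))[:, 1]
        flat = np.concatenate([oob_p, n_p + oob_u])
        sums[flat] += est
        counts[flat] += 1

    never = counts == 0
    if never.any():
        warnings.warn(f"{int(never.sum())} variants never out-of-bag; scores NaN")
    with np.errstate(invalid="ignore"):
        scores = np.where(never, np.nan, sums / np.maximum(counts, 1))
    return scores[:n_p], scores[n_p:]


def distance_curve(scores_p, scores_u, seed=0):
    """DistCurve removal sequence.

    Iteratively draw a labeled positive score with replacement and remove the
    closest remaining unlabeled score, recording the absolute distance;
    returns the |U| recorded distances in removal order.
    """
    scores_p = np.asarray(scores_p, dtype=float)
    scores_u = np.asarray(scores_u, dtype=float)
    if scores_p.size == 0 or scores_u.size == 0:
        raise ValueError("both score sets must be nonempty")
    rng = np.random.default_rng(seed)
    remaining = scores_u.copy()
    alive = np.ones(len(remaining), dtype=bool)
    out = np.empty(len(remaining))
    draws = rng.integers(0, len(scores_p), size=len(remaining))
    for t in range(len(remaining)):
        p = scores_p[draws[t]]
        idx_alive = np.nonzero(alive)[0]
        d = np.abs(remaining[idx_alive] - p)
        j = idx_alive[np.argmin(d)]
        out[t] = np.abs(remaining[j] - p)
        alive[j] = False
    return out


def _segment_sse(sx, sy, sxx, sxy, syy, n):
    """SSE of the least-squares line through n points given moment sums."""
    if n < 2:
        return 0.0
    det = n * sxx - sx * sx
    if det <= 0:
        return float(syy - sy * sy / n)
    slope = (n * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / n
    return float(
        syy + slope * slope * sxx + n * intercept * intercept
        - 2 * slope * sxy - 2 * intercept * sy + 2 * slope * intercept * sx
    )


def estimate_prior_from_curve(curve, n_u=None, min_segment=5):
    """Elbow of the cumulative distance curve -> prior = t*/|U|.

    Two-segment piecewise-linear least squares on the cumulative curve; the
    breakpoint minimizing total SSE is the estimated count of unlabeled
    positives. Degenerate curves are flagged: flat (prior 0) or uniformly
    steep (prior 1).
    """
    curve = np.asarray(curve, dtype=float)
    n = len(curve)
    if n_u is None:
        n_u = n
    if n < 20:
        raise ValueError("curve too short for elbow detection (need >= 20)")
    y = np.cumsum(curve)
    x = np.arange(1, n + 1, dtype=float)

    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])

    best_t, best_sse = None, np.inf
    for t in range(min_segment, n - min_segment + 1):
        sse1 = _segment_sse(cx[t], cy[t], cxx[t], cxy[t], cyy[t], t)
        sse2 = _segment_sse(
            cx[n] - cx[t], cy[n] - cy[t], cxx[n] - cxx[t],
            cxy[n] - cxy[t], cyy[n] - cyy[t], n - t,
        )
        if sse1 + sse2 < best_sse:
            best_sse, best_t = sse1 + sse2, t

    slope1 = y[best_t - 1] / best_t
    slope2 = (y[-1] - y[best_t - 1]) / max(n - best_t, 1)
    flag = ""
    if slope1 <= 1e-12 or slope2 / max(slope1, 1e-300) < 1.5:
        # no pronounced slope increase at the breakpoint: degenerate curve
        if float(np.mean(curve)) < 0.05:
            # distances uniformly tiny: U is (nearly) all positives
            return 1.0, "monotone-small-distances"
        # distances uniformly large from the start: no unlabeled positives
        return 0.0, "flat"
    prior = best_t / n_u
    return float(np.clip(prior, 0.0, 1.0)), flag


def bootstrap_prior(scores_p, scores_u, n_bootstrap=5000, seed=0):
    """Median-and-IQR prior over bootstrap distance curves, with PU-AUC gate.

    ``scores_p``/``scores_u`` are out-of-bag ensemble scores (NaNs dropped).
    The retained flag requires PU-AUC strictly above 0.75.
    """
    scores_p = np.asarray(scores_p, dtype=float)
    scores_u = np.asarray(scores_u, dtype=float)
    scores_p = scores_p[np.isfinite(scores_p)]
    scores_u = scores_u[np.isfinite(scores_u)]
    if n_bootstrap < 100:
        warnings.warn("n_bootstrap < 100: test-mode estimate")

    y = np.concatenate([np.ones(len(scores_p)), np.zeros(len(scores_u))])
    pu_auc = float(roc_auc_score(y, np.concatenate([scores_p, scores_u])))

    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_bootstrap)
    estimates = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        rng = np.random.default_rng(seeds[2 * b])
        bp = rng.choice(scores_p, size=len(scores_p), replace=True)
        bu = rng.choice(scores_u, size=len(scores_u), replace=True)
        curve = distance_curve(bp, bu, seed=seeds[2 * b + 1])
        estimates[b], _ = estimate_prior_from_curve(curve)

    q25, med, q75 = np.percentile(estimates, [25, 50, 75])
    return PriorEstimate(
        prior_median=float(med),
        iqr=(float(q25), float(q75)),
        n_bootstrap=n_bootstrap,
        pu_auc=pu_auc,
        retained=pu_auc > PU_AUC_THRESHOLD,
    )
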