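"""Protein-domain aggregation by score-distribution shape.

Domains from many genes are pooled when the distributions of predictor scores
over all possible missense SNVs in each domain look alike. Distribution shape
is summarized as a normalized histogram; pairwise similarity is the
Jensen-Shannon distance (square root of the base-2 JS divergence, a bounded
metric); domains are clustered hierarchically and the dendrogram is cut
dynamically so that no cluster exceeds a maximum count of labeled control
variants, with the maximum chosen by grid search to put the median cluster's
labeled count near a target (500 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import jensenshannon, squareform

__all__ = [
    "DomainInterval",
    "DomainClustering",
    "resolve_overlaps",
    "score_histogram",
    "jsd_matrix",
    "cluster_and_split",
    "grid_search_max_count",
    "cluster_validation",
    "assign_variant_to_cluster",
]

N_BINS = 100
PSEUDOCOUNT = 1e-6


@dataclass(frozen=True)
class DomainInterval:
    gene: str
    start: int
    end: int
    domain_id: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start > end in {self.domain_id}")

    @property
    def length(self):
        return self.end - self.start + 1


@dataclass
class DomainClustering:
    domains: list
    histograms: np.ndarray
    jsd: np.ndarray
    clusters: dict
    clinvar_counts: dict
    max_count: int | None = None
    flagged_singletons: list = field(default_factory=list)


def _overlap(a, b):
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def resolve_overlaps(intervals):
    """Make a gene's domain intervals non-overlapping.

    Reciprocal overlap >= 50% of both intervals merges them (the merged
    interval keeps both ids joined by '+'); smaller overlaps are split at the
    overlap midpoint. Applied left-to-right until no overlaps remain.
    """
    work = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    changed = True
    while changed:
        changed = False
        out = []
        i = 0
        while i < len(work):
            if i + 1 < len(work):
                a, b = work[i], work[i + 1]
                ov = _overlap(a, b)
                if ov > 0:
                    changed = True
                    if ov >= 0.5 * a.length and ov >= 0.5 * b.length:
                        merged_id = (
                            a.domain_id
                            if a.domain_id == b.domain_id
                            else f"{a.domain_id}+{b.domain_id}"
                        )
                        out.append(
                            DomainInterval(
                                a.gene, min(a.start, b.start),
                                max(a.end, b.end), merged_id,
                            )
                        )
                    else:
                        mid = (max(a.start, b.start) + min(a.end, b.end)) // 2
                        left = DomainInterval(a.gene, a.start, mid, a.domain_id)
                        right = DomainInterval(b.gene, mid + 1, b.end, b.domain_id)
                        out.extend([left, right])
                    i += 2
                    continue
            out.append(work[i])
            i += 1
        work = sorted(out, key=lambda iv: (iv.start, iv.end))
    return work


def score_histogram(scores, n_bins=N_BINS, pseudocount=PSEUDOCOUNT):
    """Equal-width normalized histogram of scores on [0, 1] with pseudocount."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot histogram an empty score list")
    hist, _ = np.histogram(scores, bins=n_bins, range=(0.0, 1.0))
    hist = hist.astype(float) + pseudocount
    return hist / hist.sum()


def jsd_matrix(histograms):
    """All-by-all Jensen-Shannon distance (sqrt of base-2 JS divergence)."""
    h = np.asarray(histograms, dtype=float)
    n = len(h)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jensenshannon(h[i], h[j], base=2)
    return out


def cluster_and_split(jsd, clinvar_counts, max_count, method="average"):
    """Hierarchical clustering with a dynamic labeled-count tree cut.

    Builds an average-linkage dendrogram on the distance matrix and descends
    from the root: any branch whose member domains carry more than
    ``max_count`` labeled variants in total is replaced by its two children;
    compliant branches (and unsplittable single leaves, which are flagged)
    become clusters. Returns ``(labels, flagged_leaf_indices)`` with labels as
    an int array over domains.
    """
    jsd = np.asarray(jsd, dtype=float)
    counts = np.asarray(clinvar_counts, dtype=float)
    n = len(counts)
    if n == 1:
        return np.zeros(1, dtype=int), ([0] if counts[0] > max_count else [])
    tree = to_tree(linkage(squareform(jsd, checks=False), method=method))

    labels = -np.ones(n, dtype=int)
    flagged = []
    next_label = [0]

    def descend(node):
        leaves = node.pre_order()
        total = counts[leaves].sum()
        if total > max_count and not node.is_leaf():
            descend(node.get_left())
            descend(node.get_right())
            return
        if total > max_count and node.is_leaf():
            flagged.append(node.id)
        labels[leaves] = next_label[0]
        next_label[0] += 1

    descend(tree)
    return labels, flagged


def grid_search_max_count(
    jsd, clinvar_counts, target_median=500, n_candidates=50, method="average"
):
    """Choose the max labeled count whose clustering has median count near target.

    Candidates are log-spaced between 50 and the total labeled count; ties in
    |median - target| break toward the larger (coarser) maximum.
    """
    counts = np.asarray(clinvar_counts, dtype=float)
    total = counts.sum()
    lo = min(50.0, total)
    cands = np.unique(np.geomspace(max(lo, 1.0), max(total, lo + 1), n_candidates))
    best = None
    for mc in cands:
        labels, _ = cluster_and_split(jsd, counts, mc, method=method)
        cluster_counts = [counts[labels == c].sum() for c in np.unique(labels)]
        med = float(np.median(cluster_counts))
        key = (abs(med - target_median), -mc)
        if best is None or key < best[0]:
            best = (key, mc, labels)
    _, max_count, labels = best
    return int(round(max_count)), labels


def _weighted_skewnorm_nll(theta, x, w):
    a, loc, log_scale = theta
    scale = np.exp(log_scale)
    with np.errstate(all="ignore"):
        lp = stats.skewnorm.logpdf(x, a, loc, scale)
    if not np.all(np.isfinite(lp[w > 0])):
        return 1e12
    return -float(np.sum(w * lp))


def _fit_skewnorm_mixture(scores, n_restarts=5, max_iter=60, seed=0, tol=1e-6):
    """Two-component skew-normal mixture by EM with weighted M-steps."""
    x = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        # moment-based perturbation of the split initialization
        q = rng.uniform(0.3, 0.7)
        thr = np.quantile(x, q)
        params = []
        for mask in (x <= thr, x > thr):
            sub = x[mask] if mask.sum() > 5 else x
            params.append((0.0, float(np.mean(sub)), float(np.std(sub) or 0.05)))
        weight = q
        prev_ll = -np.inf
        converged = False
        for _ in range(max_iter):
            p0 = stats.skewnorm.pdf(x, params[0][0], params[0][1], params[0][2])
            p1 = stats.skewnorm.pdf(x, params[1][0], params[1][1], params[1][2])
            num0 = weight * np.maximum(p0, 1e-300)
            num1 = (1 - weight) * np.maximum(p1, 1e-300)
            resp0 = num0 / (num0 + num1)
            ll = float(np.sum(np.log(num0 + num1)))
            if abs(ll - prev_ll) < tol * abs(ll):
                converged = True
                break
            prev_ll = ll
            weight = float(np.mean(resp0))
            for k, w in enumerate((resp0, 1 - resp0)):
                a0, loc0, sc0 = params[k]
                res = optimize.minimize(
                    _weighted_skewnorm_nll,
                    [a0, loc0, np.log(sc0)],
                    args=(x, w),
                    method="Nelder-Mead",
                    options={"maxiter": 200, "fatol": 1e-6},
                )
                params[k] = (res.x[0], res.x[1], float(np.exp(res.x[2])))
        if best is None or prev_ll > best[0]:
            best = (prev_ll, params, weight, converged)
    ll, params, weight, converged = best
    # order components by mean so component 1 is the lower-mean "normal" class
    means = [stats.skewnorm.mean(*p) for p in params]
    if means[0] > means[1]:
        params = params[::-1]
        weight = 1 - weight
    return params, weight, converged


def cluster_validation(
    cluster_all_scores,
    cluster_benign_scores,
    cluster_pathogenic_scores,
    global_benign_scores,
    global_pathogenic_scores,
    n_bins=N_BINS,
    seed=0,
):
    """Compare mixture components to cluster-level vs genome-wide controls.

    Fits an unsupervised two-component skew-normal mixture to the cluster's
    all-variant scores (component 1 = lower-mean "normal" class, component 2 =
    "abnormal"), then measures the Jensen-Shannon distance between each
    component density and the benign/pathogenic control histograms at the
    cluster and genome-wide levels. ``difference`` is mean(global JSD) -
    mean(cluster JSD); positive values mean the cluster's own controls match
    the mixture better.
    """
    scores = np.asarray(cluster_all_scores, dtype=float)
    if scores.size < 50:
        raise ValueError("need >= 50 all-variant scores to fit the mixture")
    params, weight, converged = _fit_skewnorm_mixture(scores, seed=seed)

    edges = np.linspace(0, 1, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2

    def component_hist(p):
        dens = stats.skewnorm.pdf(centers, p[0], p[1], p[2]) + PSEUDOCOUNT
        return dens / dens.sum()

    comp = [component_hist(p) for p in params]  # [normal, abnormal]
    report = {"converged": converged, "weight_normal": weight}
    pairs = {
        "cluster": (cluster_benign_scores, cluster_pathogenic_scores),
        "global": (global_benign_scores, global_pathogenic_scores),
    }
    for level, (ben, path) in pairs.items():
        jsd_b = jensenshannon(comp[0], score_histogram(ben, n_bins), base=2)
        jsd_p = jensenshannon(comp[1], score_histogram(path, n_bins), base=2)
        report[f"jsd_benign_{level}"] = float(jsd_b)
        report[f"jsd_pathogenic_{level}"] = float(jsd_p)
        report[f"jsd_mean_{level}"] = float((jsd_b + jsd_p) / 2)
    report["difference"] = report["jsd_mean_global"] - report["jsd_mean_cluster"]
    return report


def assign_variant_to_cluster(gene, protein_pos, resolved_domains, clusters):
    """Map one variant to its domain's cluster, or 'non_domain'.

    ``resolved_domains``: list of non-overlapping :class:`DomainInterval`;
    ``clusters``: domain_id -> cluster id. Interval bounds are inclusive.
    """
    if protein_pos is None or (
        isinstance(protein_pos, float) and not np.isfinite(protein_pos)
    ):
        return "non_domain"
    for iv in resolved_domains:
        if iv.gene == gene and iv.start <= protein_pos <= iv.end:
            return clusters.get(iv.domain_id, "non_domain")
    return "non_domain"
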