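"""Posterior-calibration methods for predictor scores.

Eleven methods map a score in [0, 1] to a posterior probability of
pathogenicity: three logistic-family parametric maps (Platt, weighted Platt,
beta calibration), three class-conditional density-mixture maps (skew-normal,
beta, truncated-normal families combined through Bayes' rule at the training
pathogenic fraction), three shape-constrained non-parametric maps (isotonic,
smoothed isotonic, smoothing spline on a logit isotonic pre-fit), a monotone
neural network, and the sliding-window local posterior estimator used by
genome-wide calibration.

A fitted map reflects the pathogenic fraction of its training set; when that
fraction differs from the deployment prior, :func:`prior_shift_correct`
re-weights the posterior through the likelihood ratio. The out-of-bag
bootstrap produces 5th/95th-percentile conservative posterior envelopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator, UnivariateSpline
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression

from ._mononn import MonotoneNet
from .evidence import EPS, continuous_points, lr_from_posterior
from .simulate import fit_family, family_pdf

__all__ = [
    "METHODS",
    "MONOTONE_METHODS",
    "LOCAL_WINDOW_FRACS",
    "LOCAL_GNOMAD_FRACS",
    "ScoreSet",
    "FittedCalibrator",
    "PosteriorEnvelope",
    "CalibrationFitError",
    "fit_calibrator",
    "local_posterior",
    "prior_shift_correct",
    "oob_bootstrap_envelope",
]

METHODS = (
    "platt",
    "weighted_platt",
    "beta_calibration",
    "skewnormal_mixture",
    "beta_mixture",
    "truncnormal_mixture",
    "isotonic",
    "smoothed_isotonic",
    "spline",
    "mono_post_nn",
    "local_posterior",
)

MONOTONE_METHODS = (
    "platt",
    "weighted_platt",
    "beta_calibration",
    "isotonic",
    "smoothed_isotonic",
    "mono_post_nn",
)

#: local-posterior sensitivity grid (window fraction x unlabeled fraction)
LOCAL_WINDOW_FRACS = (0.10, 0.20, 0.30)
LOCAL_GNOMAD_FRACS = (0.0, 0.03, 0.06)


class CalibrationFitError(RuntimeError):
    """A calibration method failed to fit; the method is excluded, not fatal."""


@dataclass
class ScoreSet:
    """Labeled (and optionally unlabeled) scores for one calibration unit."""

    pathogenic_scores: np.ndarray
    benign_scores: np.ndarray
    unlabeled_scores: np.ndarray | None = None
    unit_id: str = ""

    def __post_init__(self):
        self.pathogenic_scores = np.asarray(self.pathogenic_scores, dtype=float)
        self.benign_scores = np.asarray(self.benign_scores, dtype=float)
        if self.unlabeled_scores is not None:
            self.unlabeled_scores = np.asarray(self.unlabeled_scores, dtype=float)
        for arr in (self.pathogenic_scores, self.benign_scores):
            if arr.size and (not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1):
                raise ValueError("scores must be finite and within [0, 1]")

    @property
    def n_p(self):
        return len(self.pathogenic_scores)

    @property
    def n_b(self):
        return len(self.benign_scores)

    @property
    def alpha_obs(self):
        total = self.n_p + self.n_b
        if total == 0:
            raise ValueError("alpha_obs undefined for an empty score set")
        return self.n_p / total

    def labeled(self):
        """(scores, labels) with pathogenic = 1."""
        scores = np.concatenate([self.pathogenic_scores, self.benign_scores])
        labels = np.concatenate(
            [np.ones(self.n_p, dtype=int), np.zeros(self.n_b, dtype=int)]
        )
        return scores, labels

    def to_tsv(self, path):
        scores, labels = self.labeled()
        rows = [
            {"unit_id": self.unit_id, "score": s, "label": "P" if l else "B"}
            for s, l in zip(scores, labels)
        ]
        if self.unlabeled_scores is not None:
            rows += [
                {"unit_id": self.unit_id, "score": s, "label": "U"}
                for s in self.unlabeled_scores
            ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t")
        unit = str(df["unit_id"].iloc[0]) if len(df) else ""
        u = df.loc[df.label == "U", "score"].to_numpy()
        return cls(
            pathogenic_scores=df.loc[df.label == "P", "score"].to_numpy(),
            benign_scores=df.loc[df.label == "B", "score"].to_numpy(),
            unlabeled_scores=u if len(u) else None,
            unit_id=unit,
        )


@dataclass
class FittedCalibrator:
    method: str
    train_alpha: float
    posterior_fn: callable
    fit_diagnostics: dict = field(default_factory=dict)

    def __call__(self, scores):
        out = np.clip(self.posterior_fn(np.asarray(scores, dtype=float)), 0.0, 1.0)
        return out


def _clip01(s):
    return np.clip(s, 1e-6, 1 - 1e-6)


def _check_fittable(data, min_per_class=2):
    if data.n_p < min_per_class or data.n_b < min_per_class:
        raise CalibrationFitError(
            f"need >= {min_per_class} scores per class "
            f"(got {data.n_p} P, {data.n_b} B)"
        )
    scores, _ = data.labeled()
    if np.ptp(scores) == 0:
        raise ValueError("degenerate single-valued score set")


def _fit_logistic(scores, labels, sample_weight=None):
    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    clf.fit(scores.reshape(-1, 1), labels, sample_weight=sample_weight)
    return clf


def _fit_platt(data, weighted=False):
    scores, labels = data.labeled()
    weight = None
    if weighted:
        # inverse class-frequency weights
        n = len(labels)
        w_pos = n / (2.0 * max(labels.sum(), 1))
        w_neg = n / (2.0 * max(n - labels.sum(), 1))
        weight = np.where(labels == 1, w_pos, w_neg)
    clf = _fit_logistic(scores, labels, weight)
    a, b = float(clf.coef_[0, 0]), float(clf.intercept_[0])

    def fn(s):
        return 1.0 / (1.0 + np.exp(-np.clip(a * s + b, -35, 35)))

    return fn, {"slope": a, "intercept": b, "converged": True}


def _fit_beta_calibration(data):
    """Three-parameter beta calibration: logistic fit on (ln s, -ln(1-s)).

    Negative shape coefficients break monotonicity, so any negative
    coefficient drops its feature and the model is refit (the standard
    reduction of beta calibration to its monotone sub-family).
    """
    scores, labels = data.labeled()
    s = _clip01(scores)
    feats = np.column_stack([np.log(s), -np.log(1.0 - s)])
    use = [0, 1]
    for _ in range(2):
        clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
        clf.fit(feats[:, use], labels)
        coefs = clf.coef_[0]
        neg = [use[i] for i in range(len(use)) if coefs[i] < 0]
        if not neg:
            break
        use = [u for u in use if u not in neg]
        if not use:
            raise CalibrationFitError("beta calibration degenerate: both shapes < 0")
    a = float(clf.coef_[0][use.index(0)]) if 0 in use else 0.0
    b = float(clf.coef_[0][use.index(1)]) if 1 in use else 0.0
    c = float(clf.intercept_[0])

    def fn(x):
        x = _clip01(x)
        z = a * np.log(x) - b * np.log(1.0 - x) + c
        return 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))

    return fn, {"a": a, "b": b, "c": c, "converged": True}


_MIXTURE_FAMILY = {
    "skewnormal_mixture": "skewnorm",
    "beta_mixture": "beta",
    "truncnormal_mixture": "trunc_normal",
}


def _fit_class_density(scores, family):
    scores = _clip01(np.asarray(scores, dtype=float))
    if family == "skewnorm":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, loc, scale = stats.skewnorm.fit(scores)
        if not np.isfinite([a, loc, scale]).all() or scale <= 0:
            raise CalibrationFitError("skew-normal fit diverged")
        return lambda x: stats.skewnorm.pdf(x, a, loc, scale), (a, loc, scale), True
    if family == "beta":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, b, _, _ = stats.beta.fit(scores, floc=0, fscale=1)
        return lambda x: stats.beta.pdf(_clip01(x), a, b), (a, b), True
    if family == "trunc_normal":
        fit = fit_family(scores, "trunc_normal")
        return (
            lambda x: family_pdf("trunc_normal", fit.params, x),
            fit.params,
            fit.converged,
        )
    raise ValueError(family)


def _fit_mixture(data, method):
    family = _MIXTURE_FAMILY[method]
    pdf_p, params_p, ok_p = _fit_class_density(data.pathogenic_scores, family)
    pdf_b, params_b, ok_b = _fit_class_density(data.benign_scores, family)
    alpha = data.alpha_obs

    def fn(s):
        fp = np.maximum(pdf_p(s), 0.0)
        fb = np.maximum(pdf_b(s), 0.0)
        denom = alpha * fp + (1.0 - alpha) * fb
        return np.where(denom <= 0, alpha, alpha * fp / np.maximum(denom, 1e-300))

    diag = {
        "params_P": tuple(params_p),
        "params_B": tuple(params_b),
        "converged": bool(ok_p and ok_b),
    }
    if not diag["converged"]:
        raise CalibrationFitError(f"{method}: class density fit did not converge")
    return fn, diag


def _fit_isotonic(data):
    scores, labels = data.labeled()
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(scores, labels)
    return (lambda s: iso.predict(s)), {"converged": True, "model": iso}


def _fit_smoothed_isotonic(data):
    """Monotone PCHIP through the midpoints of the isotonic steps."""
    fn_iso, diag = _fit_isotonic(data)
    iso = diag["model"]
    x_thr = np.asarray(iso.X_thresholds_, dtype=float)
    y_thr = np.asarray(iso.y_thresholds_, dtype=float)
    # collapse each constant step to its midpoint
    xs, ys = [], []
    i = 0
    while i < len(y_thr):
        j = i
        while j + 1 < len(y_thr) and y_thr[j + 1] == y_thr[i]:
            j += 1
        xs.append((x_thr[i] + x_thr[j]) / 2.0)
        ys.append(y_thr[i])
        i = j + 1
    if len(xs) < 2:
        return fn_iso, {"converged": True, "note": "single step; isotonic used"}
    pchip = PchipInterpolator(xs, ys, extrapolate=False)
    lo_x, hi_x = xs[0], xs[-1]
    lo_y, hi_y = ys[0], ys[-1]

    def fn(s):
        s = np.asarray(s, dtype=float)
        out = pchip(np.clip(s, lo_x, hi_x))
        out = np.where(s <= lo_x, lo_y, out)
        out = np.where(s >= hi_x, hi_y, out)
        return np.clip(out, 0.0, 1.0)

    return fn, {"converged": True, "n_knots": len(xs)}


def _logit(p):
    p = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(p / (1.0 - p))


def _spline_from_iso(scores, labels, smooth_factor):
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(scores, labels)
    xs = np.unique(scores)
    ys = _logit(iso.predict(xs))
    if len(xs) < 5:
        raise CalibrationFitError("too few distinct scores for the spline method")
    spl = UnivariateSpline(xs, ys, k=3, s=smooth_factor * len(xs))

    def fn(s):
        z = spl(np.clip(s, xs[0], xs[-1]))
        return 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))

    return fn


def _fit_spline(data, smooth_grid=(0.01, 0.1, 1.0, 10.0), n_folds=5, seed=0):
    """Cubic smoothing spline on the logit of an isotonic pre-fit.

    The smoothing parameter is chosen by k-fold cross-validated log-loss.
    """
    scores, labels = data.labeled()
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(labels))
    folds = np.array_split(idx, n_folds)
    losses = []
    for sf in smooth_grid:
        fold_losses = []
        for k in range(n_folds):
            test = folds[k]
            train = np.concatenate([folds[j] for j in range(n_folds) if j != k])
            if len(np.unique(labels[train])) < 2:
                continue
            try:
                fn = _spline_from_iso(scores[train], labels[train], sf)
            except Exception:
                continue
            p = np.clip(fn(scores[test]), 1e-9, 1 - 1e-9)
            y = labels[test]
            fold_losses.append(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        losses.append(np.mean(fold_losses) if fold_losses else np.inf)
    best = smooth_grid[int(np.argmin(losses))]
    fn = _spline_from_iso(scores, labels, best)
    return fn, {"converged": True, "smooth_factor": best}


def _fit_mono_nn(data, seed=0, max_epochs=400):
    scores, labels = data.labeled()
    net = MonotoneNet(seed=seed).fit(scores, labels, max_epochs=max_epochs)
    return (lambda s: net.predict(s)), {"converged": True, "seed": seed}


def fit_calibrator(method, data, options=None):
    """Fit one of the eleven calibration methods to a :class:`ScoreSet`.

    Raises :class:`CalibrationFitError` on non-convergence so that the caller
    can exclude the method without aborting a pipeline.
    """
    options = dict(options or {})
    if method == "local_posterior":
        return local_posterior(
            data,
            window_frac=options.get("window_frac", 0.20),
            gnomad_frac=options.get("gnomad_frac", 0.0),
            target_prior=options.get("target_prior", data.alpha_obs),
        )
    _check_fittable(data)
    try:
        if method == "platt":
            fn, diag = _fit_platt(data)
        elif method == "weighted_platt":
            fn, diag = _fit_platt(data, weighted=True)
        elif method == "beta_calibration":
            fn, diag = _fit_beta_calibration(data)
        elif method in _MIXTURE_FAMILY:
            fn, diag = _fit_mixture(data, method)
        elif method == "isotonic":
            fn, diag = _fit_isotonic(data)
        elif method == "smoothed_isotonic":
            fn, diag = _fit_smoothed_isotonic(data)
        elif method == "spline":
            fn, diag = _fit_spline(data, seed=options.get("seed", 0))
        elif method == "mono_post_nn":
            fn, diag = _fit_mono_nn(
                data,
                seed=options.get("seed", 0),
                max_epochs=options.get("max_epochs", 400),
            )
        else:
            raise ValueError(f"unknown method: {method}")
    except (CalibrationFitError, ValueError):
        raise
    except Exception as exc:  # optimizer blow-ups become fit failures
        raise CalibrationFitError(f"{method}: {exc}") from exc
    return FittedCalibrator(
        method=method,
        train_alpha=data.alpha_obs,
        posterior_fn=fn,
        fit_diagnostics=diag,
    )


def local_posterior(data, window_frac=0.20, gnomad_frac=0.0, target_prior=None):
    """Sliding-window local posterior (genome-wide calibration estimator).

    At each evaluation score a symmetric window expands until it holds at
    least ``window_frac`` of the labeled scores and ``gnomad_frac`` of the
    unlabeled scores; the posterior combines the window's class fractions
    with the target prior:
    ``a*(nP/NP) / (a*nP/NP + (1-a)*nB/NB)``.
    """
    if gnomad_frac > 0 and (
        data.unlabeled_scores is None or len(data.unlabeled_scores) == 0
    ):
        raise CalibrationFitError(
            "local_posterior with gnomad_frac > 0 requires unlabeled scores"
        )
    path = np.sort(data.pathogenic_scores)
    ben = np.sort(data.benign_scores)
    labeled = np.sort(np.concatenate([path, ben]))
    n_l = len(labeled)
    n_p_tot, n_b_tot = len(path), len(ben)
    if n_p_tot == 0 or n_b_tot == 0:
        raise CalibrationFitError("local_posterior needs scores in both classes")
    unl = (
        np.sort(data.unlabeled_scores)
        if data.unlabeled_scores is not None
        else np.empty(0)
    )
    alpha = data.alpha_obs if target_prior is None else float(target_prior)
    k_l = max(1, int(np.ceil(window_frac * n_l)))
    k_u = int(np.ceil(gnomad_frac * len(unl))) if gnomad_frac > 0 else 0

    def fn(s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        d_l = np.abs(s[:, None] - labeled[None, :])
        radius = np.partition(d_l, k_l - 1, axis=1)[:, k_l - 1]
        if k_u > 0:
            d_u = np.abs(s[:, None] - unl[None, :])
            r_u = np.partition(d_u, k_u - 1, axis=1)[:, k_u - 1]
            radius = np.maximum(radius, r_u)
        # tiny slack keeps boundary points inside the window despite rounding
        lo = s - radius - 1e-12
        hi = s + radius + 1e-12
        n_pw = np.searchsorted(path, hi, side="right") - np.searchsorted(
            path, lo, side="left"
        )
        n_bw = np.searchsorted(ben, hi, side="right") - np.searchsorted(
            ben, lo, side="left"
        )
        num = alpha * n_pw / n_p_tot
        den = num + (1.0 - alpha) * n_bw / n_b_tot
        out = np.where(den <= 0, alpha, num / np.maximum(den, 1e-300))
        return out

    name = f"local_posterior_w{window_frac:g}_g{gnomad_frac:g}"
    return FittedCalibrator(
        method=name,
        # the estimator already targets the deployment prior
        train_alpha=alpha,
        posterior_fn=fn,
        fit_diagnostics={
            "converged": True,
            "window_frac": window_frac,
            "gnomad_frac": gnomad_frac,
            "target_prior": alpha,
        },
    )


def prior_shift_correct(rho, alpha_train, alpha_target):
    """Correct a calibrated posterior for a train/deployment prior shift.

    ``LR = rho/(1-rho) * (1-a')/a'`` then Bayes at the target prior. Identity
    when the priors coincide. Saturated posteriors are clamped.
    """
    if not 0 < alpha_train < 1 or not 0 < alpha_target < 1:
        raise ValueError("priors must be in (0, 1)")
    rho = np.asarray(rho, dtype=float)
    rho_c = np.clip(rho, EPS, 1.0 - EPS)
    lr = rho_c / (1.0 - rho_c) * (1.0 - alpha_train) / alpha_train
    out = alpha_target * lr / (alpha_target * lr + (1.0 - alpha_target))
    return float(out) if out.ndim == 0 else out


@dataclass
class PosteriorEnvelope:
    """Per-score bootstrap posterior envelope with conservative substitution."""

    grid: np.ndarray
    point_estimate: np.ndarray
    lower_05: np.ndarray
    upper_95: np.ndarray
    conservative: np.ndarray
    n_boot: int = 0
    never_oob: int = 0

    def conservative_on(self, grid):
        return np.interp(grid, self.grid, self.conservative)

    def to_tsv(self, path):
        pd.DataFrame(
            {
                "grid": self.grid,
                "point": self.point_estimate,
                "lo": self.lower_05,
                "hi": self.upper_95,
                "conservative": self.conservative,
            }
        ).to_csv(path, sep="\t", index=False)


def oob_bootstrap_envelope(
    data,
    method,
    scale,
    n_boot=1000,
    seed=0,
    target_prior=None,
    options=None,
):
    """Out-of-bag bootstrap posterior envelope at the labeled scores.

    Each round resamples the labeled scores with replacement, fits the method
    on the in-bag sample, and records posterior estimates for the out-of-bag
    scores. Per-score 5th/95th percentiles bound the estimate; conservative
    substitution uses the 5th percentile wherever the full-data fit implies
    >= +1 point, the 95th wherever it implies <= -1 point, and the full-data
    fit itself in the indeterminate region. All posteriors are expressed at
    ``target_prior`` (the scale's prior by default).
    """
    target_prior = scale.prior if target_prior is None else float(target_prior)
    options = dict(options or {})
    full = fit_calibrator(method, data, options)
    scores, labels = data.labeled()
    order = np.argsort(scores, kind="stable")
    n = len(scores)

    received = [[] for _ in range(n)]
    done = 0
    for b in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        take = rng.integers(0, n, size=n)
        in_lab = labels[take]
        if in_lab.sum() < 2 or (len(in_lab) - in_lab.sum()) < 2:
            continue
        boot = ScoreSet(
            pathogenic_scores=scores[take][in_lab == 1],
            benign_scores=scores[take][in_lab == 0],
            unlabeled_scores=data.unlabeled_scores,
            unit_id=data.unit_id,
        )
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[np.unique(take)] = False
        if not oob_mask.any():
            continue
        try:
            fit = fit_calibrator(method, boot, options)
        except CalibrationFitError:
            continue
        est = fit(scores[oob_mask])
        for i, e in zip(np.nonzero(oob_mask)[0], est):
            received[i].append(e)
        done += 1

    point_raw = full(scores)
    lo = np.empty(n)
    hi = np.empty(n)
    never = 0
    for i in range(n):
        if received[i]:
            lo[i] = np.percentile(received[i], 5)
            hi[i] = np.percentile(received[i], 95)
        else:
            never += 1
            lo[i] = hi[i] = point_raw[i]
    if never:
        warnings.warn(f"{never} scores never out-of-bag after {done} rounds")

    # express everything at the deployment prior (monotone, commutes with
    # percentiles) and substitute by region of the full-data fit
    shift = lambda p: prior_shift_correct(p, full.train_alpha, target_prior)
    point_t = shift(point_raw)
    lo_t, hi_t = shift(lo), shift(hi)
    ep_full = continuous_points(lr_from_posterior(point_t, scale.prior), scale)
    conservative = np.where(ep_full >= 1, lo_t, np.where(ep_full <= -1, hi_t, point_t))

    return PosteriorEnvelope(
        grid=scores[order],
        point_estimate=point_t[order],
        lower_05=lo_t[order],
        upper_95=hi_t[order],
        conservative=conservative[order],
        n_boot=done,
        never_oob=never,
    )
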