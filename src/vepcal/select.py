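"""Data-adaptive calibration-method selection.

A gene qualifies for gene-specific calibration through tiered control-variant
requirements (size and class balance). For an eligible unit, the framework
fits the best parametric family to each control class, generates replicate
synthetic score sets matching the unit's size and pathogenic fraction, runs
every candidate method on each replicate, and selects a single method through
three stages: (1) a safety filter removing methods with frequent overconfident
tail errors, (2) mean-rank of MAPE, keeping the top three, and (3) the lowest
mean-rank of PFraction + BFraction among those three. The chosen method is
then applied to the real unit with an out-of-bag bootstrap to produce
conservative posterior estimates and evidence score intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import calibrators as cal
from . import metrics as met
from . import simulate as sim
from .evidence import build_evidence_scale, score_intervals

__all__ = [
    "EligibilityDecision",
    "SelectionOutcome",
    "SelectionConfig",
    "gene_eligibility",
    "candidate_methods",
    "stage1_safety_filter",
    "stage2_rank_mape",
    "stage3_pick",
    "select_and_calibrate",
    "hybrid_route",
]


@dataclass(frozen=True)
class EligibilityDecision:
    eligible: bool
    condition: str
    n_p: int
    n_b: int
    sum: int
    pfrac: float | None


def gene_eligibility(n_p, n_b):
    """Tiered eligibility: size range paired with an allowed class balance.

    50-99 labeled variants need 0.4 <= pfrac <= 0.7; 100-299 allow
    0.1 <= pfrac <= 0.9; >= 300 allow 0.05 <= pfrac <= 0.99 with at least 10
    benign controls. The size ranges are disjoint, so at most one condition
    can hold.
    """
    n_p, n_b = int(n_p), int(n_b)
    if n_p < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    total = n_p + n_b
    pfrac = n_p / total if total else None
    cond = "none"
    if total and 50 <= total <= 99 and 0.4 <= pfrac <= 0.7:
        cond = "cond1"
    elif total and 100 <= total <= 299 and 0.1 <= pfrac <= 0.9:
        cond = "cond2"
    elif total >= 300 and 0.05 <= pfrac <= 0.99 and n_b >= 10:
        cond = "cond3"
    return EligibilityDecision(
        eligible=cond != "none", condition=cond, n_p=n_p, n_b=n_b,
        sum=total, pfrac=pfrac,
    )


@dataclass
class SelectionConfig:
    """Knobs of the selection pipeline.

    ``n_replicates=30`` and ``n_boot=1000`` reproduce the full protocol;
    the smaller defaults keep a desk-scale run fast. ``stage_posterior``
    chooses whether stage metrics are computed from each method's plain fit
    ("point") or from the conservative out-of-bag envelope ("conservative",
    the full-protocol setting).
    """

    n_replicates: int = 10
    n_test: int = 1000
    n_boot: int = 200
    stage_posterior: str = "point"
    stage1_violation_rate: float = 0.25
    stage1_pct75_limit: float = 2.0
    stage1_max_limit: float = 3.0
    include_local: bool = True
    nn_max_epochs: int = 400
    local_window_fracs: tuple = cal.LOCAL_WINDOW_FRACS
    local_gnomad_fracs: tuple = cal.LOCAL_GNOMAD_FRACS


@dataclass
class SelectionOutcome:
    survivors_stage1: list
    top3_stage2: list
    chosen: str | None
    per_method_scores: dict = field(default_factory=dict)
    chosen_options: dict = field(default_factory=dict)


def candidate_methods(config, has_unlabeled):
    """(name, method, options) triples entering selection.

    The nine local-posterior configurations compete as distinct candidates
    alongside the ten post-hoc methods.
    """
    cands = [
        (m, m, {"max_epochs": config.nn_max_epochs} if m == "mono_post_nn" else {})
        for m in cal.METHODS
        if m != "local_posterior"
    ]
    if config.include_local:
        for w in config.local_window_fracs:
            for g in config.local_gnomad_fracs:
                if g > 0 and not has_unlabeled:
                    continue
                cands.append(
                    (
                        f"local_posterior_w{w:g}_g{g:g}",
                        "local_posterior",
                        {"window_frac": w, "gnomad_frac": g},
                    )
                )
    return cands


def stage1_safety_filter(
    region_errors, violation_rate=0.25, pct75_limit=2.0, max_limit=3.0
):
    """Remove methods with frequent overconfident tail errors.

    ``region_errors``: method -> list of per-replicate summaries (objects or
    dicts with pct75/max errors per region). A replicate violates when its
    75th-percentile overconfidence error exceeds ``pct75_limit`` or its
    maximum exceeds ``max_limit`` in either region; methods violating in more
    than ``violation_rate`` of replicates are dropped.
    """
    survivors, rates = [], {}
    for method, summaries in region_errors.items():
        violations = 0
        for s in summaries:
            get = s.get if isinstance(s, dict) else lambda k, _s=s: getattr(_s, k)
            if (
                get("pct75_err_P") > pct75_limit
                or get("max_err_P") > max_limit
                or get("pct75_err_B") > pct75_limit
                or get("max_err_B") > max_limit
            ):
                violations += 1
        rate = violations / len(summaries) if summaries else 1.0
        rates[method] = rate
        if rate <= violation_rate:
            survivors.append(method)
    return survivors, rates


def _mean_ranks(values_by_method, methods):
    """Mean across replicates of the per-replicate rank (1 = lowest)."""
    mat = np.array([values_by_method[m] for m in methods], dtype=float)
    ranks = np.apply_along_axis(rankdata, 0, mat)
    return dict(zip(methods, ranks.mean(axis=1)))


def stage2_rank_mape(survivors, mape_by_method, top_k=3):
    """Keep the ``top_k`` survivors with the lowest mean MAPE rank."""
    if not survivors:
        return [], {}
    mean_rank = _mean_ranks(mape_by_method, survivors)
    # alphabetical tie-break keeps selection deterministic
    ordered = sorted(survivors, key=lambda m: (mean_rank[m], m))
    return ordered[:top_k], mean_rank


def stage3_pick(top3, overconf_by_method):
    """Among finalists, the lowest mean rank of PFraction + BFraction wins."""
    if not top3:
        return None, {}
    mean_rank = _mean_ranks(overconf_by_method, top3)
    return min(top3, key=lambda m: (mean_rank[m], m)), mean_rank


def _stage_posterior(name, method, options, boot_set, test_scores, scale,
                     prior, config, seed):
    """A candidate's posterior for the test scores of one replicate."""
    options = dict(options)
    if method == "local_posterior":
        options["target_prior"] = prior
    if config.stage_posterior == "conservative":
        env = cal.oob_bootstrap_envelope(
            boot_set, method, scale, n_boot=config.n_boot, seed=seed,
            target_prior=prior, options=options,
        )
        return env.conservative_on(test_scores)
    fit = cal.fit_calibrator(method, boot_set, options)
    return cal.prior_shift_correct(fit(test_scores), fit.train_alpha, prior)


def select_and_calibrate(unit, prior, config=None, seed=0):
    """Run the full data-adaptive pipeline on one calibration unit.

    Returns ``(outcome, envelope, intervals, scale)``; ``chosen`` is None and
    the remaining entries are None when every method is filtered out.
    """
    config = config or SelectionConfig()
    scale = build_evidence_scale(prior)
    fit_p = sim.select_best_family(unit.pathogenic_scores)
    fit_b = sim.select_best_family(unit.benign_scores)
    pair = sim.DistributionPair(
        family_P=fit_p.family, params_P=fit_p.params,
        family_B=fit_b.family, params_B=fit_b.params,
    )
    scn = sim.SimulationScenario(
        pair=pair, n=unit.n_p + unit.n_b, alpha_obs=unit.alpha_obs,
        alpha_true=prior, n_test=config.n_test,
    )

    cands = candidate_methods(config, unit.unlabeled_scores is not None)
    summaries = {name: [] for name, _, _ in cands}
    failures = {name: 0 for name, _, _ in cands}

    for r in range(config.n_replicates):
        rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % 2**31)
        rep_scn = scn.with_seed(rep_seed)
        boot_set = sim.sample_calibration_set(rep_scn)
        if unit.unlabeled_scores is not None:
            boot_set.unlabeled_scores = unit.unlabeled_scores
        test = sim.sample_test_set(rep_scn, scale=scale)
        for name, method, options in cands:
            try:
                est = _stage_posterior(
                    name, method, options, boot_set, test.scores, scale,
                    prior, config, rep_seed,
                )
                summaries[name].append(
                    met.miscalibration(est, test.posterior_true, scale)
                )
            except (cal.CalibrationFitError, ValueError):
                failures[name] += 1

    # a method must have produced a summary on every replicate to compete
    complete = [n for n in summaries if len(summaries[n]) == config.n_replicates]
    survivors, rates = stage1_safety_filter(
        {n: summaries[n] for n in complete},
        violation_rate=config.stage1_violation_rate,
        pct75_limit=config.stage1_pct75_limit,
        max_limit=config.stage1_max_limit,
    )
    mape = {n: [s.mape for s in summaries[n]] for n in complete}
    overconf = {
        n: [(s.pfraction or 0.0) + (s.bfraction or 0.0) for s in summaries[n]]
        for n in complete
    }
    top3, mape_rank = stage2_rank_mape(survivors, mape)
    chosen, over_rank = stage3_pick(top3, overconf)

    outcome = SelectionOutcome(
        survivors_stage1=survivors,
        top3_stage2=top3,
        chosen=chosen,
        per_method_scores={
            n: {
                "violation_rate": rates.get(n),
                "mean_mape": float(np.mean(mape[n])) if n in mape else None,
                "mape_rank": mape_rank.get(n),
                "overconf_rank": over_rank.get(n),
                "failures": failures[n],
            }
            for n in summaries
        },
    )
    if chosen is None:
        return outcome, None, None, scale

    chosen_method, chosen_options = next(
        (m, o) for n, m, o in cands if n == chosen
    )
    chosen_options = dict(chosen_options)
    if chosen_method == "local_posterior":
        chosen_options["target_prior"] = prior
    outcome.chosen_options = chosen_options
    env = cal.oob_bootstrap_envelope(
        unit, chosen_method, scale, n_boot=config.n_boot, seed=seed,
        target_prior=prior, options=chosen_options,
    )
    grid = np.linspace(0.0, 1.0, 1001)
    intervals = score_intervals(grid, env.conservative_on(grid), scale)
    return outcome, env, intervals, scale


def hybrid_route(eligibility, gene_calibrated, cluster_id=None,
                 cluster_calibrated=False, non_domain_calibrated=False):
    """Route a variant to gene-specific, domain-aggregate, or no calibration."""
    if eligibility.eligible and gene_calibrated:
        return "gene_specific"
    if cluster_id is not None and cluster_calibrated:
        return f"domain_aggregate:{cluster_id}"
    if non_domain_calibrated:
        return "domain_aggregate:non_domain"
    return "uncalibrated"
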