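"""Model/Results interface to the calibration framework.

:class:`VEPCalibrationModel` wraps one calibration unit (a gene or a domain
cluster): construct it from a :class:`~vepcal.calibrators.ScoreSet` or a
DataFrame of scores and labels plus a prior probability of pathogenicity,
call :meth:`fit`, and receive a :class:`VEPCalibrationResults` carrying the
selected calibration method, the conservative posterior envelope, the
per-level evidence score intervals, and prediction/summary utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibrators import ScoreSet
from .evidence import continuous_points, lr_from_posterior
from .select import SelectionConfig, gene_eligibility, select_and_calibrate

__all__ = ["VEPCalibrationModel", "VEPCalibrationResults"]


class VEPCalibrationModel:
    """Data-adaptive evidence calibration for one gene or domain cluster.

    Parameters
    ----------
    data : ScoreSet
        Pathogenic/benign control scores (and optionally unlabeled population
        scores) for the unit.
    prior : float
        Prior probability of pathogenicity for the unit, e.g. from
        :func:`vepcal.priors.bootstrap_prior`.
    config : SelectionConfig, optional
        Selection-pipeline settings (replicates, bootstrap rounds, ...).
    """

    def __init__(self, data, prior, config=None):
        if not isinstance(data, ScoreSet):
            raise TypeError("data must be a ScoreSet")
        self.data = data
        self.prior = float(prior)
        self.config = config or SelectionConfig()
        self.eligibility = gene_eligibility(data.n_p, data.n_b)

    @classmethod
    def from_dataframe(cls, df, prior, score_col="score", label_col="label",
                       unit_id="", config=None):
        """Build from a long table with P/B/U labels."""
        u = df.loc[df[label_col] == "U", score_col].to_numpy(dtype=float)
        data = ScoreSet(
            pathogenic_scores=df.loc[df[label_col] == "P", score_col].to_numpy(
                dtype=float
            ),
            benign_scores=df.loc[df[label_col] == "B", score_col].to_numpy(
                dtype=float
            ),
            unlabeled_scores=u if len(u) else None,
            unit_id=unit_id,
        )
        return cls(data, prior, config=config)

    def fit(self, seed=0):
        outcome, envelope, intervals, scale = select_and_calibrate(
            self.data, self.prior, config=self.config, seed=seed
        )
        return VEPCalibrationResults(self, outcome, envelope, intervals, scale)


class VEPCalibrationResults:
    """Fitted calibration for one unit."""

    def __init__(self, model, outcome, envelope, intervals, scale):
        self.model = model
        self.outcome = outcome
        self.envelope = envelope
        self.intervals = intervals
        self.scale = scale

    @property
    def method(self):
        return self.outcome.chosen

    @property
    def calibrated(self):
        return self.outcome.chosen is not None and self.envelope is not None

    def predict(self, scores):
        """Posterior, LR, and evidence points for new scores (DataFrame)."""
        if not self.calibrated:
            raise RuntimeError("unit is uncalibrated; no posterior available")
        scores = np.asarray(scores, dtype=float)
        post = self.envelope.conservative_on(scores)
        lr = lr_from_posterior(post, self.scale.prior)
        ep = continuous_points(lr, self.scale)
        points = np.clip(np.trunc(ep).astype(int), -4, 4)
        return pd.DataFrame(
            {
                "score": scores,
                "posterior": post,
                "lr": lr,
                "ep_continuous": ep,
                "points": points,
            }
        )

    def summary(self):
        """Plain-text summary of the fitted calibration."""
        lines = [
            "VEP calibration results",
            "=" * 55,
            f"unit:              {self.model.data.unit_id or '(unnamed)'}",
            f"controls:          {self.model.data.n_p} P / {self.model.data.n_b} B",
            f"eligibility:       {self.model.eligibility.condition}",
            f"prior:             {self.model.prior:.4f}",
            f"LR(+1) threshold:  {self.scale.lr1:.3f}",
            f"selected method:   {self.method or 'none (uncalibrated)'}",
        ]
        if self.calibrated:
            lines.append(
                f"stage-1 survivors: {len(self.outcome.survivors_stage1)}"
            )
            lines.append("evidence score intervals (conservative posterior):")
            for level in (4, 3, 2, 1, -1, -2, -3, -4):
                ivs = self.intervals.get(level, [])
                if ivs:
                    txt = ", ".join(f"[{lo:.3f}, {hi:.3f}]" for lo, hi in ivs)
                    lines.append(f"  {level:+d} points: {txt}")
        return "\n".join(lines)

    def plot_posterior(self, ax=None):
        """Posterior envelope and per-level thresholds on the score axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        env = self.envelope
        ax.fill_between(env.grid, env.lower_05, env.upper_95, alpha=0.25,
                        label="5th-95th pct bootstrap")
        ax.plot(env.grid, env.point_estimate, label="point estimate")
        ax.plot(env.grid, env.conservative, "--", label="conservative")
        for level, thr in self.scale.posterior_thresholds.items():
            ax.axhline(thr, color="grey", lw=0.4)
        ax.set_xlabel("predictor score")
        ax.set_ylabel("posterior P(pathogenic)")
        ax.legend()
        return ax
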