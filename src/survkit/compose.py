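"""Prediction-type composition pipelines.

Survival learners emit different, not directly comparable prediction types:
a risk ranking cannot be scored by a distribution measure.  Two compositors
close the gap so that any learner can make any prediction type:

* :func:`compose_distr` turns a linear-predictor (or crank) prediction into
  a full survival distribution by modulating a baseline curve ``S_0`` under
  a proportional-hazards, accelerated-failure-time or proportional-odds
  model form.
* :func:`compose_crank` turns a distribution prediction into a risk ranking
  (and optionally a survival-time response) via a summary functional — the
  restricted mean or the median.

:class:`DistrCompositor` and :class:`CrankCompositor` wrap these as
meta-estimators so a composed learner drops into resampling and
benchmarking like any other.
"""

from __future__ import annotations

import logging

import numpy as np

from .distribution import SurvDistribution, SurvPrediction, dist_mean, dist_median, eval_survival
from .estimators import SurvivalEstimator, KaplanMeier, NelsonAalen
from .exceptions import ChannelError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["compose_distr", "compose_crank", "DistrCompositor", "CrankCompositor"]

_FORMS = ("ph", "aft", "po")


def compose_distr(
    pred: SurvPrediction,
    baseline: SurvDistribution,
    form: str = "ph",
    channel: str = "lp",
) -> SurvPrediction:
    """Build a distr channel from a linear predictor and a baseline curve.

    With ``eta_i`` the chosen channel value and ``S_0`` the single baseline
    survival curve on grid ``t_1..t_m``:

    * ``ph``:  ``S_i(t) = S_0(t) ** exp(eta_i)`` — constant hazard ratio
      ``exp(eta_i)``; higher eta = higher risk.
    * ``aft``: ``S_i(t) = S_0(t * exp(-eta_i))`` via the step convention —
      higher eta stretches time, so longer survival.
    * ``po``:  ``S_i(t) = S_0(t) / (exp(eta_i) + (1 - exp(eta_i)) S_0(t))``
      — the odds of death are multiplied by the constant ``exp(eta_i)``.

    All three reduce to the baseline exactly at ``eta = 0``.  Composing from
    the crank channel is allowed (the formulas are applied verbatim) but the
    resulting distribution is only rank-meaningful, which is logged.
    """
    if form not in _FORMS:
        raise ValidationError(f"unknown composition form {form!r}; choose from {_FORMS}")
    if channel not in ("lp", "crank"):
        raise ValidationError(f"composition channel must be 'lp' or 'crank', got {channel!r}")
    pred.require(channel)
    if baseline.n != 1:
        raise ValidationError("baseline must be a single survival curve")
    eta = np.asarray(getattr(pred, channel), dtype=float)
    if channel == "crank":
        logger.warning(
            "composing a distribution from the crank channel: the result is "
            "only rank-meaningful"
        )
    S0 = baseline.S[0]
    grid = baseline.grid
    if form == "ph":
        S = S0[None, :] ** np.exp(eta)[:, None]
    elif form == "aft":
        warped = grid[None, :] * np.exp(-eta)[:, None]  # (n, m), all >= 0
        S = np.vstack([
            eval_survival(baseline, warped[i])[0] for i in range(len(eta))
        ]) if len(eta) else np.zeros((0, grid.size))
    else:  # po
        e = np.exp(eta)[:, None]
        S = S0[None, :] / (e + (1.0 - e) * S0[None, :])
    distr = SurvDistribution(grid=grid, S=S)
    return pred.with_channels(distr=distr)


def compose_crank(
    pred: SurvPrediction,
    summary: str = "mean",
    overwrite_response: bool = False,
) -> SurvPrediction:
    """Derive crank (and optionally response) from the distr channel.

    ``s_i`` is the distribution's restricted mean or median survival time;
    ``crank_i = -s_i`` (shorter expected survival = higher risk).  The
    response channel is set to ``s_i`` when absent or when
    ``overwrite_response`` is true.
    """
    pred.require("distr")
    if summary == "mean":
        s = dist_mean(pred.distr)
    elif summary == "median":
        s = dist_median(pred.distr)
    else:
        raise ValidationError(f"summary must be 'mean' or 'median', got {summary!r}")
    response = s if (overwrite_response or pred.response is None) else pred.response
    return pred.with_channels(crank=-s, response=response)


class DistrCompositor(SurvivalEstimator):
    """Meta-learner: fit a wrapped learner plus a baseline estimator, then
    compose the learner's lp/crank prediction into a distribution.

    Parameters
    ----------
    learner : SurvivalEstimator
        The wrapped model; must emit the chosen channel.
    estimator : {"kaplan", "nelson"}, default "kaplan"
        Baseline survival-curve estimator fitted on the training data.
    form : {"ph", "aft", "po"}, default "ph"
    channel : {"lp", "crank"}, default "lp"
    """

    def __init__(self, learner=None, estimator: str = "kaplan", form: str = "ph",
                 channel: str = "lp"):
        self.learner = learner
        self.estimator = estimator
        self.form = form
        self.channel = channel

    @property
    def predict_types(self) -> frozenset[str]:
        base = self.learner.predict_types if self.learner is not None else frozenset()
        return base | {"distr"}

    def fit(self, X, y):
        if self.learner is None:
            raise ValidationError("DistrCompositor requires a wrapped learner")
        if self.channel not in self.learner.predict_types:
            raise ChannelError(
                f"wrapped learner does not emit channel {self.channel!r}"
            )
        baseline_cls = {"kaplan": KaplanMeier, "nelson": NelsonAalen}.get(self.estimator)
        if baseline_cls is None:
            raise ValidationError(f"unknown baseline estimator {self.estimator!r}")
        self.learner_ = self.learner.fit(X, y)
        self.baseline_learner_ = baseline_cls().fit(X, y)
        self.baseline_ = self.baseline_learner_.baseline_
        return self

    def predict_surv(self, X) -> SurvPrediction:
        pred = self.learner_.predict_surv(X)
        out = compose_distr(pred, self.baseline_, form=self.form, channel=self.channel)
        return out.with_channels()  # re-validate


class CrankCompositor(SurvivalEstimator):
    """Meta-learner composing crank/response from a distr-emitting learner."""

    def __init__(self, learner=None, summary: str = "mean",
                 overwrite_response: bool = False):
        self.learner = learner
        self.summary = summary
        self.overwrite_response = overwrite_response

    @property
    def predict_types(self) -> frozenset[str]:
        base = self.learner.predict_types if self.learner is not None else frozenset()
        return base | {"crank", "response"}

    def fit(self, X, y):
        if self.learner is None:
            raise ValidationError("CrankCompositor requires a wrapped learner")
        if "distr" not in self.learner.predict_types:
            raise ChannelError("wrapped learner does not emit a distr channel")
        self.learner_ = self.learner.fit(X, y)
        return self

    def predict_surv(self, X) -> SurvPrediction:
        return compose_crank(self.learner_.predict_surv(X), summary=self.summary,
                             overwrite_response=self.overwrite_response)
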