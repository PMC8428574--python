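"""Censoring-aware evaluation measures for survival predictions.

Three families, mirroring how survival models are usually judged:

* **Discrimination** — Harrell's and Uno's concordance over the crank
  channel, and a cumulative/dynamic time-dependent AUC.
* **Scoring rules** — the Graf (integrated Brier) score, the IPCW integrated
  log-loss and the Schmid absolute score over the distr channel.  All three
  share one inverse-probability-of-censoring-weighting skeleton: at an
  evaluation time ``t``, a subject observed to die by ``t`` contributes a
  loss on ``1 - S_i(t)`` weighted by ``1/G(T_i-)``; a subject still at risk
  past ``t`` contributes a loss on ``S_i(t)`` weighted by ``1/G(t)``; a
  subject censored by ``t`` contributes nothing.  ``G`` is the Kaplan-Meier
  estimate of the censoring survival function.
* **Calibration** — van Houwelingen's calibration slope (refit a
  one-covariate Cox model on the predicted lp; 1 = well calibrated) and the
  maximal gap between the mean predicted curve and the Kaplan-Meier
  estimate of the test data.

The integrated variants average the pointwise score over the evaluation
grid by the trapezoid rule, normalized by the grid range; the default grid
is the unique event times of the test set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._constants import EPS
from .distribution import SurvDistribution, SurvPrediction, eval_survival
from .exceptions import ChannelError, ScoringError, ValidationError
from .nonparametric import CensoringDistribution, kaplan_meier_curve

__all__ = [
    "CensoringDistribution",
    "harrell_c",
    "uno_c",
    "graf_score",
    "integrated_logloss",
    "schmid_score",
    "houwelingen_beta",
    "uno_auc",
    "km_calibration",
    "KMCalibrationResult",
    "Measure",
    "MEASURES",
]


def _check_vectors(*arrays):
    out = [np.asarray(a, dtype=float).ravel() for a in arrays]
    n = len(out[0])
    if any(len(a) != n for a in out):
        raise ValidationError(f"input vectors have unequal lengths {[len(a) for a in out]}")
    return out


# --------------------------------------------------------------------------- #
# concordance
# --------------------------------------------------------------------------- #


def harrell_c(crank, time, status) -> float:
    """Harrell's concordance index over the risk ranking.

    A pair ``(i, j)`` is comparable iff ``T_i < T_j`` and subject ``i`` had
    the event; it is concordant iff ``crank_i > crank_j`` (earlier death,
    higher risk).  Tied cranks count one half.
    """
    crank, time, status = _check_vectors(crank, time, status)
    comp = (time[:, None] < time[None, :]) & (status[:, None] == 1)
    n_comp = comp.sum()
    if n_comp == 0:
        raise ScoringError("no comparable pairs (all subjects censored or tied in time)")
    conc = comp & (crank[:, None] > crank[None, :])
    ties = comp & (crank[:, None] == crank[None, :])
    return float((conc.sum() + 0.5 * ties.sum()) / n_comp)


def uno_c(crank, time, status, G: CensoringDistribution, tau: float | None = None) -> float:
    """Uno's IPCW concordance: comparable pairs are weighted ``1/G(T_i-)^2``
    where ``i`` is the earlier, uncensored member and ``T_i < tau``.

    With no censoring ``G`` is identically 1 and the measure equals
    Harrell's C.  ``tau`` defaults to the largest event time.
    """
    crank, time, status = _check_vectors(crank, time, status)
    if tau is None:
        if status.sum() == 0:
            raise ScoringError("no events: cannot set default tau")
        tau = float(time[status == 1].max())
    w = 1.0 / G.survival_left(time) ** 2
    comp = (time[:, None] < time[None, :]) & (status[:, None] == 1) & (time[:, None] < tau)
    if comp.sum() == 0:
        raise ScoringError("no comparable pairs below tau")
    W = np.where(comp, w[:, None], 0.0)
    total = W.sum()
    if total <= 0:
        raise ScoringError("zero total IPCW weight")
    conc = (crank[:, None] > crank[None, :])
    ties = (crank[:, None] == crank[None, :])
    return float(((W * conc).sum() + 0.5 * (W * ties).sum()) / total)


# --------------------------------------------------------------------------- #
# IPCW scoring rules
# --------------------------------------------------------------------------- #


def _ipcw_score(distr, time, status, G, eval_times, integrated, loss):
    """Shared IPCW skeleton; ``loss(S_dead, S_alive)`` returns the two
    pointwise contributions given survival probabilities."""
    time, status = _check_vectors(time, status)
    if not isinstance(distr, SurvDistribution):
        raise ChannelError("a SurvDistribution (distr channel) is required")
    if distr.n != len(time):
        raise ValidationError(f"distr has {distr.n} rows for {len(time)} subjects")
    if eval_times is None:
        if status.sum() == 0:
            raise ScoringError("no events in test data: supply eval_times explicitly")
        eval_times = np.unique(time[status == 1])
    eval_times = np.asarray(eval_times, dtype=float).ravel()
    if eval_times.size == 0:
        raise ScoringError("empty evaluation grid")
    S = eval_survival(distr, eval_times)  # (n, m)
    dead = (time[:, None] <= eval_times[None, :]) & (status[:, None] == 1)
    alive = time[:, None] > eval_times[None, :]
    w_dead = 1.0 / G.survival_left(time)  # (n,)
    w_alive = 1.0 / G.survival(eval_times)  # (m,)
    L_dead, L_alive = loss(S)
    contrib = dead * L_dead * w_dead[:, None] + alive * L_alive * w_alive[None, :]
    pointwise = contrib.mean(axis=0)  # (m,)
    if not integrated:
        return pointwise
    if eval_times.size == 1 or eval_times[-1] == eval_times[0]:
        return float(pointwise.mean())
    return float(np.trapezoid(pointwise, eval_times) / (eval_times[-1] - eval_times[0]))


def graf_score(distr, time, status, G, eval_times=None, integrated: bool = True):
    """Graf/Brier score: squared error of the predicted event probability.

    ``BS(t) = (1/n) sum_i [ S_i(t)^2 1(T_i<=t, d_i=1)/G(T_i-)
    + (1-S_i(t))^2 1(T_i>t)/G(t) ]``; the integrated variant averages over
    the evaluation grid (trapezoid, range-normalized).
    """
    return _ipcw_score(distr, time, status, G, eval_times, integrated,
                       lambda S: (S ** 2, (1.0 - S) ** 2))


def integrated_logloss(distr, time, status, G, eval_times=None, integrated: bool = True):
    """IPCW log-loss: ``-log(1 - S_i(t))`` for subjects dead by ``t``,
    ``-log S_i(t)`` for subjects at risk past ``t``, probabilities clamped
    to ``[EPS, 1 - EPS]``."""
    def loss(S):
        Sc = np.clip(S, EPS, 1.0 - EPS)
        return -np.log(1.0 - Sc), -np.log(Sc)
    return _ipcw_score(distr, time, status, G, eval_times, integrated, loss)


def schmid_score(distr, time, status, G, eval_times=None, integrated: bool = True):
    """Schmid/absolute score: the absolute-error analogue of the Graf score."""
    return _ipcw_score(distr, time, status, G, eval_times, integrated,
                       lambda S: (S, 1.0 - S))


# --------------------------------------------------------------------------- #
# calibration and time-dependent AUC
# --------------------------------------------------------------------------- #


def houwelingen_beta(lp, time, status) -> float:
    """Calibration slope: refit a one-covariate Cox model with the predicted
    linear predictor as the only covariate and return its coefficient.

    A well calibrated model gives a slope near 1; overfitted effects shrink
    the slope below 1 (a doubled lp halves it).
    """
    from .estimators import CoxPH  # local import avoids a cycle

    lp, time, status = _check_vectors(lp, time, status)
    if np.ptp(lp) == 0:
        raise ValidationError("calibration slope undefined for constant lp")
    if status.sum() == 0:
        raise ValidationError("calibration slope requires at least one event")
    model = CoxPH().fit(lp.reshape(-1, 1), (time, status))
    return float(model.coef_[0])


def uno_auc(marker, time, status, G: CensoringDistribution, t: float) -> float:
    """IPCW cumulative/dynamic AUC at horizon ``t``.

    Cases are subjects with an observed event by ``t`` (weighted
    ``1/G(T_i-)``), controls are subjects still at risk past ``t``; the AUC
    is the weighted probability a case's marker exceeds a control's, ties
    counting one half.
    """
    marker, time, status = _check_vectors(marker, time, status)
    cases = (time <= t) & (status == 1)
    controls = time > t
    if not cases.any():
        raise ScoringError(f"no cases (events by t={t})")
    if not controls.any():
        raise ScoringError(f"no controls (subjects at risk past t={t})")
    w = 1.0 / G.survival_left(time[cases])
    mi = marker[cases][:, None]
    mj = marker[controls][None, :]
    wins = (mi > mj) + 0.5 * (mi == mj)
    num = float((w[:, None] * wins).sum())
    den = float(w.sum() * controls.sum())
    return num / den


@dataclass
class KMCalibrationResult:
    """Maximal discrepancy between the mean predicted curve and the test-set
    Kaplan-Meier estimate, plus the full curve pair for plotting."""

    discrepancy: float
    grid: np.ndarray
    mean_predicted: np.ndarray
    km: np.ndarray

    def __float__(self) -> float:
        return self.discrepancy


def km_calibration(distr, time, status) -> KMCalibrationResult:
    """Numeric surrogate for the visual average-prediction-vs-KM check:
    ``max_t | S_bar(t) - KM(t) |`` on the test data's KM grid."""
    time, status = _check_vectors(time, status)
    grid, km = kaplan_meier_curve(time, status)
    mean_pred = eval_survival(distr, grid).mean(axis=0)
    return KMCalibrationResult(
        discrepancy=float(np.max(np.abs(mean_pred - km))),
        grid=grid,
        mean_predicted=mean_pred,
        km=km,
    )


# --------------------------------------------------------------------------- #
# measure registry for resampling / benchmarking / CLI
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class Measure:
    """A named measure with its required prediction channel and direction.

    Scoring a prediction that lacks ``required_channel`` raises
    :class:`ChannelError`; there is no silent fallback between channels.
    """

    id: str
    required_channel: str
    direction: str  # "minimize" | "maximize"
    needs_ipcw: bool = False
    needs_horizon: bool = False
    integrated: bool = False

    def __call__(self, pred: SurvPrediction, time, status,
                 G: CensoringDistribution | None = None,
                 at_time: float | None = None) -> float:
        pred.require(self.required_channel)
        if self.needs_ipcw and G is None:
            G = CensoringDistribution.fit(time, status)
        if self.id == "surv.cindex":
            return harrell_c(pred.crank, time, status)
        if self.id == "surv.cindex.uno":
            return uno_c(pred.crank, time, status, G, tau=at_time)
        if self.id == "surv.graf":
            return graf_score(pred.distr, time, status, G)
        if self.id == "surv.intlogloss":
            return integrated_logloss(pred.distr, time, status, G)
        if self.id == "surv.schmid":
            return schmid_score(pred.distr, time, status, G)
        if self.id == "surv.calib.beta":
            return houwelingen_beta(pred.lp, time, status)
        if self.id == "surv.calib.km":
            return km_calibration(pred.distr, time, status).discrepancy
        if self.id == "surv.auc":
            status_arr = np.asarray(status)
            t = at_time
            if t is None:
                t = float(np.median(np.asarray(time)[status_arr == 1]))
            return uno_auc(pred.crank, time, status, G, t)
        raise ValidationError(f"unknown measure id {self.id!r}")


MEASURES: dict[str, Measure] = {
    m.id: m
    for m in [
        Measure("surv.cindex", "crank", "maximize"),
        Measure("surv.cindex.uno", "crank", "maximize", needs_ipcw=True),
        Measure("surv.graf", "distr", "minimize", needs_ipcw=True, integrated=True),
        Measure("surv.intlogloss", "distr", "minimize", needs_ipcw=True, integrated=True),
        Measure("surv.schmid", "distr", "minimize", needs_ipcw=True, integrated=True),
        Measure("surv.calib.beta", "lp", "minimize"),
        Measure("surv.calib.km", "distr", "minimize"),
        Measure("surv.auc", "crank", "maximize", needs_ipcw=True, needs_horizon=True),
    ]
}
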