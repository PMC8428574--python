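"""Reference survival learners with a scikit-learn estimator interface.

Each learner declares the prediction channels it emits (``predict_types``)
and returns a :class:`~survkit.distribution.SurvPrediction` from
:meth:`predict_surv`.  The plain :meth:`predict` returns the ``crank``
channel (a continuous risk score, larger = higher risk), which is what
sklearn model-selection utilities expect from a risk model.

``y`` may be given as an ``(n, 2)`` array ``[time, status]``, a
``(time, status)`` tuple, or a structured array with fields resembling
scikit-survival's ``(event, time)`` convention.  The
``fit_*`` module functions accept a :class:`~survkit.task.SurvTask` directly.

Any object with ``fit(X, y)``, ``predict_surv(X) -> SurvPrediction`` and a
``predict_types`` attribute plugs into the resampling and benchmarking
machinery — that contract is the extension point for wrapping external
machine-learning engines (forests, boosting, neural networks), which this
package deliberately does not ship.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from ._constants import EPS
from .distribution import SurvDistribution, SurvPrediction, dist_mean
from .exceptions import ConvergenceError, ValidationError
from .nonparametric import kaplan_meier_curve, nelson_aalen_curve, risk_table
from .task import SurvTask

__all__ = [
    "SurvivalEstimator",
    "KaplanMeier",
    "NelsonAalen",
    "CoxPH",
    "WeibullAFT",
    "fit_kaplan_meier",
    "fit_nelson_aalen",
    "fit_coxph",
    "fit_weibull_aft",
    "predict",
    "LEARNERS",
    "make_learner",
    "cox_partial_loglik",
    "breslow_baseline",
]


def as_time_status(y) -> tuple[np.ndarray, np.ndarray]:
    """Normalize the outcome argument to ``(time, status)`` float/int arrays."""
    if isinstance(y, SurvTask):
        return y.time, y.status
    if isinstance(y, tuple) and len(y) == 2:
        time, status = y
    elif hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        names = y.dtype.names
        time_field = next(n for n in names if "time" in n.lower() or n.lower() in ("t", "futime"))
        event_field = next(n for n in names if n != time_field)
        time, status = y[time_field], y[event_field]
    else:
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValidationError(
                "y must be an (n, 2) array [time, status], a (time, status) "
                "tuple, or a structured array"
            )
        time, status = y[:, 0], y[:, 1]
    return np.asarray(time, dtype=float).ravel(), np.asarray(status).astype(int).ravel()


class SurvivalEstimator(BaseEstimator):
    """Base class: channel declaration plus shared validation."""

    predict_types: frozenset[str] = frozenset()

    def _validate(self, X, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        time, status = as_time_status(y)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        task = SurvTask(X=X, time=time, status=status)  # runs full validation
        return task.X, task.time, task.status

    def fit_task(self, task: SurvTask) -> "SurvivalEstimator":
        return self.fit(task.X, (task.time, task.status))

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.predict_surv(X).crank)

    def predict_surv(self, X) -> SurvPrediction:  # pragma: no cover - abstract
        raise NotImplementedError


class KaplanMeier(SurvivalEstimator):
    """Product-limit estimator of the marginal survival function.

    Ignores features: every test subject receives the training curve.  The
    crank channel is ``-RMST`` of that curve (identical across subjects), so
    concordance against it is pure ties.
    """

    predict_types = frozenset({"distr", "crank"})

    def fit(self, X, y):
        X, time, status = self._validate(X, y)
        self.n_features_in_ = X.shape[1]
        grid, S = kaplan_meier_curve(time, status)
        self.grid_, self.surv_ = grid, S
        self.baseline_ = SurvDistribution(grid=grid, S=S.reshape(1, -1))
        return self

    def predict_surv(self, X) -> SurvPrediction:
        n = np.atleast_2d(np.asarray(X, dtype=float)).shape[0] if np.ndim(X) > 1 else len(X)
        distr = self.baseline_.replicate(n)
        crank = np.repeat(-dist_mean(self.baseline_), n)
        return SurvPrediction(n=n, crank=crank, distr=distr, provenance="kaplan")


class NelsonAalen(SurvivalEstimator):
    """Nelson-Aalen cumulative-hazard estimator; survival via ``exp(-H)``."""

    predict_types = frozenset({"distr", "crank"})

    def fit(self, X, y):
        X, time, status = self._validate(X, y)
        self.n_features_in_ = X.shape[1]
        grid, H = nelson_aalen_curve(time, status)
        self.grid_, self.cum_hazard_ = grid, H
        self.baseline_ = SurvDistribution(grid=grid, S=np.exp(-H).reshape(1, -1))
        return self

    def predict_surv(self, X) -> SurvPrediction:
        n = np.atleast_2d(np.asarray(X, dtype=float)).shape[0] if np.ndim(X) > 1 else len(X)
        distr = self.baseline_.replicate(n)
        crank = np.repeat(-dist_mean(self.baseline_), n)
        return SurvPrediction(n=n, crank=crank, distr=distr, provenance="nelson")


# --------------------------------------------------------------------------- #
# Cox proportional hazards
# --------------------------------------------------------------------------- #


def _cox_sufficient_stats(X, time, status):
    """Sort ascending by time and precompute per-event-time risk-set indices."""
    order = np.argsort(time, kind="mergesort")
    Xs, ts, ds = X[order], time[order], status[order]
    grid, d, _ = risk_table(ts, ds)
    first = np.searchsorted(ts, grid, side="left")  # start of each risk set
    # sum of covariates over subjects who die at each event time
    s = np.vstack([Xs[(ts == t) & (ds == 1)].sum(axis=0) for t in grid]) if grid.size else np.zeros((0, X.shape[1]))
    return Xs, grid, d, first, s


def cox_partial_loglik(beta, X, time, status) -> float:
    """Breslow-tie Cox partial log-likelihood at ``beta``.

    ``l(beta) = sum_j [ s_j' beta - d_j log sum_{i in R(t_j)} exp(x_i' beta) ]``
    with ``s_j`` the covariate sum over the ``d_j`` events at ``t_j`` and
    ``R(t_j) = {i : T_i >= t_j}``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    beta = np.asarray(beta, dtype=float).ravel()
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    Xs, grid, d, first, s = _cox_sufficient_stats(X, time, status)
    eta = Xs @ beta
    shift = eta.max() if eta.size else 0.0  # overflow guard
    ce = np.cumsum(np.exp(eta - shift)[::-1])[::-1]
    return float(np.sum(s @ beta) - np.sum(d * (np.log(ce[first]) + shift)))


def breslow_baseline(Xc, time, status, beta):
    """Breslow cumulative baseline hazard on the event-time grid:
    ``H_0(t) = sum_{t_j <= t} d_j / sum_{i in R(t_j)} exp(x_i' beta)``.

    At ``beta = 0`` this reduces exactly to the Nelson-Aalen estimator.
    """
    Xs, grid, d, first, _ = _cox_sufficient_stats(np.asarray(Xc, dtype=float),
                                                  np.asarray(time, dtype=float),
                                                  np.asarray(status))
    e = np.exp(Xs @ np.asarray(beta, dtype=float))
    ce = np.cumsum(e[::-1])[::-1]
    return grid, np.cumsum(d / ce[first])


class CoxPH(SurvivalEstimator):
    """Cox proportional-hazards model via Newton-Raphson on the Breslow
    partial likelihood, with a Breslow baseline cumulative hazard.

    Features are centered internally; the linear predictor is reported on the
    centered scale, ``lp_i = (x_i - x_bar)' beta``.  Tied event times are
    handled with the Breslow approximation.  Convergence requires
    ``max |gradient| <= tol``.  Monotone-likelihood separation (the MLE at
    infinity) is flagged and raised as :class:`ConvergenceError` naming the
    covariate when a coefficient escapes ``[-beta_bound, beta_bound]``, when
    the per-covariate linear-predictor spread ``|beta_j| * range(x_j)``
    exceeds ``lp_bound`` (relative risks beyond ``exp(lp_bound)`` are
    numerically infinite), or when a step cannot increase the partial
    likelihood after halving.

    Parameters
    ----------
    tol : float, default 1e-9
        Convergence threshold on the max absolute score component.
    max_iter : int, default 100
    beta_bound : float, default 50.0
        Absolute divergence guard on individual coefficients.
    lp_bound : float, default 18.0
        Scale-aware divergence guard on ``|beta_j| * range(x_j)``.
    """

    predict_types = frozenset({"lp", "crank", "distr"})

    def __init__(self, tol: float = 1e-9, max_iter: int = 100,
                 beta_bound: float = 50.0, lp_bound: float = 18.0):
        self.tol = tol
        self.max_iter = max_iter
        self.beta_bound = beta_bound
        self.lp_bound = lp_bound

    def fit(self, X, y):
        X, time, status = self._validate(X, y)
        if X.shape[0] < 2:
            raise ValidationError("Cox PH requires at least two subjects")
        if status.sum() < 1:
            raise ValidationError("Cox PH requires at least one event")
        const = np.flatnonzero(np.ptp(X, axis=0) == 0)
        if const.size:
            raise ValidationError(
                f"constant covariate(s) at column(s) {const.tolist()}: "
                "information matrix is singular"
            )
        self.train_mean_ = X.mean(axis=0)
        Xc = X - self.train_mean_
        beta, n_iter, gnorm = self._newton(Xc, time, status)
        self.coef_ = beta
        self.n_iter_ = n_iter
        self.final_grad_norm_ = gnorm
        self.n_features_in_ = X.shape[1]
        self.baseline_grid_, self.baseline_cum_hazard_ = breslow_baseline(
            Xc, time, status, beta)
        return self

    def _loglik_grad_hess(self, beta, Xs, grid, d, first, s):
        eta = Xs @ beta
        e = np.exp(eta)
        p = Xs.shape[1]
        ce = np.cumsum(e[::-1])[::-1]
        cxe = np.cumsum((Xs * e[:, None])[::-1], axis=0)[::-1]
        xxe = np.einsum("ij,ik->ijk", Xs, Xs) * e[:, None, None]
        cxxe = np.cumsum(xxe[::-1], axis=0)[::-1]
        se, sxe, sxxe = ce[first], cxe[first], cxxe[first]
        ll = float(np.sum(s @ beta) - np.sum(d * np.log(se)))
        mean = sxe / se[:, None]
        grad = s.sum(axis=0) - (d[:, None] * mean).sum(axis=0)
        outer = np.einsum("jk,jl->jkl", mean, mean)
        hess = -np.einsum("j,jkl->kl", d, sxxe / se[:, None, None] - outer)
        return ll, grad, hess

    def _newton(self, Xc, time, status):
        Xs, grid, d, first, s = _cox_sufficient_stats(Xc, time, status)
        p = Xc.shape[1]
        beta = np.zeros(p)
        ll, grad, hess = self._loglik_grad_hess(beta, Xs, grid, d, first, s)
        for it in range(1, self.max_iter + 1):
            gnorm = float(np.max(np.abs(grad)))
            if gnorm <= self.tol:
                return beta, it - 1, gnorm
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError as err:
                raise ConvergenceError(f"singular information matrix: {err}") from err
            new_beta = beta + step
            new_ll, new_grad, new_hess = self._loglik_grad_hess(new_beta, Xs, grid, d, first, s)
            halvings = 0
            while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
                halvings += 1
                if halvings > 30:
                    j = int(np.argmax(np.abs(beta)))
                    raise ConvergenceError(
                        f"partial likelihood cannot be increased (covariate "
                        f"column {j}): likely monotone likelihood"
                    )
                step = step / 2.0
                new_beta = beta + step
                new_ll, new_grad, new_hess = self._loglik_grad_hess(new_beta, Xs, grid, d, first, s)
            beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
            if np.max(np.abs(step)) < 1e-10:
                # parameter change at rounding level: the score cannot be
                # reduced further in float64 even if it sits above tol
                return beta, it, float(np.max(np.abs(grad)))
            spread = np.abs(beta) * np.ptp(Xc, axis=0)
            if np.any(np.abs(beta) > self.beta_bound) or np.any(spread > self.lp_bound):
                j = int(np.argmax(spread))
                raise ConvergenceError(
                    f"coefficient for covariate column {j} diverged "
                    f"(|beta_j| * range = {spread[j]:.2f}): monotone "
                    "likelihood (perfect separation of risk)"
                )
        gnorm = float(np.max(np.abs(grad)))
        if gnorm > self.tol:
            raise ConvergenceError(
                f"Newton-Raphson did not converge in {self.max_iter} "
                f"iterations (max |gradient| = {gnorm:.3e})"
            )
        return beta, self.max_iter, gnorm

    def predict_lp(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        return (X - self.train_mean_) @ self.coef_

    def predict_surv(self, X) -> SurvPrediction:
        lp = self.predict_lp(X)
        H0 = self.baseline_cum_hazard_
        S = np.exp(-np.outer(np.exp(lp), H0))
        distr = SurvDistribution(grid=self.baseline_grid_, S=S)
        return SurvPrediction(n=len(lp), lp=lp, crank=lp.copy(), distr=distr,
                              provenance="coxph")


# --------------------------------------------------------------------------- #
# Weibull accelerated failure time
# --------------------------------------------------------------------------- #


class WeibullAFT(SurvivalEstimator):
    """Weibull AFT model, ``log T = mu + x' gamma + sigma W`` with ``W`` a
    standard minimum-Gumbel variable, fitted by maximizing the right-censored
    log-likelihood in the ``(mu, gamma, log sigma)`` parameterization.

    The linear predictor ``lp_i = mu + x_i' gamma`` lives on the log-time
    scale, so *larger lp means longer survival*; the crank channel is
    therefore ``-lp``.  The response channel is the predicted median time
    ``exp(lp + sigma * log log 2)``; distr is the fitted parametric survival
    function evaluated on the training event-time grid.
    """

    predict_types = frozenset({"response", "lp", "crank", "distr"})

    def fit(self, X, y):
        X, time, status = self._validate(X, y)
        if X.shape[0] < 2:
            raise ValidationError("Weibull AFT requires at least two subjects")
        if status.sum() < 1:
            raise ValidationError("Weibull AFT requires at least one event")
        if np.any(time <= 0):
            rows = np.flatnonzero(time <= 0)
            raise ValidationError(f"Weibull AFT requires strictly positive times; "
                                  f"offending rows {rows.tolist()}")
        logt = np.log(time)
        p = X.shape[1]

        def neg_ll_and_grad(theta):
            mu, gamma, logs = theta[0], theta[1 : 1 + p], theta[-1]
            sigma = np.exp(logs)
            z = (logt - mu - X @ gamma) / sigma
            ez = np.exp(np.clip(z, -700, 700))
            ll = np.sum(status * (-logs + z) - ez)
            dz = status - ez  # d(ll)/dz_i
            g_mu = np.sum(dz) / sigma          # d(-ll)/dmu
            g_gamma = (X.T @ dz) / sigma       # d(-ll)/dgamma
            g_logs = np.sum(status + dz * z)   # d(-ll)/dlog(sigma)
            return -ll, np.concatenate([[g_mu], g_gamma, [g_logs]])

        theta0 = np.concatenate([[logt.mean()], np.zeros(p), [np.log(max(logt.std(), 1e-3))]])
        ll0 = -neg_ll_and_grad(theta0)[0]
        res = optimize.minimize(neg_ll_and_grad, theta0, jac=True, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        gnorm = float(np.max(np.abs(res.jac)))
        if not np.isfinite(res.fun) or (-res.fun) < ll0 - 1e-8:
            raise ConvergenceError(
                f"Weibull AFT optimizer failed (final gradient norm {gnorm:.3e})"
            )
        self.intercept_ = float(res.x[0])
        self.coef_ = res.x[1 : 1 + p].copy()
        self.scale_ = float(np.exp(res.x[-1]))
        self.loglik_ = float(-res.fun)
        self.loglik_init_ = float(ll0)
        self.final_grad_norm_ = gnorm
        self.n_features_in_ = p
        grid = np.unique(time[status == 1])
        self.baseline_grid_ = grid
        return self

    def predict_lp(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        return self.intercept_ + X @ self.coef_

    def predict_surv(self, X) -> SurvPrediction:
        lp = self.predict_lp(X)
        grid = self.baseline_grid_
        z = (np.log(grid)[None, :] - lp[:, None]) / self.scale_
        S = np.exp(-np.exp(np.clip(z, -700, 700)))
        distr = SurvDistribution(grid=grid, S=S)
        response = np.exp(lp + self.scale_ * np.log(np.log(2.0)))
        return SurvPrediction(n=len(lp), response=response, lp=lp, crank=-lp,
                              distr=distr, provenance="weibull")


# --------------------------------------------------------------------------- #
# functional wrappers and the learner registry
# --------------------------------------------------------------------------- #


def fit_kaplan_meier(task: SurvTask) -> KaplanMeier:
    return KaplanMeier().fit_task(task)


def fit_nelson_aalen(task: SurvTask) -> NelsonAalen:
    return NelsonAalen().fit_task(task)


def fit_coxph(task: SurvTask, **params) -> CoxPH:
    return CoxPH(**params).fit_task(task)


def fit_weibull_aft(task: SurvTask) -> WeibullAFT:
    return WeibullAFT().fit_task(task)


def predict(model: SurvivalEstimator, X) -> SurvPrediction:
    return model.predict_surv(X)


LEARNERS = {
    "kaplan": KaplanMeier,
    "nelson": NelsonAalen,
    "coxph": CoxPH,
    "weibull": WeibullAFT,
}


def make_learner(learner_id: str, **hyperparams) -> SurvivalEstimator:
    if learner_id not in LEARNERS:
        raise ValidationError(
            f"unknown learner {learner_id!r}; available: {sorted(LEARNERS)}"
        )
    return LEARNERS[learner_id](**hyperparams)
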