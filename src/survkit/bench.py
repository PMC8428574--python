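"""Resampling, benchmarking and score aggregation.

The workflow: specify a task, a list of learners (possibly composition
pipelines) and a resampling plan; each learner is fitted on every training
fold and scored on the held-out fold with the requested measures.  Within a
task every learner sees identical fold indices, so comparisons are paired.
IPCW censoring weights are fitted on the training fold by default (no
outcome information from the test fold enters scoring weights); fitting on
the test fold is available as a sensitivity option.

Aggregation is the macro-average of per-fold scores (with the pooled
alternative left to the caller via the per-fold table).  A learner failure
on a fold is recorded as a failed cell — the rest of the grid completes.
"""

from __future__ import annotations

import logging
import time as _clock
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distribution import SurvPrediction
from .exceptions import ChannelError, ValidationError
from .metrics import MEASURES, CensoringDistribution, Measure
from .task import SurvTask

logger = logging.getLogger(__name__)

__all__ = ["ResamplingPlan", "make_cv", "make_holdout", "resample", "benchmark", "BenchmarkResult"]


@dataclass(frozen=True)
class ResamplingPlan:
    """A concrete, reproducible partition of ``0..n-1`` into test folds."""

    scheme: str
    n: int
    seed: int
    test_folds: tuple  # tuple of index arrays
    stratified: bool = False

    def __post_init__(self):
        all_idx = np.sort(np.concatenate(self.test_folds))
        if self.scheme == "cv":
            if not np.array_equal(all_idx, np.arange(self.n)):
                raise ValidationError("cv folds must partition the index set")
        if any(len(f) == 0 for f in self.test_folds):
            raise ValidationError("every test fold must be non-empty")

    @property
    def k(self) -> int:
        return len(self.test_folds)

    def splits(self):
        """Yield (train_idx, test_idx) pairs."""
        full = np.arange(self.n)
        for test in self.test_folds:
            mask = np.ones(self.n, dtype=bool)
            mask[test] = False
            yield full[mask], np.asarray(test)


def make_cv(task: SurvTask, k: int, seed: int = 0, stratify: bool = False) -> ResamplingPlan:
    """Deterministic k-fold partition; fold sizes differ by at most one.

    With ``stratify=True`` events and censored subjects are partitioned
    separately, so per-fold event counts differ by at most one from exact
    proportionality.
    """
    n = task.n
    if k < 2:
        raise ValidationError(f"cv needs at least 2 folds, got {k}")
    if k > n:
        raise ValidationError(f"cannot make {k} folds from {n} subjects")
    rng = np.random.default_rng(seed)
    if stratify:
        folds = [[] for _ in range(k)]
        for group in (np.flatnonzero(task.status == 1), np.flatnonzero(task.status == 0)):
            perm = rng.permutation(group)
            for slot, chunk in enumerate(np.array_split(perm, k)):
                folds[slot].extend(chunk.tolist())
        test_folds = tuple(np.sort(np.asarray(f, dtype=int)) for f in folds)
    else:
        perm = rng.permutation(n)
        test_folds = tuple(np.sort(chunk) for chunk in np.array_split(perm, k))
    return ResamplingPlan(scheme="cv", n=n, seed=seed, test_folds=test_folds,
                          stratified=stratify)


def make_holdout(task: SurvTask, test_fraction: float = 0.3, seed: int = 0) -> ResamplingPlan:
    n = task.n
    if not (0.0 < test_fraction < 1.0):
        raise ValidationError("test_fraction must lie in (0, 1)")
    n_test = max(1, int(round(n * test_fraction)))
    if n_test >= n:
        raise ValidationError("holdout leaves no training data")
    perm = np.random.default_rng(seed).permutation(n)
    return ResamplingPlan(scheme="holdout", n=n, seed=seed,
                          test_folds=(np.sort(perm[:n_test]),))


def _resolve_measures(measures) -> list[Measure]:
    out = []
    for m in measures:
        if isinstance(m, Measure):
            out.append(m)
        elif m in MEASURES:
            out.append(MEASURES[m])
        else:
            raise ValidationError(f"unknown measure {m!r}; available: {sorted(MEASURES)}")
    return out


def _preflight(learner, measures: list[Measure]) -> None:
    for m in measures:
        if m.required_channel not in learner.predict_types:
            lid = type(learner).__name__
            raise ChannelError(
                f"learner {lid} lacks channel {m.required_channel!r} required "
                f"by {m.id} — wrap it with a compositor pipeline"
            )


def resample(
    task: SurvTask,
    learner,
    plan: ResamplingPlan,
    measures,
    ipcw_on: str = "train",
) -> pd.DataFrame:
    """Fit/predict/score the learner over every fold of the plan.

    Returns a tidy frame with one row per (fold, measure).  Folds whose test
    part has zero events are scored as missing (NaN) with a warning and are
    excluded from aggregation downstream.
    """
    measures = _resolve_measures(measures)
    _preflight(learner, measures)
    if ipcw_on not in ("train", "test"):
        raise ValidationError("ipcw_on must be 'train' or 'test'")
    rows = []
    for fold, (train_idx, test_idx) in enumerate(plan.splits()):
        t0 = _clock.perf_counter()
        train, test = task.subset(train_idx), task.subset(test_idx)
        model = learner.fit(train.X, (train.time, train.status))
        pred: SurvPrediction = model.predict_surv(test.X)
        G_src = train if ipcw_on == "train" else test
        G = CensoringDistribution.fit(G_src.time, G_src.status)
        for m in measures:
            if test.n_events == 0:
                logger.warning("fold %d has zero events; %s scored as missing", fold, m.id)
                score = np.nan
            else:
                score = float(m(pred, test.time, test.status, G=G))
            rows.append({"task": task.id, "learner": getattr(learner, "id", type(learner).__name__),
                         "fold": fold, "measure": m.id, "score": score})
        logger.info("fold %d scored in %.3fs", fold, _clock.perf_counter() - t0)
    return pd.DataFrame(rows)


@dataclass
class BenchmarkResult:
    """Per-fold score table plus its macro-aggregation."""

    scores: pd.DataFrame  # columns: task, learner, fold, measure, score
    errors: pd.DataFrame = field(default_factory=pd.DataFrame)

    def aggregate(self) -> pd.DataFrame:
        """Mean and sd of fold scores per (task, learner, measure), NaN folds
        excluded."""
        ok = self.scores.dropna(subset=["score"])
        agg = (
            ok.groupby(["task", "learner", "measure"], sort=True)["score"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"mean": "score_mean", "std": "score_sd", "count": "n_folds"})
        )
        return agg


def benchmark(tasks, learners, plan_factory, measures, ipcw_on: str = "train") -> BenchmarkResult:
    """Full factorial grid of tasks x learners under shared fold indices.

    ``plan_factory`` is either a ready :class:`ResamplingPlan` (single task)
    or a callable ``task -> ResamplingPlan``; within a task all learners use
    the same plan, making fold scores paired across learners.  ``learners``
    may be a dict ``{id: learner}`` or a list (ids default to class names).
    A learner failure on a fold is recorded in ``errors`` and the remaining
    cells complete.
    """
    if not tasks or not learners:
        raise ValidationError("benchmark requires non-empty task and learner lists")
    if isinstance(learners, dict):
        learner_items = list(learners.items())
    else:
        learner_items = [(getattr(l, "id", type(l).__name__), l) for l in learners]
    measures = _resolve_measures(measures)
    score_rows, error_rows = [], []
    for task in tasks:
        plan = plan_factory(task) if callable(plan_factory) else plan_factory
        for lid, learner in learner_items:
            try:
                _preflight(learner, measures)
            except ChannelError as err:
                error_rows.append({"task": task.id, "learner": lid, "fold": -1,
                                   "error": str(err)})
                continue
            for fold, (train_idx, test_idx) in enumerate(plan.splits()):
                try:
                    train, test = task.subset(train_idx), task.subset(test_idx)
                    model = learner.fit(train.X, (train.time, train.status))
                    pred = model.predict_surv(test.X)
                    G_src = train if ipcw_on == "train" else test
                    G = CensoringDistribution.fit(G_src.time, G_src.status)
                    for m in measures:
                        score = np.nan if test.n_events == 0 else float(
                            m(pred, test.time, test.status, G=G))
                        score_rows.append({"task": task.id, "learner": lid,
                                           "fold": fold, "measure": m.id,
                                           "score": score})
                except Exception as err:  # cell isolation by design
                    logger.warning("benchmark cell failed (task=%s learner=%s fold=%d): %s",
                                   task.id, lid, fold, err)
                    error_rows.append({"task": task.id, "learner": lid,
                                       "fold": fold, "error": str(err)})
    scores = pd.DataFrame(score_rows, columns=["task", "learner", "fold", "measure", "score"])
    scores = scores.sort_values(["task", "learner", "measure", "fold"]).reset_index(drop=True)
    return BenchmarkResult(scores=scores, errors=pd.DataFrame(error_rows))
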