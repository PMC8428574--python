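"""Survival task container: features plus a right-censored (time, status) outcome.

A :class:`SurvTask` bundles an ``n x p`` numeric feature matrix ``X`` with the
observed time ``T_i >= 0`` and the event indicator ``delta_i`` (1 = event
observed, 0 = right-censored).  Validation is strict: any malformed input
raises, nothing is silently coerced or imputed.  Times are unit-agnostic
non-negative reals; ties are allowed and preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ShapeError, ValidationError

__all__ = ["SurvTask", "make_task", "read_task_csv", "write_task_csv", "task_summary"]


@dataclass(frozen=True)
class SurvTask:
    """Right-censored single-event survival task.

    Attributes
    ----------
    X : ndarray of shape (n, p)
        Numeric feature matrix, no missing values.
    time : ndarray of shape (n,)
        Observed times ``T_i = min(event time, censoring time)``, non-negative.
    status : ndarray of shape (n,)
        Event indicators ``delta_i``; 1 = event, 0 = right-censored.
    feature_names : list of str
        Column identifiers, length ``p``.
    id : str
        Label for reporting.
    censoring_type : str
        Fixed to ``"right"``; reserved for future censoring schemes.
    """

    X: np.ndarray
    time: np.ndarray
    status: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    id: str = "task"
    censoring_type: str = "right"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ShapeError(f"X must be 2-dimensional, got ndim={X.ndim}")
        time = np.asarray(self.time, dtype=float).ravel()
        status = np.asarray(self.status, dtype=float).ravel()
        n = X.shape[0]
        if n < 1:
            raise ValidationError("task must contain at least one subject")
        if len(time) != n or len(status) != n:
            raise ShapeError(
                f"length mismatch: X has {n} rows, time has {len(time)}, "
                f"status has {len(status)}"
            )
        if not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))
            raise ValidationError(
                f"feature matrix contains missing/non-finite values at "
                f"(row, col) = {[tuple(map(int, rc)) for rc in bad[:10]]}"
            )
        if not np.all(np.isfinite(time)):
            rows = np.flatnonzero(~np.isfinite(time))
            raise ValidationError(f"non-finite time at rows {rows.tolist()}")
        if np.any(time < 0):
            rows = np.flatnonzero(time < 0)
            raise ValidationError(f"negative time at rows {rows.tolist()}")
        bad_status = ~np.isin(status, (0.0, 1.0))
        if np.any(bad_status):
            rows = np.flatnonzero(bad_status)
            raise ValidationError(
                f"status must be 0 (censored) or 1 (event); offending rows "
                f"{rows.tolist()} with values {status[rows].tolist()}"
            )
        if self.censoring_type != "right":
            raise ValidationError(
                f"only right censoring is supported, got {self.censoring_type!r}"
            )
        names = list(self.feature_names) or [f"x{j + 1}" for j in range(X.shape[1])]
        if len(names) != X.shape[1]:
            raise ShapeError(
                f"{len(names)} feature names for {X.shape[1]} feature columns"
            )
        # dataclass is frozen: install validated, read-only copies
        for key, val in (
            ("X", X.copy()),
            ("time", time.copy()),
            ("status", status.astype(int)),
            ("feature_names", names),
        ):
            if isinstance(val, np.ndarray):
                val.setflags(write=False)
            object.__setattr__(self, key, val)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, idx: np.ndarray, id_suffix: str = "") -> "SurvTask":
        """Row-subset of the task (used by resampling)."""
        idx = np.asarray(idx)
        return SurvTask(
            X=self.X[idx],
            time=self.time[idx],
            status=self.status[idx],
            feature_names=self.feature_names,
            id=self.id + id_suffix,
        )

    def to_frame(self, time_col: str = "time", status_col: str = "status") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, status_col, self.status)
        df.insert(0, time_col, self.time)
        return df


def make_task(X, time, status, id: str = "task") -> SurvTask:
    """Validate raw arrays into a :class:`SurvTask`.

    Data are copied, so later mutation of the caller's arrays cannot corrupt
    the task.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and np.ndim(time) == 1 and len(np.asarray(time)) == X.shape[1]:
        # a 1-D feature vector was passed; treat it as a single column
        X = X.T
    return SurvTask(X=X, time=np.asarray(time), status=np.asarray(status), id=id)


def read_task_csv(
    path,
    time_col: str = "time",
    status_col: str = "status",
    feature_cols: list[str] | None = None,
    id: str | None = None,
) -> SurvTask:
    """Read a survival task from an RFC-4180 CSV with a header row.

    All columns other than ``time_col`` and ``status_col`` are used as
    features unless ``feature_cols`` names them explicitly.  Non-numeric or
    missing cells are a hard error (no imputation).
    """
    df = pd.read_csv(path)
    for col in (time_col, status_col):
        if col not in df.columns:
            raise ValidationError(f"column {col!r} not found in {path}")
    if feature_cols is None:
        feature_cols = [c for c in df.columns if c not in (time_col, status_col)]
    else:
        missing = [c for c in feature_cols if c not in df.columns]
        if missing:
            raise ValidationError(f"feature columns not found: {missing}")
    feats = pd.DataFrame(index=df.index)
    for col in feature_cols:
        feats[col] = _coerce_numeric(df[col], col)
    time = _coerce_numeric(df[time_col], time_col)
    status = _coerce_numeric(df[status_col], status_col)
    return SurvTask(
        X=feats.to_numpy(dtype=float).reshape(len(df), len(feature_cols)),
        time=time.to_numpy(),
        status=status.to_numpy(),
        feature_names=list(feature_cols),
        id=id or str(path),
    )


def _coerce_numeric(series: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"non-numeric or missing value in column {name!r} at row {row}: "
            f"{series.iloc[row]!r}"
        )
    return out


def write_task_csv(task: SurvTask, path, time_col: str = "time", status_col: str = "status") -> None:
    task.to_frame(time_col=time_col, status_col=status_col).to_csv(path, index=False)


def task_summary(task: SurvTask) -> dict:
    """Basic descriptive record: size, events, censoring proportion, time range."""
    return {
        "id": task.id,
        "n": task.n,
        "p": task.p,
        "n_events": task.n_events,
        "censoring_prop": 1.0 - float(np.mean(task.status)),
        "time_min": float(task.time.min()),
        "time_max": float(task.time.max()),
    }
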