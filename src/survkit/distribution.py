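"""Discrete-time survival distributions and the multi-channel prediction object.

A :class:`SurvDistribution` stores one survival curve per subject on a shared
strictly-increasing time grid ``t_1 < ... < t_m``.  The curve is interpreted
as a right-continuous step function with the product-limit conventions

* ``S_i(t) = 1``            for ``t < t_1``,
* ``S_i(t) = S[i, k]``      for ``t in [t_k, t_{k+1})``,
* ``S_i(t) = S[i, m]``      for ``t >= t_m`` (constant extrapolation).

All evaluation measures in :mod:`survkit.metrics` consume this form, so any
learner that can produce a survival curve — nonparametric, semi-parametric or
parametric — is comparable on the same footing.

The mean functional is the restricted mean survival time (RMST) on
``[0, t_m]``: the integral of the step function.  When ``S(t_m) > 0`` the
unrestricted mean is undefined from the grid alone; the restriction is a
documented saturation, not an approximation error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._constants import EPS
from .exceptions import ChannelError, ShapeError, ValidationError

__all__ = [
    "SurvDistribution",
    "SurvPrediction",
    "eval_survival",
    "eval_cdf",
    "eval_cumhazard",
    "dist_mean",
    "dist_median",
]


@dataclass(frozen=True)
class SurvDistribution:
    """Per-subject survival curves ``S[i, k] = S_i(t_k)`` on a shared grid."""

    grid: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float).ravel()
        S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if grid.size == 0:
            raise ValidationError("grid must contain at least one time point")
        if not np.all(np.isfinite(grid)):
            raise ValidationError("grid contains non-finite values")
        if np.any(np.diff(grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        if S.shape[1] != grid.size:
            raise ShapeError(
                f"S has {S.shape[1]} columns but grid has {grid.size} points"
            )
        if not np.all(np.isfinite(S)):
            raise ValidationError("S contains non-finite values")
        if np.any(S < -1e-12) or np.any(S > 1 + 1e-12):
            raise ValidationError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(S, axis=1) > 1e-12):
            raise ValidationError("each survival curve must be non-increasing")
        S = np.clip(S, 0.0, 1.0)
        # enforce exact monotonicity after rounding-level clipping
        S = np.minimum.accumulate(S, axis=1)
        grid = grid.copy()
        grid.setflags(write=False)
        S.setflags(write=False)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "S", S)

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def m(self) -> int:
        return self.grid.size

    # ------------------------------------------------------------------ #

    def survival(self, times) -> np.ndarray:
        return eval_survival(self, times)

    def cdf(self, times) -> np.ndarray:
        return eval_cdf(self, times)

    def cum_hazard(self, times) -> np.ndarray:
        return eval_cumhazard(self, times)

    def mean(self) -> np.ndarray:
        return dist_mean(self)

    def median(self) -> np.ndarray:
        return dist_median(self)

    def row(self, i: int) -> "SurvDistribution":
        return SurvDistribution(grid=self.grid, S=self.S[i : i + 1])

    def replicate(self, n: int) -> "SurvDistribution":
        """Broadcast a single curve to ``n`` identical subjects."""
        if self.n != 1:
            raise ShapeError("replicate requires a single-row distribution")
        return SurvDistribution(grid=self.grid, S=np.repeat(self.S, n, axis=0))

    # serialization ----------------------------------------------------- #

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.S.T, columns=[f"subject_{i}" for i in range(self.n)])
        df.insert(0, "time", self.grid)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvDistribution":
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise ValidationError("distribution CSV must have a 'time' column")
        grid = df["time"].to_numpy(dtype=float)
        S = df.drop(columns="time").to_numpy(dtype=float).T
        return cls(grid=grid, S=S)

    def to_json(self) -> str:
        return json.dumps({"grid": self.grid.tolist(), "S": self.S.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "SurvDistribution":
        obj = json.loads(text)
        return cls(grid=np.asarray(obj["grid"]), S=np.asarray(obj["S"]))


def _check_times(times) -> np.ndarray:
    times = np.asarray(times, dtype=float).ravel()
    if not np.all(np.isfinite(times)):
        raise ValidationError("evaluation times must be finite")
    if np.any(times < 0):
        raise ValidationError("evaluation times must be non-negative")
    return times


def eval_survival(dist: SurvDistribution, times) -> np.ndarray:
    """Evaluate ``S_i(t)`` at each requested time, shape ``(n, len(times))``."""
    times = _check_times(times)
    # index of the last grid point <= t; -1 means "before the grid" => S = 1
    idx = np.searchsorted(dist.grid, times, side="right") - 1
    padded = np.concatenate([np.ones((dist.n, 1)), dist.S], axis=1)
    return padded[:, idx + 1]


def eval_cdf(dist: SurvDistribution, times) -> np.ndarray:
    """``F = 1 - S`` pointwise."""
    return 1.0 - eval_survival(dist, times)


def eval_cumhazard(dist: SurvDistribution, times) -> np.ndarray:
    """``H = -log S`` with S clamped to ``[EPS, 1]``."""
    S = eval_survival(dist, times)
    return -np.log(np.clip(S, EPS, 1.0))


def dist_mean(dist: SurvDistribution) -> np.ndarray:
    """Restricted mean survival time on ``[0, t_m]`` of the step function.

    ``mean_i = t_1 + sum_{k>=2} (t_k - t_{k-1}) * S_i(t_{k-1})``: survival is
    certain on ``[0, t_1)`` by the below-grid convention.
    """
    widths = np.diff(dist.grid)
    return dist.grid[0] + dist.S[:, :-1] @ widths


def dist_median(dist: SurvDistribution) -> np.ndarray:
    """Smallest grid time with ``S <= 0.5``; saturates at ``t_m`` if none."""
    below = dist.S <= 0.5
    first = np.argmax(below, axis=1)
    med = dist.grid[first].astype(float)
    med[~below.any(axis=1)] = dist.grid[-1]
    return med


_CHANNELS = ("response", "crank", "lp", "distr")


@dataclass(frozen=True)
class SurvPrediction:
    """Prediction container with optional channels per test subject.

    Channels
    --------
    response : predicted survival time (larger = survives longer).
    crank : continuous risk ranking (larger = higher risk, shorter survival).
    lp : linear predictor on the model's native scale.
    distr : a :class:`SurvDistribution` with one curve per subject.
    """

    n: int
    response: np.ndarray | None = None
    crank: np.ndarray | None = None
    lp: np.ndarray | None = None
    distr: SurvDistribution | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        present = False
        for name in ("response", "crank", "lp"):
            v = getattr(self, name)
            if v is None:
                continue
            present = True
            v = np.asarray(v, dtype=float).ravel()
            if len(v) != self.n:
                raise ShapeError(f"channel {name!r} has length {len(v)}, expected {self.n}")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"channel {name!r} contains non-finite values")
            v = v.copy()
            v.setflags(write=False)
            object.__setattr__(self, name, v)
        if self.distr is not None:
            present = True
            if self.distr.n != self.n:
                raise ShapeError(
                    f"distr has {self.distr.n} rows, expected {self.n}"
                )
        if not present:
            raise ChannelError("a prediction must populate at least one channel")

    @property
    def channels(self) -> frozenset[str]:
        return frozenset(c for c in _CHANNELS if getattr(self, c) is not None)

    def require(self, channel: str) -> None:
        if channel not in _CHANNELS:
            raise ChannelError(f"unknown channel {channel!r}")
        if getattr(self, channel) is None:
            raise ChannelError(
                f"prediction from {self.provenance or 'unknown learner'} lacks "
                f"required channel {channel!r}"
            )

    def with_channels(self, **kwargs) -> "SurvPrediction":
        """Copy with some channels replaced."""
        fields = {c: getattr(self, c) for c in _CHANNELS}
        fields.update(kwargs)
        return SurvPrediction(n=self.n, provenance=self.provenance, **fields)
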