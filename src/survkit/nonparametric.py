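"""Product-limit machinery shared by learners and IPCW weights.

Everything here reduces to the risk-set counting process: at each unique
event time ``t_j`` we record the number of events ``d_j`` and the at-risk
count ``n_j = #{i : T_i >= t_j}``.  Kaplan-Meier multiplies ``(1 - d_j/n_j)``
factors; Nelson-Aalen sums ``d_j/n_j`` increments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._constants import G_FLOOR
from .distribution import SurvDistribution

logger = logging.getLogger(__name__)

__all__ = ["risk_table", "kaplan_meier_curve", "nelson_aalen_curve", "CensoringDistribution"]


def risk_table(time, status) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique event times with event and at-risk counts.

    Returns ``(grid, d, n_at_risk)`` where ``grid`` holds the unique times at
    which at least one event occurred.  Empty arrays when there are no events.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    grid = np.unique(time[status == 1])
    d = np.array([np.sum((time == t) & (status == 1)) for t in grid], dtype=float)
    n_at_risk = np.array([np.sum(time >= t) for t in grid], dtype=float)
    return grid, d, n_at_risk


def kaplan_meier_curve(time, status) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimate ``S(t) = prod_{t_j <= t} (1 - d_j / n_j)``.

    With zero events the estimate is identically 1 on the grid of unique
    observed times (logged as a warning, not an error).
    """
    grid, d, n = risk_table(time, status)
    if grid.size == 0:
        logger.warning("kaplan_meier_curve: no events; S is identically 1")
        grid = np.unique(np.asarray(time, dtype=float))
        return grid, np.ones_like(grid)
    return grid, np.cumprod(1.0 - d / n)


def nelson_aalen_curve(time, status) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative hazard ``H(t) = sum_{t_j <= t} d_j / n_j``."""
    grid, d, n = risk_table(time, status)
    if grid.size == 0:
        logger.warning("nelson_aalen_curve: no events; H is identically 0")
        grid = np.unique(np.asarray(time, dtype=float))
        return grid, np.zeros_like(grid)
    return grid, np.cumsum(d / n)


@dataclass
class CensoringDistribution:
    """Kaplan-Meier estimate ``G(t)`` of the censoring survival function.

    Fitted on the training data with the status flipped (a censoring is the
    "event"), this supplies the inverse-probability-of-censoring weights of
    the scoring rules: event contributions at ``T_i`` are weighted by
    ``1 / G(T_i-)`` (left limit) and at-risk contributions at ``t`` by
    ``1 / G(t)``.  Denominators are floored at ``floor`` to bound weights;
    the number of floored evaluations is counted and logged.
    """

    grid: np.ndarray
    G: np.ndarray
    floor: float = G_FLOOR
    n_floored: int = 0

    @classmethod
    def fit(cls, time, status, floor: float = G_FLOOR) -> "CensoringDistribution":
        status = np.asarray(status)
        grid, G = kaplan_meier_curve(time, 1 - status)
        return cls(grid=np.asarray(grid, dtype=float), G=np.asarray(G, dtype=float), floor=floor)

    def _eval(self, times, side: str) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.grid, times, side=side) - 1
        padded = np.concatenate([[1.0], self.G])
        out = padded[idx + 1]
        floored = out < self.floor
        if np.any(floored):
            self.n_floored += int(np.sum(floored))
            logger.warning(
                "CensoringDistribution: %d weight denominators floored at %g",
                int(np.sum(floored)), self.floor,
            )
        return np.maximum(out, self.floor)

    def survival(self, times) -> np.ndarray:
        """``G(t)``, right-continuous."""
        return self._eval(times, side="right")

    def survival_left(self, times) -> np.ndarray:
        """Left limit ``G(t-)``: the product over censor times strictly before t."""
        return self._eval(times, side="left")

    def as_distribution(self) -> SurvDistribution:
        return SurvDistribution(grid=self.grid, S=self.G.reshape(1, -1))
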