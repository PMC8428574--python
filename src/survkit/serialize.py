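"""On-disk formats for fitted models and prediction bundles (CLI plumbing).

A *model directory* holds ``model.json`` (learner id, scalar parameters)
plus ``baseline.csv`` (grid and baseline curve) where applicable.  A
*prediction bundle* directory holds ``prediction.json`` (vector channels)
plus ``distr.csv`` (the distribution channel, grid in the first column).
Everything is plain text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .distribution import SurvDistribution, SurvPrediction
from .estimators import CoxPH, KaplanMeier, NelsonAalen, WeibullAFT
from .exceptions import ValidationError

__all__ = ["save_model", "load_model", "save_prediction", "load_prediction"]


def save_model(model, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(model, (KaplanMeier, NelsonAalen)):
        lid = "kaplan" if isinstance(model, KaplanMeier) else "nelson"
        meta = {"learner": lid}
        pd.DataFrame({"time": model.baseline_.grid, "S": model.baseline_.S[0]}).to_csv(
            path / "baseline.csv", index=False)
    elif isinstance(model, CoxPH):
        meta = {
            "learner": "coxph",
            "coef": model.coef_.tolist(),
            "train_mean": model.train_mean_.tolist(),
        }
        pd.DataFrame({"time": model.baseline_grid_,
                      "cum_hazard": model.baseline_cum_hazard_}).to_csv(
            path / "baseline.csv", index=False)
    elif isinstance(model, WeibullAFT):
        meta = {
            "learner": "weibull",
            "intercept": model.intercept_,
            "coef": model.coef_.tolist(),
            "scale": model.scale_,
            "grid": model.baseline_grid_.tolist(),
        }
    else:
        raise ValidationError(f"cannot serialize model of type {type(model).__name__}")
    (path / "model.json").write_text(json.dumps(meta, indent=1))


def load_model(path):
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    lid = meta["learner"]
    if lid in ("kaplan", "nelson"):
        df = pd.read_csv(path / "baseline.csv")
        model = KaplanMeier() if lid == "kaplan" else NelsonAalen()
        model.grid_ = df["time"].to_numpy()
        model.baseline_ = SurvDistribution(grid=model.grid_, S=df["S"].to_numpy().reshape(1, -1))
        if lid == "kaplan":
            model.surv_ = df["S"].to_numpy()
        else:
            model.cum_hazard_ = -np.log(np.clip(df["S"].to_numpy(), 1e-300, 1.0))
        return model
    if lid == "coxph":
        model = CoxPH()
        model.coef_ = np.asarray(meta["coef"], dtype=float)
        model.train_mean_ = np.asarray(meta["train_mean"], dtype=float)
        df = pd.read_csv(path / "baseline.csv")
        model.baseline_grid_ = df["time"].to_numpy()
        model.baseline_cum_hazard_ = df["cum_hazard"].to_numpy()
        return model
    if lid == "weibull":
        model = WeibullAFT()
        model.intercept_ = float(meta["intercept"])
        model.coef_ = np.asarray(meta["coef"], dtype=float)
        model.scale_ = float(meta["scale"])
        model.baseline_grid_ = np.asarray(meta["grid"], dtype=float)
        return model
    raise ValidationError(f"unknown serialized learner {lid!r}")


def save_prediction(pred: SurvPrediction, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {"n": pred.n, "provenance": pred.provenance}
    for ch in ("response", "crank", "lp"):
        v = getattr(pred, ch)
        meta[ch] = v.tolist() if v is not None else None
    (path / "prediction.json").write_text(json.dumps(meta))
    if pred.distr is not None:
        pred.distr.to_csv(path / "distr.csv")


def load_prediction(path) -> SurvPrediction:
    path = Path(path)
    meta = json.loads((path / "prediction.json").read_text())
    distr = None
    if (path / "distr.csv").exists():
        distr = SurvDistribution.from_csv(path / "distr.csv")
    return SurvPrediction(
        n=int(meta["n"]),
        response=None if meta.get("response") is None else np.asarray(meta["response"]),
        crank=None if meta.get("crank") is None else np.asarray(meta["crank"]),
        lp=None if meta.get("lp") is None else np.asarray(meta["lp"]),
        distr=distr,
        provenance=meta.get("provenance", ""),
    )
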