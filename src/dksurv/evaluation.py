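"""Censoring-aware expected prediction error and cross-validation.

The prediction error at horizon ``u`` given base time ``t`` averages, over
the test subjects still at risk at ``t``, the loss between the true survival
status at ``u`` and the predicted survival probability.  Subjects censored
inside the window [t, u) have unknown status; their loss is a mixture of the
survivor and event losses, weighted by the model's own probability of
surviving to ``u`` given survival to the censoring time:

    PE(u|t) = (1/n(t)) * sum_{i: T_i >= t} [
        I(T_i >= u)            L(1 - pi_i)
      + delta_i I(T_i < u)     L(0 - pi_i)
      + (1-delta_i) I(T_i < u) { pic_i L(1 - pi_i) + (1 - pic_i) L(0 - pi_i) } ]

with ``pi_i = pi(u | Z_[0,t]i, t)`` and ``pic_i = pi(u | Z_[0,t]i, T_i)``.
Squared loss gives a censoring-adjusted Brier score (PE = 0.25 when every
prediction is 0.5; 0 for perfect and 1 for perfectly inverted predictions).

A *predictor* is any object with the two methods
``predict_survival(subj, u, t)`` and
``conditional_survival_from_censoring(subj, t, u)`` — fitted delayed-kernel
results and landmarking predictors both qualify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset

__all__ = [
    "EvalConfig",
    "PECurve",
    "prediction_error",
    "pe_fixed_base_curve",
    "pe_fixed_window_curve",
    "kfold_cross_validate",
]

SQUARED = "squared"
ABSOLUTE = "absolute"


def _loss(x: float, loss: str) -> float:
    if loss == SQUARED:
        return x * x
    if loss == ABSOLUTE:
        return abs(x)
    raise ValueError(f"unknown loss {loss!r}")


@dataclass
class EvalConfig:
    """Evaluation settings: loss, time grids, cross-validation layout."""

    loss: str = SQUARED
    base_time: float | None = None
    u_grid: tuple = ()
    t_grid: tuple = ()
    window: float | None = None
    folds: int = 10
    seed: int = 0
    stratify: bool = False

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("cross-validation needs k >= 2 folds")
        for grid in (self.u_grid, self.t_grid):
            if len(grid) > 1 and np.any(np.diff(grid) <= 0):
                raise ValueError("time grids must be strictly increasing")
        if self.window is not None and self.window <= 0:
            raise ValueError("prediction window must be > 0")


@dataclass
class PECurve:
    """Rows of (t, u, n_at_risk, pe) with optional fold/model metadata."""

    rows: list = field(default_factory=list)
    model_id: str = ""
    fold: str = ""

    def add(self, t: float, u: float, n_at_risk: int, pe: float) -> None:
        self.rows.append({"t": t, "u": u, "n_at_risk": n_at_risk, "pe": pe,
                          "fold": self.fold})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["t", "u", "n_at_risk", "pe", "fold"])


def prediction_error(predictor, test: Dataset, t: float, u: float,
                     loss: str = SQUARED) -> float:
    """Censoring-aware expected prediction error PE(u | t) on a test set."""
    at_risk = [s for s in test if s.event_time >= t]
    if not at_risk:
        raise ValueError(f"no subjects at risk at t={t}")
    total = 0.0
    for s in at_risk:
        pi = predictor.predict_survival(s, u, t)
        if s.event_time >= u:
            # status known: survivor (censoring exactly at u counts here)
            total += _loss(1.0 - pi, loss)
        elif s.event == 1:
            total += _loss(0.0 - pi, loss)
        else:
            pic = predictor.conditional_survival_from_censoring(s, t, u)
            total += pic * _loss(1.0 - pi, loss) + (1.0 - pic) * _loss(0.0 - pi, loss)
    return total / len(at_risk)


def pe_fixed_base_curve(predictor, test: Dataset, t: float, u_grid,
                        cfg: EvalConfig | None = None) -> PECurve:
    """PE(u | t) over a grid of horizons at one fixed base time."""
    cfg = cfg or EvalConfig()
    curve = PECurve(model_id=getattr(predictor, "model_id", ""))
    n = sum(1 for s in test if s.event_time >= t)
    for u in u_grid:
        curve.add(t, u, n, prediction_error(predictor, test, t, u, cfg.loss))
    return curve


def pe_fixed_window_curve(predictor, test: Dataset, t_grid, w: float,
                          cfg: EvalConfig | None = None) -> PECurve:
    """PE(t + w | t) over a grid of base times with a fixed window w.

    A single fitted delayed-kernel model serves every base time; a
    landmarking predictor internally refits at each t.
    """
    cfg = cfg or EvalConfig()
    curve = PECurve(model_id=getattr(predictor, "model_id", ""))
    for t in t_grid:
        u = t + w
        n = sum(1 for s in test if s.event_time >= t)
        curve.add(t, u, n, prediction_error(predictor, test, t, u, cfg.loss))
    return curve


def _make_folds(n: int, k: int, seed: int, events=None, stratify: bool = False):
    """Seeded partition of range(n) into k near-equal folds."""
    rng = np.random.default_rng(seed)
    if stratify and events is not None:
        order = np.concatenate([
            rng.permutation(np.flatnonzero(events == 1)),
            rng.permutation(np.flatnonzero(events == 0)),
        ])
    else:
        order = rng.permutation(n)
    return [order[i::k] for i in range(k)]


def kfold_cross_validate(d: Dataset, recipes: dict, cfg: EvalConfig) -> dict:
    """k-fold cross-validated prediction-error curves.

    Parameters
    ----------
    d : Dataset
        Full data; split into ``cfg.folds`` seeded near-equal folds.
    recipes : dict of str -> callable
        Each callable maps a training Dataset to a predictor.
    cfg : EvalConfig
        Must define either a fixed base time with a horizon grid
        (``base_time`` + ``u_grid``) or a base-time grid with a fixed window
        (``t_grid`` + ``window``).

    Returns
    -------
    dict mapping recipe name to ``{"folds": [PECurve, ...], "mean": PECurve}``
    where the mean curve averages PE pointwise across folds (folds without a
    training event, or without test subjects at risk, are skipped with a
    warning).
    """
    if cfg.folds > d.n:
        raise ValueError("more folds than subjects")
    fixed_base = cfg.base_time is not None and len(cfg.u_grid) > 0
    fixed_window = cfg.window is not None and len(cfg.t_grid) > 0
    if fixed_base == fixed_window:
        raise ValueError("specify exactly one of (base_time, u_grid) or (t_grid, window)")

    folds = _make_folds(d.n, cfg.folds, cfg.seed, d.events, cfg.stratify)
    out = {name: {"folds": []} for name in recipes}
    for f_idx, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(d.n), test_idx)
        train, test = d.subset(train_idx), d.subset(test_idx)
        if train.events.sum() == 0:
            warnings.warn(f"fold {f_idx}: no events in training data, skipped")
            continue
        for name, recipe in recipes.items():
            predictor = recipe(train)
            try:
                if fixed_base:
                    curve = pe_fixed_base_curve(predictor, test, cfg.base_time,
                                                cfg.u_grid, cfg)
                else:
                    curve = pe_fixed_window_curve(predictor, test, cfg.t_grid,
                                                  cfg.window, cfg)
            except ValueError as exc:
                warnings.warn(f"fold {f_idx}, model {name}: {exc}; fold skipped")
                continue
            curve.fold = str(f_idx)
            curve.model_id = name
            out[name]["folds"].append(curve)

    for name, entry in out.items():
        frames = [c.to_frame() for c in entry["folds"]]
        if not frames:
            entry["mean"] = PECurve(model_id=name, fold="mean")
            continue
        allf = pd.concat(frames)
        mean = PECurve(model_id=name, fold="mean")
        for (t, u), grp in allf.groupby(["t", "u"], sort=True):
            mean.rows.append({"t": t, "u": u,
                              "n_at_risk": int(grp["n_at_risk"].sum()),
                              "pe": float(grp["pe"].mean()), "fold": "mean"})
        entry["mean"] = mean
    return out
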