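"""Performance metrics and Table-shaped model comparison reports.

Six figures per (engine, attribute) cell: Rc2/RMSEC on the calibration set,
Rcv2/RMSECV from seeded k-fold cross-validation, Rp2/RMSEP on the
validation set.  R^2 is the coefficient of determination 1 - SSres/SStot
(it can be negative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .errors import DataError, DegenerateTargetError, ParameterError

REPORT_DECIMALS = 4


def rmse(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise DataError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    if y_true.size == 0:
        raise DataError("empty vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise DataError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateTargetError("constant y_true has no variance to explain")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def cross_validate(fit: Callable[[np.ndarray, np.ndarray], object],
                   X: np.ndarray, y: np.ndarray, folds: int = 5,
                   seed: int = 0) -> tuple[float, float, np.ndarray]:
    """Pooled out-of-fold metrics: returns (Rcv2, RMSECV, oof_predictions).

    ``fit(X, y)`` must return an object with ``predict(X) -> vector``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if folds < 2:
        raise ParameterError("folds must be >= 2")
    if y.size < folds:
        raise ParameterError(f"need >= {folds} samples for {folds}-fold CV")
    if y.size // folds < 1:
        raise ParameterError("fold with < 1 sample")
    oof = np.empty_like(y)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        model = fit(X[train], y[train])
        oof[test] = np.asarray(model.predict(X[test])).ravel()
    return r_squared(y, oof), rmse(y, oof), oof


@dataclass
class EvaluationReport:
    """Table-1-shaped collection of metric rows with stored predictions."""

    rows: list[dict] = field(default_factory=list)
    predictions: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(self, engine: str, attribute: str, metrics: dict,
            predictions: dict | None = None) -> None:
        row = {"engine": engine, "attribute": attribute}
        row.update(metrics)
        self.rows.append(row)
        if predictions is not None:
            self.predictions[(engine, attribute)] = {
                k: np.asarray(v, dtype=float) for k, v in predictions.items()}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        metric_cols = [c for c in df.columns if c not in ("engine", "attribute", "failed")]
        df[metric_cols] = df[metric_cols].round(REPORT_DECIMALS)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {"provenance": self.provenance, "rows": self.to_frame().to_dict("records")}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def cell(self, engine: str, attribute: str) -> dict:
        for row in self.rows:
            if row["engine"] == engine and row["attribute"] == attribute:
                return row
        raise DataError(f"no report cell for ({engine}, {attribute})")


def evaluate_predictions(y_cal, pred_cal, y_val, pred_val,
                         rcv2: float, rmsecv: float) -> dict:
    return {
        "rc2": r_squared(y_cal, pred_cal), "rmsec": rmse(y_cal, pred_cal),
        "rcv2": rcv2, "rmsecv": rmsecv,
        "rp2": r_squared(y_val, pred_val), "rmsep": rmse(y_val, pred_val),
    }


def evaluate_model(fit: Callable[[np.ndarray, np.ndarray], object],
                   model, X_cal: np.ndarray, y_cal: np.ndarray,
                   X_val: np.ndarray, y_val: np.ndarray,
                   folds: int = 5, seed: int = 0) -> tuple[dict, dict]:
    """All six metrics for a fitted model + its refitting callable.

    Returns ``(metrics, prediction_vectors)``; RMSECV refits via ``fit`` on
    calibration folds.
    """
    pred_cal = np.asarray(model.predict(X_cal)).ravel()
    pred_val = np.asarray(model.predict(X_val)).ravel()
    rcv2, rmsecv, oof = cross_validate(fit, X_cal, y_cal, folds, seed)
    metrics = evaluate_predictions(y_cal, pred_cal, y_val, pred_val, rcv2, rmsecv)
    return metrics, {"calibration": pred_cal, "validation": pred_val, "oof": oof}
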