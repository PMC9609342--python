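"""Calibration engines: PLSR, SVR and the 1-D CNN, behind one contract.

Every engine fits one attribute from calibration spectra (optionally
restricted to selected channels) and exposes ``predict`` on full-axis
input.  Targets are standardised internally where the engine benefits
(z-score for SVR/CNN, centering for PLSR) and inverse-transformed on
prediction.  Models serialise to a bundle: a JSON description plus a
pickled state file.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

from ._pls import MAX_COMPONENTS, best_ncomp, pls_coefficient_paths
from .cnn import CnnSpec, build_cnn, predict_network, train_network
from .errors import (DataError, DegenerateTargetError, IncompatibilityError,
                     ParameterError)

BUNDLE_VERSION = 1

DEFAULT_SVR_GRID = {
    "C": [1.0, 10.0, 100.0],
    "gamma_factor": [0.1, 1.0, 10.0],   # x the 1/(p*Var(X)) scale heuristic
    "epsilon": [0.01, 0.1],
}


@dataclass
class CalibrationModel:
    """A fitted predictor bound to its preprocessing and channel subset."""

    engine: str
    attribute: str
    n_channels_full: int
    selected_indices: np.ndarray | None = None
    fingerprint: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    history: dict = field(default_factory=dict)
    state: dict = field(default_factory=dict, repr=False)
    training_predictions: np.ndarray | None = None

    def _slice(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_channels_full:
            raise IncompatibilityError(
                f"expected spectra with {self.n_channels_full} channels on the "
                f"training axis, got shape {X.shape}")
        if self.selected_indices is not None:
            X = X[:, self.selected_indices]
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self._slice(X)
        s = self.state
        if self.engine == "plsr":
            pred = (Xs - s["x_mean"]) @ s["coef"] + s["y_mean"]
        elif self.engine == "svr":
            pred = s["svr"].predict(Xs) * s["y_sd"] + s["y_mean"]
        elif self.engine == "cnn":
            pred = predict_network(s["network"], Xs) * s["y_sd"] + s["y_mean"]
        else:
            raise ParameterError(f"unknown engine {self.engine!r}")
        pred = np.asarray(pred, dtype=float).ravel()
        if not np.all(np.isfinite(pred)):
            raise DataError(f"{self.engine}/{self.attribute}: non-finite prediction")
        return pred

    # -- serialisation ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write ``<path>.json`` (description) and ``<path>.pkl`` (state)."""
        path = Path(path)
        desc = {
            "bundle_version": BUNDLE_VERSION,
            "engine": self.engine,
            "attribute": self.attribute,
            "n_channels_full": self.n_channels_full,
            "selected_indices": (self.selected_indices.tolist()
                                 if self.selected_indices is not None else None),
            "fingerprint": self.fingerprint,
            "params": _jsonable(self.params),
        }
        path.with_suffix(".json").write_text(json.dumps(desc, indent=1, sort_keys=True))
        with open(path.with_suffix(".pkl"), "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        with open(Path(path).with_suffix(".pkl"), "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise DataError(f"{path} is not a calibration model bundle")
        return model


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _validate_fit_input(X, y, selected_indices, allow_constant=False):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DataError(f"X {X.shape} incompatible with y ({y.size})")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in X or y")
    if np.ptp(y) == 0.0 and not allow_constant:
        raise DegenerateTargetError("constant target")
    idx = None
    if selected_indices is not None:
        idx = np.sort(np.asarray(selected_indices, dtype=int))
        if idx.size and (idx[0] < 0 or idx[-1] >= X.shape[1]):
            raise ParameterError("selected indices outside channel range")
    return X, y, idx


# ---------------------------------------------------------------------------
# PLSR
# ---------------------------------------------------------------------------

def fit_plsr(X: np.ndarray, y: np.ndarray, attribute: str = "",
             selected_indices: Sequence[int] | None = None,
             max_components: int = MAX_COMPONENTS, folds: int = 5,
             seed: int = 0) -> CalibrationModel:
    """PLS regression; latent-variable count chosen by minimal RMSECV."""
    X, y, idx = _validate_fit_input(X, y, selected_indices)
    Xs = X if idx is None else X[:, idx]
    k, rmsecv = best_ncomp(Xs, y, max_components, folds, seed)
    B, x_mean, y_mean = pls_coefficient_paths(Xs, y, k)
    model = CalibrationModel(
        engine="plsr", attribute=attribute, n_channels_full=X.shape[1],
        selected_indices=idx,
        params={"n_components": k, "rmsecv_at_selection": rmsecv},
        state={"coef": B[-1], "x_mean": x_mean, "y_mean": y_mean})
    model.training_predictions = model.predict(X)
    return model


# ---------------------------------------------------------------------------
# SVR
# ---------------------------------------------------------------------------

def fit_svr(X: np.ndarray, y: np.ndarray, attribute: str = "",
            selected_indices: Sequence[int] | None = None,
            grid: dict | None = None, folds: int = 5, seed: int = 0,
            kernel: str = "rbf") -> CalibrationModel:
    """Kernelised epsilon-SVR; hyperparameters by inner CV over the grid."""
    X, y, idx = _validate_fit_input(X, y, selected_indices, allow_constant=True)
    Xs = X if idx is None else X[:, idx]
    grid = grid or DEFAULT_SVR_GRID
    if not grid or not all(len(v) for v in grid.values()):
        raise ParameterError("empty SVR grid")

    y_mean, y_sd = float(y.mean()), float(max(y.std(), 1e-12))
    ys = (y - y_mean) / y_sd
    scale_gamma = 1.0 / (Xs.shape[1] * max(Xs.var(), 1e-12))
    param_grid = {
        "C": list(grid.get("C", [1.0])),
        "gamma": [f * scale_gamma for f in grid.get("gamma_factor", [1.0])],
        "epsilon": list(grid.get("epsilon", [0.1])),
    }
    n_points = int(np.prod([len(v) for v in param_grid.values()]))
    if n_points == 1:
        chosen = {k: v[0] for k, v in param_grid.items()}
        svr = SVR(kernel=kernel, **chosen).fit(Xs, ys)
    else:
        cv = KFold(n_splits=min(folds, y.size), shuffle=True, random_state=seed)
        search = GridSearchCV(SVR(kernel=kernel), param_grid, cv=cv,
                              scoring="neg_root_mean_squared_error", n_jobs=1)
        search.fit(Xs, ys)
        svr = search.best_estimator_
        chosen = search.best_params_

    model = CalibrationModel(
        engine="svr", attribute=attribute, n_channels_full=X.shape[1],
        selected_indices=idx,
        params={"chosen": {k: float(v) for k, v in chosen.items()}},
        state={"svr": svr, "y_mean": y_mean, "y_sd": y_sd})
    model.training_predictions = model.predict(X)
    return model


# ---------------------------------------------------------------------------
# CNN
# ---------------------------------------------------------------------------

def fit_cnn(X: np.ndarray, y: np.ndarray, attribute: str = "",
            selected_indices: Sequence[int] | None = None,
            spec: CnnSpec | None = None, seed: int = 0) -> CalibrationModel:
    """Train the 1-D CNN on [0, 1]-scaled spectra with a z-scored target."""
    X, y, idx = _validate_fit_input(X, y, selected_indices)
    Xs = X if idx is None else X[:, idx]
    spec = spec or CnnSpec.for_attribute(attribute)
    net = build_cnn(spec, Xs.shape[1], seed=seed)
    y_mean, y_sd = float(y.mean()), float(y.std())
    history = train_network(net, Xs, (y - y_mean) / y_sd, spec, seed=seed)

    model = CalibrationModel(
        engine="cnn", attribute=attribute, n_channels_full=X.shape[1],
        selected_indices=idx,
        params={"n_parameters": net.n_parameters, "spec": spec.__dict__.copy()},
        history={"epoch_loss": history.epoch_loss,
                 "stopped_epoch": history.stopped_epoch},
        state={"network": net, "y_mean": y_mean, "y_sd": y_sd})
    model.training_predictions = model.predict(X)
    return model


ENGINES = {"plsr": fit_plsr, "svr": fit_svr, "cnn": fit_cnn}


def fit_engine(engine: str, X, y, attribute: str = "",
               selected_indices=None, seed: int = 0, **kwargs) -> CalibrationModel:
    if engine not in ENGINES:
        raise ParameterError(f"unknown engine {engine!r}; choose from {sorted(ENGINES)}")
    return ENGINES[engine](X, y, attribute=attribute,
                           selected_indices=selected_indices, seed=seed, **kwargs)
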