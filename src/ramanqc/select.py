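"""Characteristic-band selection: CARS (primary) plus UVE, SPA and siPLS.

All selectors consume a calibration block ``(X, y)`` and return a
:class:`SelectionResult` carrying the chosen channel indices and the
per-run trace that produced them; re-running with the same seed is
bit-identical.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._pls import MAX_COMPONENTS, best_ncomp, pls_coefficient_paths, rmsecv_path
from .errors import (DataError, EmptySelectionError, ParameterError)


@dataclass
class SelectionResult:
    """Chosen channels plus the per-run evidence behind the choice."""

    selected_indices: np.ndarray
    method: str
    trace: list[dict] = field(default_factory=list)
    best_run: int | None = None

    def __post_init__(self):
        idx = np.asarray(self.selected_indices, dtype=int)
        if idx.size == 0:
            raise EmptySelectionError(f"{self.method}: empty selection")
        if np.unique(idx).size != idx.size:
            raise ParameterError(f"{self.method}: duplicate indices")
        self.selected_indices = np.sort(idx)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected_indices": self.selected_indices.tolist(),
            "best_run": self.best_run,
            "trace": [{k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in rec.items()} for rec in self.trace],
        }

    def subset_of_at_least(self, min_size: int) -> np.ndarray:
        """Best-RMSECV trace subset with >= min_size channels (CARS only)."""
        candidates = [r for r in self.trace
                      if len(r.get("indices", [])) >= min_size]
        if not candidates:
            return self.selected_indices
        best = min(candidates, key=lambda r: r["rmsecv"])
        return np.sort(np.asarray(best["indices"], dtype=int))


@dataclass(frozen=True)
class CarsConfig:
    n_runs: int = 50
    mc_rate: float = 0.8
    cv_folds: int = 5
    max_components: int = MAX_COMPONENTS
    edf_end: int = 2   # variables surviving the forced schedule at the last run

    def __post_init__(self):
        if not 0.0 < self.mc_rate < 1.0:
            raise ParameterError("mc_rate must lie in (0, 1)")
        if self.n_runs < 2:
            raise ParameterError("n_runs must be >= 2")


def edf_ratio_schedule(n_channels: int, n_runs: int, end: int = 2) -> np.ndarray:
    """Exponentially decreasing retention ratios r_i = a*exp(-k*i), i=1..N,
    pinned so run 1 keeps all ``n_channels`` and run N keeps ``end``."""
    if n_channels <= end:
        return np.ones(n_runs)
    a = (n_channels / end) ** (1.0 / (n_runs - 1))
    k = math.log(n_channels / end) / (n_runs - 1)
    i = np.arange(1, n_runs + 1)
    return a * np.exp(-k * i)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise DataError(f"X ({X.shape}) incompatible with y ({y.size})")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in X or y")
    return X, y


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

def cars_select(X: np.ndarray, y: np.ndarray, cfg: CarsConfig | None = None,
                seed: int = 0) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Each run draws a Monte-Carlo subsample, fits PLS on the live channels,
    force-retains the top fraction by |coefficient| following the
    exponentially decreasing schedule, resamples survivors with weights
    proportional to |coefficient| (adaptive reweighted sampling), and scores
    the surviving subset by cross-validated RMSECV on the full calibration
    block.  The subset of the minimal-RMSECV run wins.
    """
    cfg = cfg or CarsConfig()
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n < cfg.cv_folds:
        raise ParameterError(f"need >= {cfg.cv_folds} samples for CV")
    rng = np.random.default_rng(seed)
    ratios = edf_ratio_schedule(p, cfg.n_runs, cfg.edf_end)
    n_sub = max(2, math.ceil(cfg.mc_rate * n))

    live = np.arange(p)
    trace: list[dict] = []
    for i in range(cfg.n_runs):
        sub = rng.choice(n, size=n_sub, replace=False)
        ncomp = max(1, min(cfg.max_components, live.size, n_sub - 1))
        B, _, _ = pls_coefficient_paths(X[np.ix_(sub, live)], y[sub], ncomp)
        w = np.abs(B[-1])
        n_keep = int(round(ratios[i] * p))
        n_keep = max(cfg.edf_end, min(n_keep, live.size))
        # forced EDF retention: top n_keep by |coefficient|
        top = np.argsort(-w, kind="stable")[:n_keep]
        w_top = w[top]
        if w_top.sum() <= 0:
            keep_local = top
        else:
            # adaptive reweighted sampling: n_keep weighted draws w/ replacement
            draws = rng.choice(top.size, size=n_keep, replace=True,
                               p=w_top / w_top.sum())
            keep_local = top[np.unique(draws)]
        live = np.sort(live[keep_local])
        rmse_path = rmsecv_path(X[:, live], y, cfg.max_components,
                                cfg.cv_folds, seed)
        trace.append({"run": i + 1, "n_variables": int(live.size),
                      "rmsecv": float(rmse_path.min()),
                      "indices": live.copy()})
        if live.size < 2:
            if i < cfg.n_runs - 1:
                warnings.warn("CARS subset collapsed below 2 variables; "
                              "trace truncated", stacklevel=2)
            break

    best = int(np.argmin([r["rmsecv"] for r in trace]))
    return SelectionResult(trace[best]["indices"], "cars", trace, best_run=best)


# ---------------------------------------------------------------------------
# UVE
# ---------------------------------------------------------------------------

def uve_select(X: np.ndarray, y: np.ndarray, n_noise: int | None = None,
               cutoff_rule: str = "max", cutoff_quantile: float = 0.99,
               max_components: int = MAX_COMPONENTS, seed: int = 0,
               ) -> SelectionResult:
    """Uninformative variable elimination.

    Appends ``n_noise`` artificial channels, computes each variable's
    stability mean(b)/sd(b) of PLS coefficients over leave-one-out
    refits, and keeps real channels whose |stability| exceeds the cutoff
    derived from the artificial channels (their max by default).

    The artificial channels are row-shuffled copies of randomly chosen real
    channels: same scale and marginal distribution as the data but no
    relation to the target.  (Vanishingly small random channels do not feed
    back into the PLS scores, which makes their coefficients artificially
    stable and the cutoff useless.)
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n_noise is None:
        n_noise = max(p, 10)
    if n_noise < 10:
        raise ParameterError("n_noise must be >= 10")
    rng = np.random.default_rng(seed)
    cols = rng.integers(0, p, size=n_noise)
    noise = X[:, cols].copy()
    for j in range(n_noise):
        noise[:, j] = noise[rng.permutation(n), j]
    Xa = np.hstack([X, noise])
    ncomp, _ = best_ncomp(X, y, max_components, seed=seed)
    ncomp = max(1, min(ncomp, p, n - 2))

    coefs = np.empty((n, p + n_noise))
    for i in range(n):
        keep = np.arange(n) != i
        B, _, _ = pls_coefficient_paths(Xa[keep], y[keep], ncomp)
        coefs[i] = B[-1]
    mean_b = coefs.mean(axis=0)
    sd_b = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stability = np.where(sd_b > 0, mean_b / sd_b, 0.0)

    noise_stab = np.abs(stability[p:])
    if cutoff_rule == "max":
        cutoff = float(noise_stab.max())
    elif cutoff_rule == "quantile":
        cutoff = float(np.quantile(noise_stab, cutoff_quantile))
    else:
        raise ParameterError(f"unknown cutoff rule {cutoff_rule!r}")
    keep = np.nonzero(np.abs(stability[:p]) > cutoff)[0]
    trace = [{"cutoff": cutoff, "n_noise": n_noise,
              "stability": stability[:p].copy()}]
    if keep.size == 0:
        raise EmptySelectionError("UVE removed every channel")
    return SelectionResult(keep, "uve", trace)


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def spa_select(X: np.ndarray, y: np.ndarray, max_vars: int = 20,
               folds: int = 5, seed: int = 0) -> SelectionResult:
    """Successive projections algorithm.

    From every starting channel a chain is grown by repeatedly appending the
    channel with the largest norm after projection orthogonal to the chain's
    span (minimal collinearity); each chain prefix is scored by k-fold
    linear-regression RMSE and the overall minimum wins.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if max_vars >= min(n, p):
        raise ParameterError(f"max_vars must be < min(n, p) = {min(n, p)}")
    variances = X.var(axis=0)
    usable = np.nonzero(variances > 0)[0]
    if usable.size < p:
        warnings.warn(f"SPA: excluded {p - usable.size} zero-variance channels",
                      stacklevel=2)
    if usable.size == 0:
        raise EmptySelectionError("SPA: all channels have zero variance")

    Xc = X - X.mean(axis=0)
    folds_idx = _fold_indices(n, folds, seed)

    best = (np.inf, None, None)
    trace = []
    for start in usable:
        chain = _spa_chain(Xc, int(start), min(max_vars, usable.size))
        for k in range(1, len(chain) + 1):
            idx = np.asarray(chain[:k])
            rmse = _cv_ols_rmse(X[:, idx], y, folds_idx)
            trace.append({"start": int(start), "size": k, "rmse": float(rmse)})
            if rmse < best[0] - 1e-15:
                best = (rmse, idx, len(trace) - 1)
    if best[1] is None:
        raise EmptySelectionError("SPA found no usable chain")
    return SelectionResult(best[1], "spa", trace, best_run=best[2])


def _spa_chain(Xc: np.ndarray, start: int, max_vars: int) -> list[int]:
    """Grow one projection chain; stops early if all residuals vanish."""
    p = Xc.shape[1]
    residual = Xc.copy()
    chain = [start]
    for _ in range(max_vars - 1):
        v = residual[:, chain[-1]]
        nv = v @ v
        if nv <= 1e-12 * max(1.0, np.abs(Xc).max() ** 2):
            break
        proj = (residual.T @ v) / nv
        residual = residual - np.outer(v, proj)
        norms = np.einsum("ij,ij->j", residual, residual)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-12 * max(1.0, np.abs(Xc).max() ** 2):
            break
        chain.append(nxt)
    return chain


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[i::folds] for i in range(min(folds, n))]


def _cv_ols_rmse(X: np.ndarray, y: np.ndarray, folds_idx: list[np.ndarray]) -> float:
    n = y.size
    press = 0.0
    for test in folds_idx:
        train = np.setdiff1d(np.arange(n), test)
        A = np.hstack([np.ones((train.size, 1)), X[train]])
        coef, *_ = np.linalg.lstsq(A, y[train], rcond=None)
        pred = np.hstack([np.ones((test.size, 1)), X[test]]) @ coef
        press += np.sum((pred - y[test]) ** 2)
    return math.sqrt(press / n)


# ---------------------------------------------------------------------------
# siPLS
# ---------------------------------------------------------------------------

def sipls_select(X: np.ndarray, y: np.ndarray, n_intervals: int = 20,
                 combo_sizes: tuple[int, ...] = (2, 3), folds: int = 5,
                 max_components: int = MAX_COMPONENTS, seed: int = 0,
                 max_combos: int = 100_000) -> SelectionResult:
    """Synergy-interval PLS: exhaustively score interval combinations by
    RMSECV; the best combination's channels win (lexicographically first on
    ties)."""
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n_intervals < 1 or n_intervals > p:
        raise ParameterError(f"n_intervals must lie in [1, {p}]")
    if n_intervals == 1:
        return SelectionResult(np.arange(p), "sipls",
                               [{"combo": (0,), "rmsecv": float("nan")}], 0)
    if any(c < 1 or c > n_intervals for c in combo_sizes):
        raise ParameterError("combo sizes must lie in [1, n_intervals]")
    bounds = np.linspace(0, p, n_intervals + 1).astype(int)
    intervals = [np.arange(bounds[i], bounds[i + 1]) for i in range(n_intervals)]
    intervals = [iv for iv in intervals if iv.size]

    combos = []
    for size in sorted(set(combo_sizes)):
        combos.extend(itertools.combinations(range(len(intervals)), size))
    if len(combos) > max_combos:
        raise ParameterError(
            f"{len(combos)} interval combinations exceed budget {max_combos}")

    best = (np.inf, None, None)
    trace = []
    for run, combo in enumerate(combos):
        idx = np.concatenate([intervals[i] for i in combo])
        rmse = float(rmsecv_path(X[:, idx], y, max_components, folds, seed).min())
        trace.append({"combo": combo, "n_variables": int(idx.size),
                      "rmsecv": rmse})
        if rmse < best[0] - 1e-15:
            best = (rmse, idx, run)
    return SelectionResult(best[1], "sipls", trace, best_run=best[2])


# ---------------------------------------------------------------------------
# comparison harness
# ---------------------------------------------------------------------------

SELECTORS = {
    "cars": lambda X, y, seed: cars_select(X, y, seed=seed),
    "uve": lambda X, y, seed: uve_select(X, y, seed=seed),
    "spa": lambda X, y, seed: spa_select(X, y, seed=seed),
    "sipls": lambda X, y, seed: sipls_select(X, y, seed=seed),
}


def compare_selectors(X_cal: np.ndarray, y_cal: np.ndarray,
                      X_val: np.ndarray, y_val: np.ndarray,
                      methods: tuple[str, ...] = ("cars", "uve", "spa", "sipls"),
                      folds: int = 5, seed: int = 0):
    """Rank selectors by validation Rp2 of a common downstream PLSR model.

    Returns a pandas DataFrame (method, n_selected, rp2, rmsep) sorted by
    rp2 descending.
    """
    import pandas as pd

    from .evaluate import r_squared, rmse

    if len(methods) < 2:
        raise ParameterError("need >= 2 methods to compare")
    rows = []
    for method in methods:
        if method not in SELECTORS:
            raise ParameterError(f"unknown selector {method!r}")
        result = SELECTORS[method](X_cal, y_cal, seed)
        idx = result.selected_indices
        k, _ = best_ncomp(X_cal[:, idx], y_cal, folds=folds, seed=seed)
        from ._pls import pls_fit_predictor
        predict, _ = pls_fit_predictor(X_cal[:, idx], y_cal, k)
        pred = predict(X_val[:, idx])
        rows.append({"method": method, "n_selected": int(idx.size),
                     "rp2": r_squared(y_val, pred), "rmsep": rmse(y_val, pred)})
    return (pd.DataFrame(rows)
            .sort_values("rp2", ascending=False, kind="stable")
            .reset_index(drop=True))
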