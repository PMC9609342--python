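"""Mahalanobis-distance outlier screening of preprocessed spectra.

Distances are computed in a principal-component score space (raw channel
covariance is singular at typical n), against that space's mean and
covariance.  Samples beyond a threshold -- mean + k*sd of the distance
distribution by default, or a chi-square quantile -- are flagged and
removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .errors import NumericalError, ParameterError, ScreeningDegenerateError
from .spectra import SpectraMatrix

DEFAULT_VARIANCE = 0.95
MAX_SCORES = 10


def mahalanobis_distances(m: SpectraMatrix, n_scores: int | str = "auto",
                          variance: float = DEFAULT_VARIANCE) -> np.ndarray:
    """Per-sample Mahalanobis distance in PCA score space.

    ``n_scores="auto"`` keeps the smallest number of components explaining
    ``variance`` of the total, capped at ``MAX_SCORES``.
    """
    n = m.n_samples
    if isinstance(n_scores, str):
        if n_scores != "auto":
            raise ParameterError(f"n_scores must be an int or 'auto', got {n_scores!r}")
        k_fit = min(MAX_SCORES, n - 2, m.n_channels)
        if k_fit < 1:
            raise ParameterError("need more samples for screening")
        pca = PCA(n_components=k_fit, svd_solver="covariance_eigh")
        scores = pca.fit_transform(m.intensities)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance) + 1)
        k = min(k, k_fit)
        scores = scores[:, :k]
    else:
        k = int(n_scores)
        if n <= k + 1:
            raise ParameterError(
                f"sample count ({n}) must exceed n_scores + 1 ({k + 1})")
        pca = PCA(n_components=k, svd_solver="covariance_eigh")
        scores = pca.fit_transform(m.intensities)

    mu = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    cov = np.atleast_2d(cov)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(logdet):
        raise NumericalError(
            f"singular covariance in {scores.shape[1]}-score space; "
            "reduce n_scores")
    centered = scores - mu
    solved = np.linalg.solve(cov, centered.T).T
    d2 = np.einsum("ij,ij->i", centered, solved)
    return np.sqrt(np.maximum(d2, 0.0))


@dataclass
class ScreeningResult:
    distances: np.ndarray           # aligned with input_ids
    threshold: float
    flagged_ids: list[str]
    retained: SpectraMatrix
    input_ids: list[str] = field(default_factory=list)
    rule: str = "mean3sd"
    n_scores: int | None = None

    def to_report(self) -> dict:
        return {
            "rule": self.rule,
            "threshold": float(self.threshold),
            "n_scores": self.n_scores,
            "n_flagged": len(self.flagged_ids),
            "n_retained": self.retained.n_samples,
            "flagged_ids": list(self.flagged_ids),
            "distances": {sid: float(d)
                          for sid, d in zip(self.input_ids, self.distances)},
        }


def flag_outliers(m: SpectraMatrix, distances: np.ndarray,
                  rule: str = "mean3sd", k: float = 3.0,
                  chi2_q: float = 0.999, dof: int | None = None,
                  ) -> ScreeningResult:
    """Flag samples with distance above a threshold; return the survivors.

    rules: ``"mean3sd"`` (threshold = mean + k*sd of the distances) or
    ``"chi2"`` (sqrt of the chi-square ``chi2_q`` quantile at ``dof``).
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size != m.n_samples:
        raise ParameterError("distance vector length mismatch")
    if m.n_samples < 3:
        raise ParameterError("need at least 3 samples to screen")
    if rule == "mean3sd":
        threshold = float(distances.mean() + k * distances.std(ddof=1))
    elif rule == "chi2":
        if dof is None:
            raise ParameterError("chi2 rule requires dof (the score count)")
        threshold = float(np.sqrt(stats.chi2.ppf(chi2_q, dof)))
    else:
        raise ParameterError(f"unknown screening rule {rule!r}")

    mask = distances <= threshold
    if not mask.any():
        raise ScreeningDegenerateError("screening flagged every sample")
    flagged_ids = [sid for sid, keep in zip(m.sample_ids, mask) if not keep]
    retained_ids = [sid for sid, keep in zip(m.sample_ids, mask) if keep]
    retained = m.select_samples(retained_ids)
    return ScreeningResult(distances=distances, threshold=threshold,
                           flagged_ids=flagged_ids, retained=retained,
                           input_ids=list(m.sample_ids), rule=rule)


def screen(m: SpectraMatrix, n_scores: int | str = "auto",
           rule: str = "mean3sd", k: float = 3.0,
           chi2_q: float = 0.999) -> ScreeningResult:
    """Distances + flagging in one call (the CLI entry point)."""
    distances = mahalanobis_distances(m, n_scores=n_scores)
    # recover the effective score count for the chi2 dof
    eff = _effective_scores(m, n_scores)
    result = flag_outliers(m, distances, rule=rule, k=k, chi2_q=chi2_q, dof=eff)
    result.n_scores = eff
    return result


def _effective_scores(m: SpectraMatrix, n_scores: int | str) -> int:
    if isinstance(n_scores, str):
        k_fit = min(MAX_SCORES, m.n_samples - 2, m.n_channels)
        pca = PCA(n_components=k_fit, svd_solver="covariance_eigh")
        pca.fit(m.intensities)
        cum = np.cumsum(pca.explained_variance_ratio_)
        return int(min(np.searchsorted(cum, DEFAULT_VARIANCE) + 1, k_fit))
    return int(n_scores)
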