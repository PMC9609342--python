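"""Kennard-Stone calibration/validation partitioning.

Greedy max-min selection on Euclidean distances between (preprocessed)
spectra: seed with the two mutually most distant samples, then repeatedly
add the sample whose minimum distance to the chosen set is largest.  Ties
break to the lowest sample index, so the split is deterministic for a given
input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import ParameterError
from .spectra import SpectraMatrix


@dataclass(frozen=True)
class CalibrationSplit:
    calibration_ids: tuple[str, ...]   # in selection order
    validation_ids: tuple[str, ...]
    ratio: tuple[int, int]

    def to_dict(self) -> dict:
        return {"ratio": f"{self.ratio[0]}:{self.ratio[1]}",
                "calibration_ids": list(self.calibration_ids),
                "validation_ids": list(self.validation_ids)}


def parse_ratio(ratio: str | tuple[int, int]) -> tuple[int, int]:
    if isinstance(ratio, str):
        parts = ratio.split(":")
        if len(parts) != 2:
            raise ParameterError(f"ratio must look like '4:1', got {ratio!r}")
        ratio = (int(parts[0]), int(parts[1]))
    a, b = ratio
    if a < 1 or b < 0:
        raise ParameterError(f"invalid ratio {ratio}")
    return a, b


def calibration_size(n: int, ratio: tuple[int, int]) -> int:
    """|calibration| = floor(a*n / (a+b)) -- 264 of 330 at 4:1."""
    a, b = ratio
    return (a * n) // (a + b)


def kennard_stone_split(m: SpectraMatrix, ratio: str | tuple[int, int] = (4, 1),
                        ) -> CalibrationSplit:
    n = m.n_samples
    if n < 2:
        raise ParameterError("need at least 2 samples to split")
    ratio = parse_ratio(ratio)
    n_cal = calibration_size(n, ratio)
    if n_cal < 2:
        raise ParameterError(f"ratio {ratio} leaves a calibration set of {n_cal}")
    if n_cal >= n:
        raise ParameterError(f"ratio {ratio} leaves an empty validation set")

    order = kennard_stone_order(m.intensities, n_cal)
    cal_ids = tuple(m.sample_ids[i] for i in order)
    chosen = set(order)
    val_ids = tuple(sid for i, sid in enumerate(m.sample_ids) if i not in chosen)
    return CalibrationSplit(cal_ids, val_ids, ratio)


def kennard_stone_order(X: np.ndarray, n_select: int) -> list[int]:
    """Indices of the greedy max-min selection, in selection order."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ParameterError(f"n_select must lie in [2, {n}], got {n_select}")
    d = squareform(pdist(X, metric="euclidean"))
    # seed: the most distant pair, lowest indices on ties
    flat = np.argmax(d)  # argmax returns the first (row-major => lowest) maximum
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(d[selected[0]], d[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_dist))  # first maximum => lowest-index tie-break
        selected.append(nxt)
        min_dist = np.minimum(min_dist, d[nxt])
        min_dist[nxt] = -np.inf
    return selected
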