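"""Spectral pretreatment: replicate averaging, Savitzky-Golay smoothing,
and per-spectrum min-max scaling, applied in that fixed order.

Each step is a pure function returning a new :class:`SpectraMatrix`.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateSpectrumError, GroupingError, ParameterError
from .spectra import SpectraMatrix

DEFAULT_WINDOW = 11
DEFAULT_POLYORDER = 3


def average_replicates(m: SpectraMatrix,
                       replicate_key: str | Mapping[str, str] = "#",
                       ) -> SpectraMatrix:
    """Channel-wise mean over replicate groups, one output row per group.

    ``replicate_key`` is either a delimiter string (the group id is the part
    of the sample id before its last occurrence), the name of a mapping
    stored in ``m.meta`` (e.g. ``"replicate_of"``), or an explicit
    ``{row_id: group_id}`` mapping.  Group sizes are recorded in
    ``meta["replicate_counts"]``.
    """
    if isinstance(replicate_key, Mapping):
        mapping = dict(replicate_key)
    elif replicate_key in m.meta and isinstance(m.meta[replicate_key], Mapping):
        mapping = dict(m.meta[replicate_key])
    elif isinstance(replicate_key, str) and replicate_key:
        mapping = {sid: sid.rsplit(replicate_key, 1)[0] for sid in m.sample_ids}
    else:
        raise GroupingError(f"cannot resolve replicate key {replicate_key!r}")
    missing = [sid for sid in m.sample_ids if sid not in mapping]
    if missing:
        raise GroupingError(f"no replicate group for samples: {missing[:5]}")

    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(m.sample_ids):
        groups.setdefault(mapping[sid], []).append(i)

    out = np.vstack([m.intensities[rows].mean(axis=0) for rows in groups.values()])
    counts = {gid: len(rows) for gid, rows in groups.items()}
    meta = {k: v for k, v in m.meta.items() if k != "replicate_of"}
    meta["replicate_counts"] = counts
    return SpectraMatrix(m.axis.copy(), out, list(groups.keys()), meta)


def savgol_smooth(m: SpectraMatrix, window: int = DEFAULT_WINDOW,
                  polyorder: int = DEFAULT_POLYORDER) -> SpectraMatrix:
    """Per-spectrum Savitzky-Golay smoothing with polynomial-fit edges.

    Edge channels are filled by evaluating the least-squares polynomial of
    the nearest full window (``mode="interp"``), keeping channel count fixed.
    """
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ParameterError(
            f"window ({window}) must exceed polyorder ({polyorder})")
    if window > m.n_channels:
        raise ParameterError(
            f"window ({window}) exceeds channel count ({m.n_channels})")
    smoothed = savgol_filter(m.intensities, window, polyorder,
                             axis=1, mode="interp")
    meta = dict(m.meta)
    meta["savgol"] = {"window": window, "polyorder": polyorder}
    return SpectraMatrix(m.axis.copy(), smoothed, list(m.sample_ids), meta)


def minmax_scale(m: SpectraMatrix) -> SpectraMatrix:
    """Affinely map each spectrum onto [0, 1]: min -> 0, max -> 1."""
    lo = m.intensities.min(axis=1, keepdims=True)
    hi = m.intensities.max(axis=1, keepdims=True)
    flat = np.nonzero((hi - lo).ravel() == 0.0)[0]
    if flat.size:
        raise DegenerateSpectrumError(
            f"constant spectrum cannot be min-max scaled: "
            f"{[m.sample_ids[i] for i in flat]}"
        )
    scaled = (m.intensities - lo) / (hi - lo)
    meta = dict(m.meta)
    meta["minmax"] = True
    return SpectraMatrix(m.axis.copy(), scaled, list(m.sample_ids), meta)


def preprocess(m: SpectraMatrix, replicate_key: str | Mapping[str, str] | None = "#",
               window: int = DEFAULT_WINDOW,
               polyorder: int = DEFAULT_POLYORDER) -> SpectraMatrix:
    """Replicate averaging -> S-G smoothing -> min-max, the fixed order.

    Pass ``replicate_key=None`` to skip averaging (already-averaged input).
    """
    if replicate_key is not None:
        m = average_replicates(m, replicate_key)
    return minmax_scale(savgol_smooth(m, window, polyorder))
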