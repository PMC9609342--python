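"""Core data containers and I/O for spectral matrices and reference tables.

A :class:`SpectraMatrix` is the pipeline's currency: a ``(n_samples,
n_channels)`` intensity block on a strictly increasing wavenumber axis
(cm^-1), with unique sample ids and a free-form ``meta`` dict carrying
acquisition provenance.

Spectra are exchanged as *wide* CSV (first column ``wavenumber``, one column
per sample id, one row per channel) or as minimal JCAMP-DX files
(``##XYDATA=(XY..XY)``, one file per sample).
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

WAVENUMBER_COLUMN = "wavenumber"


@dataclass
class SpectraMatrix:
    """Samples x wavenumber-channels intensity matrix with axis metadata."""

    axis: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.axis.ndim != 1:
            raise FormatError("axis must be one-dimensional")
        if np.any(np.diff(self.axis) <= 0):
            raise FormatError("wavenumber axis must be strictly increasing")
        n, p = self.intensities.shape
        if p != self.axis.size:
            raise FormatError(
                f"intensity columns ({p}) do not match axis length ({self.axis.size})"
            )
        if n != len(self.sample_ids):
            raise FormatError(
                f"row count ({n}) does not match sample id count ({len(self.sample_ids)})"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise FormatError(f"duplicate sample ids: {dupes}")
        if not np.all(np.isfinite(self.intensities)):
            bad = [self.sample_ids[i] for i in
                   sorted(set(np.argwhere(~np.isfinite(self.intensities))[:, 0]))]
            raise FormatError(f"non-finite intensities in samples: {bad}")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def copy(self, **replacements) -> "SpectraMatrix":
        base = dict(
            axis=self.axis.copy(),
            intensities=self.intensities.copy(),
            sample_ids=list(self.sample_ids),
            meta=dict(self.meta),
        )
        base.update(replacements)
        return SpectraMatrix(**base)

    def select_samples(self, ids: Sequence[str]) -> "SpectraMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise DataError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in ids]
        return self.copy(intensities=self.intensities[rows], sample_ids=list(ids))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities.T, columns=self.sample_ids)
        df.insert(0, WAVENUMBER_COLUMN, self.axis)
        return df


# ---------------------------------------------------------------------------
# wide CSV
# ---------------------------------------------------------------------------

def write_spectra_csv(m: SpectraMatrix, path: str | os.PathLike) -> None:
    m.to_frame().to_csv(path, index=False)


def read_spectra_csv(path: str | os.PathLike) -> SpectraMatrix:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises many flavours for ragged/bad files
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a wavenumber column plus >= 1 sample column")
    cols = list(df.columns)
    if len(set(cols)) != len(cols) or any(str(c).endswith((".1", ".2", ".3")) for c in cols[1:]):
        # pandas mangles duplicate headers to 'x.1'; detect via the raw header
        with open(path) as fh:
            raw = fh.readline().rstrip("\n").split(",")
        if len(set(raw)) != len(raw):
            dupes = sorted({c for c in raw if raw.count(c) > 1})
            raise FormatError(f"{path}: duplicate sample columns {dupes}")
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(pd.isna(df.to_numpy())):
        rows = np.argwhere(pd.isna(df).to_numpy())
        raise FormatError(f"{path}: missing value at row {int(rows[0][0]) + 2}")
    order = np.argsort(axis, kind="stable")
    axis = axis[order]
    intensities = df.iloc[:, 1:].to_numpy(dtype=float).T[:, order]
    try:
        return SpectraMatrix(axis, intensities, [str(c) for c in df.columns[1:]])
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# minimal JCAMP-DX (XY..XY pairs), one spectrum per file
# ---------------------------------------------------------------------------

def write_jcamp(m: SpectraMatrix, directory: str | os.PathLike) -> list[Path]:
    """Write one ``<sample_id>.jdx`` per sample; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sid in enumerate(m.sample_ids):
        path = directory / f"{_safe_name(sid)}.jdx"
        with open(path, "w") as fh:
            fh.write("##TITLE=" + sid + "\n")
            fh.write("##JCAMP-DX=4.24\n")
            fh.write("##DATA TYPE=RAMAN SPECTRUM\n")
            fh.write("##XUNITS=1/CM\n##YUNITS=ARBITRARY UNITS\n")
            fh.write(f"##NPOINTS={m.n_channels}\n")
            fh.write(f"##FIRSTX={m.axis[0]:.6f}\n##LASTX={m.axis[-1]:.6f}\n")
            fh.write("##XYDATA=(XY..XY)\n")
            for x, y in zip(m.axis, m.intensities[i]):
                fh.write(f"{x:.6f} {y:.10g}\n")
            fh.write("##END=\n")
        paths.append(path)
    return paths


def read_jcamp(paths: Iterable[str | os.PathLike]) -> SpectraMatrix:
    """Read one-spectrum-per-file JCAMP-DX; a reversed axis is re-sorted."""
    axis_ref = None
    rows, ids = [], []
    for path in paths:
        title, xs, ys = None, [], []
        in_data = False
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("##"):
                    key, _, value = line[2:].partition("=")
                    key = key.strip().upper().replace(" ", "")
                    if key == "TITLE":
                        title = value.strip()
                    in_data = key == "XYDATA"
                    continue
                if in_data:
                    parts = line.replace(",", " ").split()
                    if len(parts) % 2 != 0:
                        raise FormatError(f"{path}:{lineno}: odd token count in XY data")
                    for j in range(0, len(parts), 2):
                        xs.append(float(parts[j]))
                        ys.append(float(parts[j + 1]))
        if not xs:
            raise FormatError(f"{path}: no XYDATA block found")
        order = np.argsort(np.asarray(xs), kind="stable")
        axis = np.asarray(xs)[order]
        if axis_ref is None:
            axis_ref = axis
        elif not np.allclose(axis, axis_ref):
            raise FormatError(f"{path}: axis differs from first file's axis")
        rows.append(np.asarray(ys)[order])
        ids.append(title if title else Path(path).stem)
    if axis_ref is None:
        raise FormatError("no JCAMP files given")
    return SpectraMatrix(axis_ref, np.vstack(rows), ids)


def read_spectra(path: str | os.PathLike, format: str = "csv") -> SpectraMatrix:
    """Read spectra from a wide CSV file or a directory of JCAMP-DX files."""
    if format == "csv":
        return read_spectra_csv(path)
    if format == "jcamp":
        p = Path(path)
        files = sorted(p.glob("*.jdx")) if p.is_dir() else [p]
        return read_jcamp(files)
    raise FormatError(f"unknown spectra format: {format!r}")


def write_spectra(m: SpectraMatrix, path: str | os.PathLike, format: str = "csv"):
    if format == "csv":
        return write_spectra_csv(m, path)
    if format == "jcamp":
        return write_jcamp(m, path)
    raise FormatError(f"unknown spectra format: {format!r}")


def _safe_name(sid: str) -> str:
    return "".join(c if (c.isalnum() or c in "-_.") else "_" for c in sid)


# ---------------------------------------------------------------------------
# reference values
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Tidy per-sample ground-truth values: (sample_id, analyte, value, units)."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "analyte", "value", "units")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"reference table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        dup = self.table.duplicated(subset=["sample_id", "analyte"])
        if dup.any():
            raise FormatError("duplicate (sample_id, analyte) rows in reference table")

    @property
    def analytes(self) -> list[str]:
        return sorted(self.table["analyte"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["sample_id"]))

    def values_for(self, analyte: str, sample_ids: Sequence[str]) -> np.ndarray:
        sub = self.table[self.table["analyte"] == analyte]
        if sub.empty:
            raise DataError(f"analyte {analyte!r} not in reference table")
        lookup = dict(zip(sub["sample_id"], sub["value"]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise DataError(f"reference values missing for samples: {missing[:5]}")
        return np.asarray([lookup[s] for s in sample_ids], dtype=float)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "ReferenceTable":
        return cls(pd.read_csv(path, dtype={"sample_id": str}))

    @classmethod
    def from_dict(cls, values: Mapping[str, Mapping[str, float]],
                  units: Mapping[str, str] | str = "ug/mL") -> "ReferenceTable":
        """Build from ``{sample_id: {analyte: value}}``."""
        rows = []
        for sid, per_analyte in values.items():
            for analyte, value in per_analyte.items():
                u = units if isinstance(units, str) else units.get(analyte, "ug/mL")
                rows.append((str(sid), analyte, float(value), u))
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))
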