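"""Spectrum containers and plain-text I/O.

A :class:`Spectrum` is one wavenumber axis (cm^-1, strictly increasing)
plus an intensity vector and metadata; a :class:`SpectrumSet` is a stack of
spectra sharing one axis with per-spectrum labels (cell id, culture time,
growth phase, replicate).  Supported formats are deliberately plain:
two-column delimited text for single spectra, and a matrix CSV whose first
column is the wavenumber axis with one column per spectrum, plus a sidecar
labels CSV (id, culture_time_h, replicate_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PhaseBoundaries, phases_for_times

AXIS_MIN_CM1 = 400.0
AXIS_MAX_CM1 = 2000.0


class SpectrumFormatError(ValueError):
    """Malformed spectrum file (bad cell, ragged columns, unsupported dialect)."""


class LabelError(ValueError):
    """Missing or inconsistent spectrum labels."""


class AlignmentError(ValueError):
    """Spectra do not share a wavenumber axis within tolerance."""


@dataclass
class Spectrum:
    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumFormatError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise SpectrumFormatError(
                f"axis length {self.wavenumbers.size} != "
                f"intensity length {self.intensities.size}")
        if self.wavenumbers.size and np.any(np.diff(self.wavenumbers) <= 0):
            raise SpectrumFormatError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectrumFormatError("intensities must be finite")
        if self.wavenumbers.size and not self.meta.get("allow_partial_axis", False):
            lo, hi = self.wavenumbers[0], self.wavenumbers[-1]
            if lo < AXIS_MIN_CM1 - 1e-9 or hi > AXIS_MAX_CM1 + 1e-9:
                raise SpectrumFormatError(
                    f"axis [{lo:g}, {hi:g}] outside the supported "
                    f"[{AXIS_MIN_CM1:g}, {AXIS_MAX_CM1:g}] cm^-1 range "
                    "(set meta['allow_partial_axis']=True to override)")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def copy_with(self, intensities: np.ndarray, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float), meta)


@dataclass
class SpectrumSet:
    """Aligned intensity matrix (n_spectra x n_channels) with per-spectrum labels."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    labels: pd.DataFrame  # columns: cell_id, culture_time_h, phase, replicate_index

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise AlignmentError("intensity matrix must be 2-D")
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise AlignmentError("matrix width must match axis length")
        if len(self.labels) != self.intensities.shape[0]:
            raise LabelError("one label row per spectrum required")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def phases(self) -> np.ndarray:
        return self.labels["phase"].to_numpy()

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.intensities[i],
                        meta=dict(self.labels.iloc[i]))


# ---------------------------------------------------------------------------
# single-spectrum I/O


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def read_spectrum(path: str | Path, dialect: str = "two-column") -> Spectrum:
    """Read a single spectrum from a two-column delimited text file.

    Descending axes are reversed (together with intensities).  Non-numeric
    cells raise :class:`SpectrumFormatError` naming the offending line.
    """
    if dialect != "two-column":
        raise SpectrumFormatError(f"unsupported dialect: {dialect!r}")
    path = Path(path)
    wn, it = [], []
    with open(path) as fh:
        delim = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            parts = [p for p in line.split(delim) if p != ""]
            if len(parts) != 2:
                # tolerate a single header line
                if lineno == 1 and not _is_number(parts[0] if parts else ""):
                    continue
                raise SpectrumFormatError(
                    f"{path.name}: expected 2 columns on line {lineno}, got {len(parts)}")
            if not (_is_number(parts[0]) and _is_number(parts[1])):
                if lineno == 1:
                    continue  # header
                raise SpectrumFormatError(
                    f"{path.name}: non-numeric value on line {lineno}: {line!r}")
            wn.append(float(parts[0]))
            it.append(float(parts[1]))
    if not wn:
        raise SpectrumFormatError(f"{path.name}: no data rows")
    w = np.asarray(wn)
    x = np.asarray(it)
    if w.size > 1 and w[0] > w[-1]:
        w, x = w[::-1], x[::-1]
    return Spectrum(w, x, meta={"source": str(path)})


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_spectrum(spectrum: Spectrum, path: str | Path, delimiter: str = ",") -> None:
    arr = np.column_stack([spectrum.wavenumbers, spectrum.intensities])
    np.savetxt(path, arr, delimiter=delimiter, fmt="%.17g")


# ---------------------------------------------------------------------------
# matrix I/O


def write_matrix(sset: SpectrumSet, path: str | Path, header_comment: str = "") -> None:
    """Matrix CSV: header row ``wavenumber,<id1>,<id2>,...``, one row per channel."""
    ids = [str(i) for i in sset.labels["spectrum_id"]] if "spectrum_id" in sset.labels \
        else [f"s{i}" for i in range(len(sset))]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("wavenumber," + ",".join(ids) + "\n")
        for j, w in enumerate(sset.wavenumbers):
            row = ",".join("%.10g" % v for v in sset.intensities[:, j])
            fh.write(f"{w:.6g},{row}\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a matrix CSV; returns (wavenumbers, intensities[n_spec, n_chan], ids)."""
    df = pd.read_csv(path, comment="#")
    if df.columns[0].lower() != "wavenumber":
        raise SpectrumFormatError("matrix CSV must start with a 'wavenumber' column")
    w = df.iloc[:, 0].to_numpy(dtype=float)
    mat = df.iloc[:, 1:].to_numpy(dtype=float).T
    return w, mat, [str(c) for c in df.columns[1:]]


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# assembly


def assemble_set(spectra: Sequence[Spectrum],
                 labels: pd.DataFrame | None = None,
                 boundaries: PhaseBoundaries | None = None,
                 resample_tolerance: float | None = None) -> SpectrumSet:
    """Stack spectra sharing an axis into a SpectrumSet and derive phase labels.

    ``labels`` needs a ``culture_time_h`` column (or every spectrum's meta must
    carry ``culture_time_h``); the growth phase is derived from it via the
    configured boundaries.  If axes differ and ``resample_tolerance`` is given,
    spectra are linearly interpolated onto the first spectrum's axis provided
    every target point is inside the source range.
    """
    if not spectra:
        raise AlignmentError("cannot assemble an empty spectrum list")
    axis = spectra[0].wavenumbers
    rows = []
    for k, sp in enumerate(spectra):
        if sp.wavenumbers.shape == axis.shape and np.allclose(sp.wavenumbers, axis):
            rows.append(sp.intensities)
            continue
        if resample_tolerance is None:
            raise AlignmentError(f"spectrum {k} axis differs and no resampling allowed")
        src = sp.wavenumbers
        if axis[0] < src[0] - resample_tolerance or axis[-1] > src[-1] + resample_tolerance:
            raise AlignmentError(
                f"spectrum {k}: target axis outside source range beyond tolerance")
        rows.append(np.interp(axis, src, sp.intensities))

    if labels is None:
        labels = pd.DataFrame([
            {
                "cell_id": sp.meta.get("cell_id", f"cell{k}"),
                "culture_time_h": sp.meta.get("culture_time_h"),
                "replicate_index": sp.meta.get("replicate_index", 0),
            }
            for k, sp in enumerate(spectra)
        ])
    labels = labels.copy().reset_index(drop=True)
    if len(labels) != len(spectra):
        raise LabelError("label count must equal spectrum count")
    if "phase" not in labels.columns:
        if "culture_time_h" not in labels.columns or labels["culture_time_h"].isna().any():
            raise LabelError("culture_time_h (or explicit phase) required for every spectrum")
        labels["phase"] = phases_for_times(labels["culture_time_h"], boundaries)
    return SpectrumSet(axis, np.vstack(rows), labels)


def average_replicates(sset: SpectrumSet, group_key: str = "cell_id") -> SpectrumSet:
    """Pointwise-mean the replicate spectra of each cell; labels are inherited.

    Replicates of one cell carrying different culture times or phases raise
    :class:`LabelError`.  Idempotent on singleton groups.
    """
    if group_key not in sset.labels.columns:
        raise LabelError(f"missing group key column {group_key!r}")
    keys = sset.labels[group_key].to_numpy()
    order = []  # first-appearance order
    seen = set()
    for k in keys:
        if k not in seen:
            order.append(k)
            seen.add(k)
    rows, lab_rows = [], []
    for k in order:
        idx = np.flatnonzero(keys == k)
        sub = sset.labels.iloc[idx]
        for col in ("culture_time_h", "phase"):
            if col in sub.columns and sub[col].nunique(dropna=False) > 1:
                raise LabelError(f"group {k!r}: inconsistent {col} across replicates")
        rows.append(sset.intensities[idx].mean(axis=0))
        lab = dict(sub.iloc[0])
        lab["n_replicates"] = int(idx.size)
        lab.pop("replicate_index", None)
        lab_rows.append(lab)
    return SpectrumSet(sset.wavenumbers, np.vstack(rows), pd.DataFrame(lab_rows))
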