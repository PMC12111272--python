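"""Domain containers for labelled absorbance spectra plus CSV I/O.

The central container is :class:`SpectraSet`: an ``n_samples x n_channels``
absorbance matrix on a strictly increasing wavelength grid (nm), with sample
ids and optional integer class labels.  Every stage of the pipeline consumes
and produces this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError, SpectraFormatError

#: Span of the effective instrument wavelength range (nm) used as the default
#: grid when synthesizing spectra.
DEFAULT_GRID_MIN_NM = 900.7592
DEFAULT_GRID_MAX_NM = 1674.9758


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise SpectraFormatError("wavelength grid needs at least 2 channels")
        if not np.all(np.isfinite(vals)):
            raise SpectraFormatError("wavelength grid contains non-finite values")
        if not np.all(np.diff(vals) > 0):
            raise SpectraFormatError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values)
        )

    @classmethod
    def uniform(
        cls,
        n_channels: int,
        lo: float = DEFAULT_GRID_MIN_NM,
        hi: float = DEFAULT_GRID_MAX_NM,
    ) -> "WavelengthGrid":
        """Uniform grid of ``n_channels`` points spanning [lo, hi] nm."""
        if n_channels < 2:
            raise ParameterError("n_channels must be >= 2")
        return cls(np.linspace(lo, hi, n_channels))


@dataclass
class SpectraSet:
    """Absorbance matrix + wavelength grid + sample ids (+ optional labels).

    ``labels`` are integer class indices ``0..C-1``; ``class_names`` maps each
    index back to its name (e.g. the five origin codes ZY, YM, WW, BY, DH).
    """

    absorbance: np.ndarray
    grid: WavelengthGrid
    sample_ids: list[str]
    labels: np.ndarray | None = None
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.absorbance, dtype=float)
        if A.ndim != 2:
            raise SpectraFormatError("absorbance must be a 2-D matrix")
        if A.shape[1] != len(self.grid):
            raise SpectraFormatError(
                f"absorbance has {A.shape[1]} channels but grid has {len(self.grid)}"
            )
        if not np.all(np.isfinite(A)):
            raise SpectraFormatError("absorbance contains non-finite values")
        self.absorbance = A
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != A.shape[0]:
            raise SpectraFormatError("sample_ids length does not match row count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SpectraFormatError("sample_ids must be unique")
        if self.labels is not None:
            y = np.asarray(self.labels, dtype=int)
            if y.shape != (A.shape[0],):
                raise SpectraFormatError("labels length does not match row count")
            if self.class_names is None:
                raise SpectraFormatError("labels present but class_names missing")
            C = len(self.class_names)
            if y.size and (y.min() < 0 or y.max() >= C):
                raise SpectraFormatError("labels outside [0, C-1]")
            self.labels = y

    # ------------------------------------------------------------------ views
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    @property
    def n_classes(self) -> int:
        if self.class_names is None:
            raise ParameterError("this SpectraSet has no labels")
        return len(self.class_names)

    def with_absorbance(self, A: np.ndarray) -> "SpectraSet":
        """Same metadata, new absorbance matrix (shape must be preserved)."""
        return replace(self, absorbance=np.asarray(A, dtype=float))

    def subset(self, idx: Sequence[int] | np.ndarray) -> "SpectraSet":
        idx = np.asarray(idx)
        return SpectraSet(
            absorbance=self.absorbance[idx],
            grid=self.grid,
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
            class_names=self.class_names,
        )


@dataclass
class ClassMeanSpectra:
    """One arithmetic-mean spectrum per class, on the parent grid."""

    means: np.ndarray  # C x n_channels
    grid: WavelengthGrid
    class_names: list[str]

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (len(self.class_names), len(self.grid)):
            raise SpectraFormatError("class-mean matrix shape mismatch")


# --------------------------------------------------------------------- I/O
ID_COLUMN = "sample_id"


def read_spectra_csv(path, label_column: str = "label") -> SpectraSet:
    """Read a spectra CSV: wavelength header, one row per sample.

    A ``sample_id`` column is optional (row numbers are used if absent); the
    label column is optional and configurable.  Class names are encoded to
    integer labels in first-appearance order.
    """
    df = pd.read_csv(path, header=0, dtype=str)
    if df.isna().any().any():
        raise SpectraFormatError(f"{path}: ragged or missing cells")
    label_col_present = label_column in df.columns
    if not label_col_present and label_column != "label":
        raise KeyError(f"label column {label_column!r} not present in {path}")
    meta_cols = [c for c in (ID_COLUMN, label_column) if c in df.columns]
    wl_cols = [c for c in df.columns if c not in meta_cols]
    if not wl_cols:
        raise SpectraFormatError(f"{path}: no wavelength columns found")
    non_numeric = [c for c in wl_cols if not _is_number(c)]
    if non_numeric:
        raise SpectraFormatError(
            f"{path}: non-numeric wavelength columns {non_numeric!r}"
        )
    wavelengths = np.array([float(c) for c in wl_cols])
    if not np.all(np.diff(wavelengths) > 0):
        raise SpectraFormatError(f"{path}: wavelength header not strictly increasing")
    try:
        A = df[wl_cols].to_numpy(dtype=float)
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric spectral cell ({exc})") from exc
    ids = (
        df[ID_COLUMN].tolist()
        if ID_COLUMN in df.columns
        else [str(i) for i in range(len(df))]
    )
    labels = None
    class_names = None
    if label_col_present:
        names = df[label_column].tolist()
        class_names = list(dict.fromkeys(names))  # first-appearance order
        lut = {name: i for i, name in enumerate(class_names)}
        labels = np.array([lut[n] for n in names], dtype=int)
    return SpectraSet(A, WavelengthGrid(wavelengths), ids, labels, class_names)


def write_spectra_csv(spectra: SpectraSet, path, label_column: str = "label") -> None:
    """Write the CSV form read by :func:`read_spectra_csv` (17 sig. digits)."""
    cols = {ID_COLUMN: spectra.sample_ids}
    for j, wl in enumerate(spectra.grid.values):
        cols[repr(float(wl))] = spectra.absorbance[:, j]
    df = pd.DataFrame(cols)
    if spectra.labels is not None:
        df[label_column] = [spectra.class_names[i] for i in spectra.labels]
    df.to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------- utilities
def average_replicates(spectra: SpectraSet, group_ids: Sequence[str]) -> SpectraSet:
    """Average replicate scans: one output spectrum per group (mean of members).

    Groups are emitted in first-appearance order.  Labels, when present, must
    agree within each group.
    """
    if len(group_ids) != spectra.n_samples:
        raise ParameterError("group_ids length must equal n_samples")
    order = list(dict.fromkeys(group_ids))
    rows, ids, labels = [], [], []
    gid_arr = np.asarray(group_ids)
    for g in order:
        members = np.flatnonzero(gid_arr == g)
        rows.append(spectra.absorbance[members].mean(axis=0))
        ids.append(str(g))
        if spectra.labels is not None:
            member_labels = set(spectra.labels[members].tolist())
            if len(member_labels) != 1:
                raise ConsistencyError(
                    f"group {g!r} mixes labels {sorted(member_labels)}"
                )
            labels.append(member_labels.pop())
    return SpectraSet(
        np.vstack(rows),
        spectra.grid,
        ids,
        np.array(labels, dtype=int) if spectra.labels is not None else None,
        spectra.class_names,
    )


def class_means(spectra: SpectraSet) -> ClassMeanSpectra:
    """Per-class arithmetic mean spectra (requires labels, no empty class)."""
    if spectra.labels is None:
        raise ParameterError("class_means requires labels")
    C = spectra.n_classes
    means = np.empty((C, spectra.n_channels))
    for c in range(C):
        members = spectra.labels == c
        if not members.any():
            raise ParameterError(f"class {spectra.class_names[c]!r} is empty")
        means[c] = spectra.absorbance[members].mean(axis=0)
    return ClassMeanSpectra(means, spectra.grid, list(spectra.class_names))


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
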