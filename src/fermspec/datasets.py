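"""Core data containers shared across the package.

The containers mirror the bilinear calibration setup: a :class:`SpectraSet`
holds the absorbance matrix ``X`` (samples x wavelengths), a
:class:`ConcentrationTable` holds the reference matrix ``Y`` (samples x
analytes, g/L), and a :class:`CalibrationDataset` keeps the two row-aligned.
Wavelengths are physical nanometres throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Default usable NIR window of the diffuse-reflectance instrument class
#: modelled here (short-wave NIR, first/second overtone region).
NIR_RANGE = (900.0, 1650.0)


class FermspecError(Exception):
    """Base class for package-specific errors."""


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing wavelength axis in nm.

    Parameters
    ----------
    points
        Wavelength values in nm, strictly increasing.
    bounds
        Inclusive admissible range; ``None`` disables the range check.
        Defaults to the 900-1650 nm short-wave NIR window.
    """

    points: np.ndarray
    bounds: tuple[float, float] | None = NIR_RANGE

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("wavelength grid needs at least two points")
        if not np.all(np.diff(pts) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.bounds is not None:
            lo, hi = self.bounds
            if pts[0] < lo or pts[-1] > hi:
                raise ValueError(
                    f"grid [{pts[0]}, {pts[-1]}] nm outside admissible "
                    f"range [{lo}, {hi}] nm"
                )
        object.__setattr__(self, "points", pts)

    @classmethod
    def regular(cls, lo: float = 900.0, hi: float = 1650.0,
                step: float = 2.0) -> "WavelengthGrid":
        """Regular grid from `lo` to `hi` inclusive with spacing `step` nm."""
        if step <= 0:
            raise ValueError("grid spacing must be positive")
        n = int(np.floor((hi - lo) / step + 1e-9)) + 1
        return cls(lo + step * np.arange(n))

    def __len__(self) -> int:
        return self.points.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.points, dtype=dtype)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.points[0]), float(self.points[-1])


def _as_segments(segments, p: int) -> tuple[tuple[int, int], ...]:
    if segments is None:
        return ((0, p),)
    segs = tuple((int(a), int(b)) for a, b in segments)
    last = 0
    for a, b in segs:
        if a != last or b <= a:
            raise ValueError(f"segments must tile [0, {p}) in order; got {segs}")
        last = b
    if last != p:
        raise ValueError(f"segments must cover all {p} wavelengths; got {segs}")
    return segs


@dataclass
class SpectraSet:
    """Absorbance spectra on a shared wavelength axis.

    ``segments`` records contiguous wavelength blocks (as half-open index
    ranges) left after region selection; derivative filters never reach
    across a segment boundary, so excluding e.g. the 1350-1410 nm water-vapour
    band keeps the two flanks independent.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: list[str]
    segments: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be 1-D")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        n, p = self.values.shape
        if p != self.wavelengths.size:
            raise ValueError(
                f"values have {p} columns but grid has {self.wavelengths.size}"
            )
        if len(self.sample_ids) != n:
            raise ValueError("one sample id per spectrum required")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        self.segments = _as_segments(self.segments, p)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "SpectraSet":
        """Same axis and ids, new absorbance matrix."""
        return replace(self, values=values)

    def take(self, indices: Sequence[int]) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            self.wavelengths,
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            self.segments,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.wavelengths,
        )


@dataclass
class ConcentrationTable:
    """Reference analyte concentrations in g/L, row-aligned with spectra."""

    analytes: list[str]
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.analytes = [str(a) for a in self.analytes]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, m = self.values.shape
        if m != len(self.analytes):
            raise ValueError("one column per analyte required")
        if len(self.sample_ids) != n:
            raise ValueError("one sample id per row required")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if len(set(self.analytes)) != m:
            raise ValueError("analyte names must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, analyte: str) -> np.ndarray:
        try:
            j = self.analytes.index(analyte)
        except ValueError:
            raise KeyError(f"unknown analyte {analyte!r}") from None
        return self.values[:, j]

    def take(self, indices: Sequence[int]) -> "ConcentrationTable":
        idx = np.asarray(indices, dtype=int)
        return ConcentrationTable(
            self.analytes, self.values[idx], [self.sample_ids[i] for i in idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.analytes,
        )


@dataclass
class CalibrationDataset:
    """Row-aligned (X, Y) pair, optionally with sampling timestamps in h."""

    spectra: SpectraSet
    concentrations: ConcentrationTable
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.spectra.sample_ids != self.concentrations.sample_ids:
            raise ValueError("spectra and concentrations must share sample ids "
                             "in the same order")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.size != self.spectra.n_samples:
                raise ValueError("one timestamp per sample required")

    @property
    def n_samples(self) -> int:
        return self.spectra.n_samples

    @property
    def sample_ids(self) -> list[str]:
        return self.spectra.sample_ids

    def take(self, indices: Sequence[int]) -> "CalibrationDataset":
        idx = np.asarray(indices, dtype=int)
        ts = None if self.timestamps is None else self.timestamps[idx]
        return CalibrationDataset(
            self.spectra.take(idx), self.concentrations.take(idx), ts
        )

    def subset_ids(self, ids: Iterable[str]) -> "CalibrationDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"sample id {exc.args[0]!r} not in dataset") from None
        return self.take(idx)
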