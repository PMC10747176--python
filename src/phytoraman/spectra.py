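"""Core spectral containers.

A :class:`Spectrum` is a single acquisition (wavenumber axis + intensities +
acquisition metadata); a :class:`SpectraSet` stacks many spectra sharing one
axis, with a per-spectrum metadata table.  All pipeline stages consume and
return these two types.

An axis may contain gaps (e.g. after cropping to the fingerprint and C-H
stretch regions): :func:`segment_slices` recovers the contiguous segments,
which baseline correction and smoothing treat independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ("spectrum_id", "day", "session", "replicate")


def _as_1d_float(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {out.shape}")
    return out


@dataclass
class Spectrum:
    """One Raman acquisition on a strictly ascending wavenumber axis (cm^-1)."""

    axis: np.ndarray
    intensities: np.ndarray
    spectrum_id: str = "s0"
    day: int = 0
    session: int = 0
    replicate: int = 0

    def __post_init__(self) -> None:
        self.axis = _as_1d_float(self.axis, "axis")
        self.intensities = _as_1d_float(self.intensities, "intensities")
        if self.axis.shape != self.intensities.shape:
            raise ValueError(
                f"axis ({self.axis.size}) and intensities ({self.intensities.size}) "
                "must have equal length"
            )
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if not np.all(np.isfinite(self.axis)) or not np.all(np.isfinite(self.intensities)):
            raise ValueError("axis and intensities must be finite")

    @property
    def n_points(self) -> int:
        return self.axis.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass
class SpectraSet:
    """A stack of spectra on a common axis with a per-spectrum metadata table.

    ``matrix`` has one row per spectrum; ``meta`` carries the columns
    ``spectrum_id, day, session, replicate`` aligned with the rows.
    """

    axis: np.ndarray
    matrix: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.axis = _as_1d_float(self.axis, "axis")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(f"matrix must be 2-D, got shape {self.matrix.shape}")
        if self.matrix.shape[1] != self.axis.size:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but axis has "
                f"{self.axis.size} points"
            )
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if not isinstance(self.meta, pd.DataFrame):
            self.meta = pd.DataFrame(self.meta)
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta table missing columns: {missing}")
        if len(self.meta) != self.matrix.shape[0]:
            raise ValueError(
                f"meta table has {len(self.meta)} rows but matrix has "
                f"{self.matrix.shape[0]}"
            )
        if self.meta["spectrum_id"].duplicated().any():
            dups = self.meta.loc[self.meta["spectrum_id"].duplicated(), "spectrum_id"]
            raise ValueError(f"duplicate spectrum ids: {sorted(set(dups))}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix must be finite")
        self.meta = self.meta.reset_index(drop=True)

    # -- basic introspection -------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_points(self) -> int:
        return self.axis.size

    def __len__(self) -> int:
        return self.n_spectra

    def days(self) -> list[int]:
        return sorted(int(d) for d in self.meta["day"].unique())

    def day_rows(self, day: int) -> np.ndarray:
        """Row indices of the spectra acquired on ``day``."""
        return np.flatnonzero(self.meta["day"].to_numpy() == day)

    def spectrum(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        return Spectrum(
            axis=self.axis,
            intensities=self.matrix[i],
            spectrum_id=str(row["spectrum_id"]),
            day=int(row["day"]),
            session=int(row["session"]),
            replicate=int(row["replicate"]),
        )

    def iter_spectra(self) -> Iterator[Spectrum]:
        for i in range(self.n_spectra):
            yield self.spectrum(i)

    # -- construction / transformation ---------------------------------------
    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectraSet":
        if not spectra:
            raise ValueError("need at least one spectrum")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if not np.array_equal(s.axis, axis):
                raise ValueError(f"spectrum {s.spectrum_id!r} is not on the shared axis")
        meta = pd.DataFrame(
            {
                "spectrum_id": [s.spectrum_id for s in spectra],
                "day": [s.day for s in spectra],
                "session": [s.session for s in spectra],
                "replicate": [s.replicate for s in spectra],
            }
        )
        return cls(axis=axis, matrix=np.vstack([s.intensities for s in spectra]), meta=meta)

    def with_matrix(self, matrix: np.ndarray, axis: np.ndarray | None = None) -> "SpectraSet":
        return SpectraSet(
            axis=self.axis if axis is None else axis,
            matrix=matrix,
            meta=self.meta.copy(),
        )

    def sort_by_meta(self) -> "SpectraSet":
        """Rows sorted by (day, session, replicate); the pipeline's canonical order."""
        order = self.meta.sort_values(
            ["day", "session", "replicate"], kind="mergesort"
        ).index.to_numpy()
        return SpectraSet(
            axis=self.axis,
            matrix=self.matrix[order],
            meta=self.meta.iloc[order].reset_index(drop=True),
        )


def segment_slices(axis: np.ndarray, gap_factor: float = 10.0) -> list[slice]:
    """Contiguous segments of an axis that may contain gaps.

    A gap is a step larger than ``gap_factor`` times the median step; the two
    cropped spectral ranges (e.g. 350-1800 and 2800-3050 cm^-1) then appear as
    two segments.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.size < 2:
        return [slice(0, axis.size)]
    d = np.diff(axis)
    breaks = np.flatnonzero(d > gap_factor * np.median(d))
    edges = [0, *(int(b) + 1 for b in breaks), axis.size]
    return [slice(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
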