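"""Spectral-quality layer based on pairwise Pearson correlation.

On a well-behaved culture run the preprocessed spectra of one day are highly
mutually correlated (repeatability) and drift away from the first day as the
physiology changes (similarity to reference); the all-pairs correlation map
shows that structure as day-blocks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectraSet

__all__ = [
    "CorrelationMap",
    "correlation_map",
    "repeatability",
    "similarity_to_reference",
    "median_spectrum",
]


def _check_non_constant(s: SpectraSet) -> None:
    sd = s.matrix.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        ids = s.meta["spectrum_id"].iloc[flat].tolist()
        raise ValueError(f"constant spectra have undefined correlation: {ids}")


@dataclass
class CorrelationMap:
    """All-pairs Pearson correlation of preprocessed spectra.

    Rows/columns are ordered by (day, session, replicate); ``day_slices``
    maps each day to its index range so the day-blocks of the map can be
    addressed directly.
    """

    matrix: np.ndarray
    ids: list[str]
    meta: pd.DataFrame = field(repr=False)
    day_slices: dict[int, slice]
    overall_mean: float
    overall_sd: float


def correlation_map(spectra: SpectraSet) -> CorrelationMap:
    """Pearson correlation of every spectrum pair over all retained points.

    The returned matrix is exactly symmetric with a unit diagonal; the
    aggregate mean/sd are taken over the strict upper triangle.
    """
    if spectra.n_spectra < 2:
        raise ValueError("correlation map needs at least 2 spectra")
    s = spectra.sort_by_meta()
    _check_non_constant(s)
    m = np.corrcoef(s.matrix)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    iu = np.triu_indices(m.shape[0], k=1)
    day_slices: dict[int, slice] = {}
    days = s.meta["day"].to_numpy()
    for day in s.days():
        rows = np.flatnonzero(days == day)
        day_slices[day] = slice(int(rows[0]), int(rows[-1]) + 1)
    return CorrelationMap(
        matrix=m,
        ids=s.meta["spectrum_id"].tolist(),
        meta=s.meta,
        day_slices=day_slices,
        overall_mean=float(m[iu].mean()),
        overall_sd=float(m[iu].std(ddof=1)),
    )


def _pair_stats(values: np.ndarray) -> tuple[float, float, int]:
    n = values.size
    if n == 0:
        return float("nan"), float("nan"), 0
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return float(values.mean()), sd, n


def repeatability(spectra: SpectraSet, pool_sessions: bool = True) -> pd.DataFrame:
    """Within-day (or within-session) repeatability of the spectra.

    For each group the mean and standard deviation of the m(m-1)/2 pairwise
    correlations, excluding self-pairs.  Groups with fewer than 2 spectra are
    reported with NaN statistics rather than failing the aggregate.

    Returns a table with columns ``day [, session], mean, sd, n_pairs``.
    """
    cm = correlation_map(spectra)
    keys = ["day"] if pool_sessions else ["day", "session"]
    records = []
    for group, sub in cm.meta.groupby(keys, sort=True):
        rows = sub.index.to_numpy()
        block = cm.matrix[np.ix_(rows, rows)]
        iu = np.triu_indices(rows.size, k=1)
        mean, sd, n = _pair_stats(block[iu])
        rec = dict(zip(keys, group if isinstance(group, tuple) else (group,)))
        rec.update(mean=mean, sd=sd, n_pairs=n)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def similarity_to_reference(
    spectra: SpectraSet, reference_day: int = 0, pool_sessions: bool = True
) -> pd.DataFrame:
    """Per-day correlation of the spectra with those of a reference day.

    For each group, mean and sd over all cross-pairs (group spectrum x
    reference spectrum).  For the reference day itself the self-pairs are
    excluded and each unordered pair counted once, so its statistic equals
    the within-day repeatability.
    """
    cm = correlation_map(spectra)
    day_col = cm.meta["day"].to_numpy()
    ref_rows = np.flatnonzero(day_col == reference_day)
    if ref_rows.size == 0:
        raise ValueError(f"reference day {reference_day} has no spectra")
    keys = ["day"] if pool_sessions else ["day", "session"]
    records = []
    for group, sub in cm.meta.groupby(keys, sort=True):
        rows = sub.index.to_numpy()
        day = group[0] if isinstance(group, tuple) else group
        if day == reference_day and np.array_equal(np.sort(rows), np.sort(ref_rows)):
            block = cm.matrix[np.ix_(rows, rows)]
            values = block[np.triu_indices(rows.size, k=1)]
        else:
            block = cm.matrix[np.ix_(rows, ref_rows)]
            # drop self-pairs of reference spectra that fall in this group
            mask = rows[:, None] != ref_rows[None, :]
            values = block[mask]
        mean, sd, n = _pair_stats(values)
        rec = dict(zip(keys, group if isinstance(group, tuple) else (group,)))
        rec.update(mean=mean, sd=sd, n_pairs=n)
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    out.attrs["reference_day"] = reference_day
    return out


def median_spectrum(spectra: SpectraSet, day: int) -> Spectrum:
    """Pointwise median across the day's spectra (midpoint for even counts)."""
    rows = spectra.day_rows(day)
    if rows.size == 0:
        raise ValueError(f"day {day} has no spectra")
    return Spectrum(
        axis=spectra.axis,
        intensities=np.median(spectra.matrix[rows], axis=0),
        spectrum_id=f"median_d{day:02d}",
        day=int(day),
    )
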