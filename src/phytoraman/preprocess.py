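"""Spectral pre-processing chain.

The stages, applied in this order by :func:`preprocess`:

1. :func:`crop` — keep the fingerprint (350-1800 cm^-1) and C-H stretch
   (2800-3050 cm^-1) ranges;
2. :func:`concave_rubberband` — iterative concave (bent) rubberband baseline
   correction (default 64 degrees, 10 iterations), per contiguous segment;
3. :func:`savitzky_golay` — Savitzky-Golay smoothing, two passes of a
   25-point, order-2 filter by default;
4. :func:`snv` — standard normal variate normalisation per spectrum.

The concave rubberband generalises the classic lower-convex-hull rubberband:
each iteration adds a parabolic bending term scaled by ``tan(bend_angle)``
and the spectrum's intensity range, so broad *concave* fluorescence
backgrounds that a straight rubberband would miss become hull-touchable.
At ``bend_angle -> 0`` a single iteration reduces to the classic rubberband.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_coeffs

from .spectra import Spectrum, SpectraSet, segment_slices

__all__ = [
    "PreprocessParams",
    "crop",
    "concave_rubberband",
    "savitzky_golay",
    "snv",
    "preprocess",
]

logger = logging.getLogger(__name__)

DEFAULT_RANGES: tuple[tuple[float, float], ...] = ((350.0, 1800.0), (2800.0, 3050.0))


@dataclass
class PreprocessParams:
    """Parameters of the pre-processing chain with the standard defaults."""

    ranges: tuple[tuple[float, float], ...] = DEFAULT_RANGES
    bend_angle: float = 64.0        # degrees, 0 < angle < 90
    n_baseline_iter: int = 10
    sg_window: int = 25             # odd number of smoothing points
    sg_order: int = 2
    sg_passes: int = 2

    def __post_init__(self) -> None:
        self.ranges = tuple((float(lo), float(hi)) for lo, hi in self.ranges)
        if not self.ranges:
            raise ValueError("ranges must be non-empty")
        for lo, hi in self.ranges:
            if not lo < hi:
                raise ValueError(f"invalid range [{lo}, {hi}]: lo must be < hi")
        ordered = sorted(self.ranges)
        for (lo1, hi1), (lo2, hi2) in zip(ordered[:-1], ordered[1:]):
            if hi1 >= lo2:
                raise ValueError(f"overlapping ranges [{lo1},{hi1}] and [{lo2},{hi2}]")
        if not 0 < self.bend_angle < 90:
            raise ValueError("bend_angle must lie in (0, 90) degrees")
        if self.n_baseline_iter < 1:
            raise ValueError("n_baseline_iter must be >= 1")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if self.sg_passes < 1:
            raise ValueError("sg_passes must be >= 1")


# ---------------------------------------------------------------------------
# crop
# ---------------------------------------------------------------------------

def crop(obj: Spectrum | SpectraSet, ranges: Sequence[tuple[float, float]] = DEFAULT_RANGES):
    """Retain exactly the axis points inside any interval (inclusive endpoints).

    Disjoint retained segments stay concatenated in one vector; the axis
    records the gap, and downstream stages split on it.
    """
    axis = obj.axis
    mask = np.zeros(axis.size, dtype=bool)
    for lo, hi in ranges:
        mask |= (axis >= lo) & (axis <= hi)
    if not mask.any():
        raise ValueError(f"no axis points fall inside ranges {list(ranges)}")
    if isinstance(obj, Spectrum):
        return Spectrum(
            axis=axis[mask],
            intensities=obj.intensities[mask],
            spectrum_id=obj.spectrum_id,
            day=obj.day,
            session=obj.session,
            replicate=obj.replicate,
        )
    return obj.with_matrix(obj.matrix[:, mask], axis=axis[mask])


# ---------------------------------------------------------------------------
# concave rubberband baseline
# ---------------------------------------------------------------------------

def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Andrew's monotone-chain lower convex hull of points sorted by x."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k unless (j -> k -> i) turns strictly counter-clockwise
            if (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j]) <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def _concave_baseline_segment(
    x: np.ndarray, y: np.ndarray, bend_angle: float, n_iter: int
) -> np.ndarray:
    if x.size < 3:
        raise ValueError("segment needs at least 3 points for baseline estimation")
    half_span = (x[-1] - x[0]) / 2.0
    # convex bending term: 0 at the segment ends, -1 mid-segment.  Pulling the
    # interior down convexifies broad concave backgrounds so the lower hull
    # can follow them; at bend_angle -> 0 the classic rubberband is recovered.
    bend_shape = -(x - x[0]) * (x[-1] - x) / half_span**2
    tan_a = np.tan(np.deg2rad(bend_angle))
    work = y.astype(float).copy()
    baseline = np.zeros_like(work)
    for _ in range(n_iter):
        amp = work.max() - work.min()
        bent = work + tan_a * amp * bend_shape
        hull = _lower_hull_indices(x, bent)
        # the bend only selects the support points; the baseline interpolates
        # the un-bent working spectrum through them, so no bending artefact
        # enters the estimate
        estimate = np.interp(x, x[hull], work[hull])
        work -= estimate
        baseline += estimate
    return baseline


def concave_rubberband(
    s: Spectrum, bend_angle: float = 64.0, n_iter: int = 10
) -> tuple[Spectrum, Spectrum]:
    """Iterative concave rubberband baseline correction.

    Returns ``(corrected, baseline)`` with ``corrected + baseline``
    reconstructing the input.  The baseline is estimated independently on
    each contiguous axis segment.  ``bend_angle`` may be 0, giving the
    classic lower-convex-hull rubberband at ``n_iter = 1``.
    """
    if not 0 <= bend_angle < 90:
        raise ValueError("bend_angle must lie in [0, 90) degrees")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    baseline = np.empty_like(s.intensities)
    for seg in segment_slices(s.axis):
        baseline[seg] = _concave_baseline_segment(
            s.axis[seg], s.intensities[seg], bend_angle, n_iter
        )
    corrected = s.intensities - baseline
    # re-derive the baseline from the corrected signal so that
    # corrected + baseline round-trips to the input at machine level
    baseline = s.intensities - corrected
    return s.with_intensities(corrected), s.with_intensities(baseline)


# ---------------------------------------------------------------------------
# Savitzky-Golay smoothing
# ---------------------------------------------------------------------------

def _polyfit_value(y: np.ndarray, lo: int, hi: int, at: int, order: int) -> float:
    t = np.arange(lo, hi, dtype=float) - at
    deg = min(order, hi - lo - 1)
    coeffs = np.polynomial.polynomial.polyfit(t, y[lo:hi], deg)
    return float(coeffs[0])


def _sg_segment(y: np.ndarray, window: int, order: int) -> np.ndarray:
    n = y.size
    half = window // 2
    kernel = savgol_coeffs(window, order)  # symmetric for smoothing
    out = np.convolve(y, kernel, mode="same")
    # edge points: least-squares fit on the truncated one-sided window
    for i in range(min(half, n)):
        out[i] = _polyfit_value(y, 0, min(n, i + half + 1), i, order)
    for i in range(max(n - half, 0), n):
        out[i] = _polyfit_value(y, max(0, i - half), n, i, order)
    return out


def savitzky_golay(
    s: Spectrum, window: int = 25, order: int = 2, passes: int = 2
) -> Spectrum:
    """Savitzky-Golay smoothing, applied per contiguous segment.

    Interior points take the value of an order-``order`` least-squares
    polynomial fitted over the centred ``window``; edge points fit the same
    polynomial on the truncated one-sided window.  ``passes`` sequential
    applications of the same filter.
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than order")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    segs = segment_slices(s.axis)
    for seg in segs:
        if (seg.stop - seg.start) < window:
            raise ValueError(
                f"segment {s.axis[seg.start]:.0f}-{s.axis[seg.stop - 1]:.0f} cm^-1 "
                f"has {seg.stop - seg.start} points, shorter than window {window}"
            )
    out = s.intensities.astype(float).copy()
    for _ in range(passes):
        for seg in segs:
            out[seg] = _sg_segment(out[seg], window, order)
    return s.with_intensities(out)


# ---------------------------------------------------------------------------
# SNV
# ---------------------------------------------------------------------------

def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: centre and scale to unit sample variance.

    Statistics are computed jointly over all retained points (one mean and
    one standard deviation per spectrum, n-1 denominator), so the fingerprint
    and C-H regions stay on a common scale.
    """
    if s.n_points < 2:
        raise ValueError("SNV needs at least 2 points")
    mean = float(np.mean(s.intensities))
    sd = float(np.std(s.intensities, ddof=1))
    if sd == 0.0:
        raise ValueError(
            f"spectrum {s.spectrum_id!r} is constant; SNV is undefined"
        )
    return s.with_intensities((s.intensities - mean) / sd)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def preprocess(spectra: SpectraSet, params: PreprocessParams | None = None) -> SpectraSet:
    """Apply crop -> concave rubberband -> Savitzky-Golay -> SNV to every spectrum.

    Metadata are preserved; stage errors are re-raised naming the offending
    spectrum.  A per-stage summary is logged at INFO level.
    """
    params = params or PreprocessParams()
    cropped = crop(spectra, params.ranges)
    logger.info(
        "crop: retained %d of %d points in ranges %s",
        cropped.n_points, spectra.n_points, list(params.ranges),
    )
    out = np.empty_like(cropped.matrix)
    baseline_fraction = 0.0
    for i in range(cropped.n_spectra):
        s = cropped.spectrum(i)
        try:
            corrected, baseline = concave_rubberband(
                s, params.bend_angle, params.n_baseline_iter
            )
            smoothed = savitzky_golay(
                corrected, params.sg_window, params.sg_order, params.sg_passes
            )
            out[i] = snv(smoothed).intensities
        except ValueError as err:
            raise ValueError(f"spectrum {s.spectrum_id!r}: {err}") from err
        total = float(np.abs(s.intensities).sum())
        if total > 0:
            baseline_fraction += float(np.abs(baseline.intensities).sum()) / total
    logger.info(
        "baseline: mean fraction of signal removed %.3f; smoothing %dx SG(%d,%d); SNV applied",
        baseline_fraction / max(cropped.n_spectra, 1),
        params.sg_passes, params.sg_window, params.sg_order,
    )
    return cropped.with_matrix(out)
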