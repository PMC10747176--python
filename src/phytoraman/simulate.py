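"""Seeded generator of Raman spectra time series for microalgal cultures.

Emulates the statistical structure of *Parachlorella kessleri* culture
spectra under progressive nitrogen starvation: Gaussian or Lorentzian
vibrational bands at the assigned wavenumbers, a broad chlorophyll-
fluorescence background (quadratic dome plus a decaying exponential),
additive white noise and multiplicative per-spectrum scale jitter.

Band amplitudes follow piecewise-linear day trajectories with a single
breakpoint at the nitrogen-depletion day: pigment bands (chlorophyll,
carotenoids) rise until depletion then decline, while storage-lipid and
unsaturation bands (1660, 1750, 2940, 3008 cm^-1) stay flat then rise.

Two acquisition scenarios are built in:

``lab``
    one session per day, 50 spectra per session, 36 days (1800 spectra).
``pilot``
    four sessions per day six hours apart, 50 spectra per session,
    14 days (2800 spectra).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectraSet

__all__ = [
    "BandKinetic",
    "SimulationConfig",
    "default_config",
    "simulate",
    "evaluate_model",
    "model_baseline",
    "rise_fall",
    "default_bands",
    "flat_rise",
    "linear",
    "step",
    "step_bands",
    "SCENARIOS",
]

AXIS_MIN_DEFAULT = 300.0
AXIS_MAX_DEFAULT = 3100.0
SCENARIOS = ("lab", "pilot")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BandKinetic:
    """One vibrational band and its per-day amplitude trajectory.

    Parameters
    ----------
    center : float
        Band center in cm^-1, inside [300, 3100].
    width : float
        Full width at half maximum in cm^-1.
    amplitude_by_day : array-like
        Non-negative band amplitude for each simulated culture day.
    shape : {"gaussian", "lorentzian"}
        Peak profile; amplitude is the peak height in both cases.
    label : str
        Optional band name carried through to reports.
    """

    center: float
    width: float
    amplitude_by_day: np.ndarray
    shape: str = "gaussian"
    label: str = ""

    def __post_init__(self) -> None:
        self.amplitude_by_day = np.asarray(self.amplitude_by_day, dtype=float)
        if not (AXIS_MIN_DEFAULT <= self.center <= AXIS_MAX_DEFAULT):
            raise ValueError(f"band center {self.center} outside [300, 3100] cm^-1")
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude_by_day.ndim != 1:
            raise ValueError("amplitude_by_day must be one-dimensional")
        if np.any(self.amplitude_by_day < 0):
            raise ValueError(f"band {self.label or self.center}: negative amplitude")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, axis: np.ndarray, amplitude: float) -> np.ndarray:
        """Peak profile with the given height on ``axis``."""
        x = np.asarray(axis, dtype=float) - self.center
        if self.shape == "gaussian":
            sigma = self.width * _FWHM_TO_SIGMA
            return amplitude * np.exp(-0.5 * (x / sigma) ** 2)
        hwhm = self.width / 2.0
        return amplitude * hwhm**2 / (x**2 + hwhm**2)


@dataclass
class SimulationConfig:
    """Full generative description of one synthetic culture run."""

    days: int
    sessions_per_day: int
    spectra_per_session: int
    bands: list[BandKinetic]
    axis_min: float = AXIS_MIN_DEFAULT
    axis_max: float = AXIS_MAX_DEFAULT
    axis_step: float = 2.0
    #: polynomial coefficients (ascending) of the fluorescence background,
    #: evaluated on the normalised coordinate u = (x - axis_min)/(axis_max - axis_min)
    baseline_coeffs: tuple[float, ...] = (2.0, 3.0, -2.5)
    #: decay constant (per cm^-1) of the optional exponential background term
    baseline_decay: float | None = 0.002
    #: peak height of the exponential background term at axis_min
    baseline_exp_amplitude: float = 4.0
    noise_sd: float = 0.02
    replicate_jitter_sd: float = 0.05
    nitrogen_depletion_day: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.bands = list(self.bands)
        self.validate()

    def validate(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.sessions_per_day < 1:
            raise ValueError("sessions_per_day must be >= 1")
        if self.spectra_per_session < 1:
            raise ValueError("spectra_per_session must be >= 1")
        if not self.axis_min < self.axis_max:
            raise ValueError("axis_min must be < axis_max")
        if self.axis_step <= 0:
            raise ValueError("axis_step must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicate_jitter_sd < 0:
            raise ValueError("replicate_jitter_sd must be >= 0")
        if not 0 <= self.nitrogen_depletion_day <= self.days:
            raise ValueError("nitrogen_depletion_day must lie in [0, days]")
        for b in self.bands:
            if b.amplitude_by_day.size != self.days:
                raise ValueError(
                    f"band {b.label or b.center}: amplitude_by_day has "
                    f"{b.amplitude_by_day.size} entries for {self.days} days"
                )

    @property
    def axis(self) -> np.ndarray:
        n = int(round((self.axis_max - self.axis_min) / self.axis_step)) + 1
        return self.axis_min + self.axis_step * np.arange(n)

    @property
    def n_spectra(self) -> int:
        return self.days * self.sessions_per_day * self.spectra_per_session


# ---------------------------------------------------------------------------
# amplitude trajectories
# ---------------------------------------------------------------------------

def rise_fall(days: int, break_day: int, start: float, peak: float, end: float) -> np.ndarray:
    """Piecewise-linear trajectory rising to ``peak`` at ``break_day`` then falling.

    Models pigments that accumulate during growth and degrade after nitrogen
    depletion.  Degenerate breakpoints (0 or the last day) reduce to a single
    linear ramp.
    """
    d = np.arange(days, dtype=float)
    if days == 1:
        return np.array([float(peak)])
    bp = min(max(break_day, 0), days - 1)
    traj = np.empty(days)
    if bp == 0:
        return np.linspace(peak, end, days)
    traj[: bp + 1] = start + (peak - start) * d[: bp + 1] / bp
    if bp < days - 1:
        traj[bp:] = peak + (end - peak) * (d[bp:] - bp) / (days - 1 - bp)
    return traj


def flat_rise(days: int, break_day: int, base: float, end: float) -> np.ndarray:
    """Flat at ``base`` until ``break_day`` then linear to ``end``.

    Models storage lipids that only accumulate once nitrogen runs out.
    """
    d = np.arange(days, dtype=float)
    if days == 1:
        return np.array([float(base)])
    bp = min(max(break_day, 0), days - 1)
    traj = np.full(days, float(base))
    if bp < days - 1:
        traj[bp:] = base + (end - base) * (d[bp:] - bp) / (days - 1 - bp)
    return traj


def linear(days: int, start: float, end: float) -> np.ndarray:
    if days == 1:
        return np.array([float(start)])
    return np.linspace(start, end, days)


def step(days: int, break_day: int, before: float, after: float) -> np.ndarray:
    """Constant at ``before`` up to ``break_day`` (exclusive), then ``after``.

    An idealised switch between two physiological states; useful when a clean
    two-cluster phase structure is wanted rather than the smooth default
    trajectories.
    """
    traj = np.full(days, float(before))
    traj[min(max(break_day, 0), days):] = after
    return traj


def step_bands(days: int, depletion: int) -> list[BandKinetic]:
    """Band set with step trajectories: two sharply separated phases.

    Pigment bands drop and storage-lipid bands jump at the depletion day,
    giving the idealised 'two main sets' score-space structure used for
    phase-discrimination checks; structural bands stay constant.
    """
    spec = [
        ("carbohydrate_479", 479.0, 18.0, step(days, depletion, 0.6, 0.6)),
        ("phospholipid_865", 865.0, 16.0, step(days, depletion, 0.5, 0.4)),
        ("chlorophyll_988", 988.0, 16.0, step(days, depletion, 1.6, 0.5)),
        ("carotenoid_1157", 1157.0, 16.0, step(days, depletion, 2.0, 0.6)),
        ("carotenoid_1524", 1524.0, 20.0, step(days, depletion, 2.5, 0.75)),
        ("lipid_1444", 1444.0, 24.0, step(days, depletion, 1.0, 1.2)),
        ("lipid_1660", 1660.0, 22.0, step(days, depletion, 0.35, 1.1)),
        ("lipid_1750", 1750.0, 18.0, step(days, depletion, 0.12, 0.55)),
        ("lipid_2850", 2850.0, 30.0, step(days, depletion, 1.0, 1.45)),
        ("lipid_2885", 2885.0, 28.0, step(days, depletion, 0.9, 0.9)),
        ("lipid_2940", 2940.0, 34.0, step(days, depletion, 1.2, 2.2)),
        ("lipid_2970", 2970.0, 26.0, step(days, depletion, 0.8, 0.8)),
        ("lipid_3008", 3008.0, 24.0, step(days, depletion, 0.12, 0.5)),
    ]
    return [
        BandKinetic(center=c, width=w, amplitude_by_day=a, label=lab)
        for lab, c, w, a in spec
    ]


def default_bands(days: int, depletion: int) -> list[BandKinetic]:
    """The built-in band set covering every assigned wavenumber.

    Pigment bands rise then fall around the depletion day; the carotenoid
    pair 1157/1524 keeps a fixed amplitude ratio (the carotenoid composition
    is assumed stable).  Storage-lipid and unsaturation bands are flat then
    rise after depletion; structural C-H bands are near-constant.
    """
    caro = rise_fall(days, depletion, 1.0, 3.0, 0.6)
    spec = [
        # label, center, width (FWHM), trajectory
        ("carbohydrate_479", 479.0, 18.0, linear(days, 0.55, 0.75)),
        ("phospholipid_865", 865.0, 16.0, rise_fall(days, depletion, 0.5, 0.55, 0.4)),
        ("chlorophyll_988", 988.0, 16.0, rise_fall(days, depletion, 0.6, 1.8, 0.4)),
        ("carotenoid_1157", 1157.0, 16.0, 0.8 * caro),
        ("carotenoid_1524", 1524.0, 20.0, caro),
        ("lipid_1444", 1444.0, 24.0, flat_rise(days, depletion, 1.0, 1.25)),
        ("lipid_1660", 1660.0, 22.0, flat_rise(days, depletion, 0.35, 1.2)),
        ("lipid_1750", 1750.0, 18.0, flat_rise(days, depletion, 0.12, 0.6)),
        ("lipid_2850", 2850.0, 30.0, flat_rise(days, depletion, 1.0, 1.5)),
        ("lipid_2885", 2885.0, 28.0, linear(days, 0.9, 0.95)),
        ("lipid_2940", 2940.0, 34.0, flat_rise(days, depletion, 1.2, 2.4)),
        ("lipid_2970", 2970.0, 26.0, linear(days, 0.8, 0.85)),
        ("lipid_3008", 3008.0, 24.0, flat_rise(days, depletion, 0.12, 0.55)),
    ]
    return [
        BandKinetic(center=c, width=w, amplitude_by_day=a, label=lab)
        for lab, c, w, a in spec
    ]


def default_config(scenario: str, seed: int = 0) -> SimulationConfig:
    """Default study conditions for the two acquisition scenarios.

    ``lab``: 36 days x 1 session x 50 spectra, nitrogen depleted on day 6.
    ``pilot``: 14 days x 4 sessions x 50 spectra, nitrogen depleted on day 8.
    """
    if scenario == "lab":
        days, sessions, reps, depletion = 36, 1, 50, 6
    elif scenario == "pilot":
        days, sessions, reps, depletion = 14, 4, 50, 8
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid scenarios are {SCENARIOS}"
        )
    return SimulationConfig(
        days=days,
        sessions_per_day=sessions,
        spectra_per_session=reps,
        bands=default_bands(days, depletion),
        nitrogen_depletion_day=depletion,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# forward model and sampling
# ---------------------------------------------------------------------------

def model_baseline(config: SimulationConfig, axis: np.ndarray | None = None) -> np.ndarray:
    """Noise-free fluorescence background on ``axis`` (default: config axis)."""
    x = config.axis if axis is None else np.asarray(axis, dtype=float)
    u = (x - config.axis_min) / (config.axis_max - config.axis_min)
    base = np.polynomial.polynomial.polyval(u, config.baseline_coeffs)
    if config.baseline_decay is not None:
        base = base + config.baseline_exp_amplitude * np.exp(
            -config.baseline_decay * (x - config.axis_min)
        )
    return base


def _band_sum(config: SimulationConfig, axis: np.ndarray, day: int) -> np.ndarray:
    total = np.zeros_like(axis)
    for b in config.bands:
        total += b.profile(axis, b.amplitude_by_day[day])
    return total


def evaluate_model(config: SimulationConfig, day: int) -> Spectrum:
    """Noiseless, jitter-free model spectrum (bands + background) for ``day``.

    ``simulate`` with ``noise_sd = replicate_jitter_sd = 0`` reproduces this
    exactly, making it the ground truth for baseline- and kinetics-recovery
    tests.
    """
    if not 0 <= day < config.days:
        raise ValueError(f"day {day} out of range [0, {config.days})")
    axis = config.axis
    intensities = _band_sum(config, axis, day) + model_baseline(config, axis)
    return Spectrum(
        axis=axis,
        intensities=intensities,
        spectrum_id=f"model_d{day:02d}",
        day=day,
    )


def simulate(config: SimulationConfig) -> SpectraSet:
    """Sample a full synthetic culture run.

    Each spectrum is ``band_sum(day) * (1 + jitter) + background + noise``
    with ``jitter ~ N(0, replicate_jitter_sd)`` per spectrum and white
    Gaussian noise per point.  Identical configs and seeds yield bit-identical
    output.
    """
    config.validate()
    axis = config.axis
    rng = np.random.default_rng(config.seed)
    baseline = model_baseline(config, axis)
    band_by_day = [_band_sum(config, axis, d) for d in range(config.days)]

    rows: list[np.ndarray] = []
    ids: list[str] = []
    days_col: list[int] = []
    sessions_col: list[int] = []
    reps_col: list[int] = []
    n_rep = config.spectra_per_session
    for day in range(config.days):
        for session in range(config.sessions_per_day):
            jitter = rng.normal(0.0, config.replicate_jitter_sd, size=n_rep)
            noise = rng.normal(0.0, config.noise_sd, size=(n_rep, axis.size))
            block = band_by_day[day][None, :] * (1.0 + jitter[:, None]) + baseline + noise
            rows.append(block)
            for rep in range(n_rep):
                ids.append(f"d{day:02d}_s{session}_r{rep:02d}")
                days_col.append(day)
                sessions_col.append(session)
                reps_col.append(rep)
    meta = pd.DataFrame(
        {
            "spectrum_id": ids,
            "day": days_col,
            "session": sessions_col,
            "replicate": reps_col,
        }
    )
    return SpectraSet(axis=axis, matrix=np.vstack(rows), meta=meta)
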