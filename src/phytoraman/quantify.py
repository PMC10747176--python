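"""Reference wet-lab arithmetic: pigments, total lipids, optical density.

Pigment concentrations follow the standard methanol-extract
spectrophotometric formulas, after subtracting the 750 nm turbidity
absorbance from every analytical channel:

    chl_a       = (V_extract / V_biomass) * (-8.0962 A652 + 16.5169 A665)
    chl_b       = (V_extract / V_biomass) * (27.4405 A652 - 12.1688 A665)
    carotenoids = (V_extract / V_biomass) * 4 * A480

in ug/mL, with V_extract the methanol volume (default 1.5 mL) and V_biomass
the centrifuged culture volume in mL.  Total lipid concentration is extract
mass (mg) over sample volume (L).  Optical densities measured on diluted
culture are multiplied back by the dilution factor; readings at or above 0.8
are outside the linear range and flagged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "AbsorbancePanel",
    "PigmentPanel",
    "LipidMeasurement",
    "CorrectedOD",
    "pigment_concentrations",
    "total_lipid_concentration",
    "corrected_od",
]

CHL_A_COEFFS = (-8.0962, 16.5169)   # (A652, A665)
CHL_B_COEFFS = (27.4405, -12.1688)  # (A652, A665)
CAROTENOID_COEFF = 4.0              # A480
OD_LINEAR_LIMIT = 0.8


@dataclass(frozen=True)
class AbsorbancePanel:
    """Raw absorbances of one methanol extract plus the sampled culture volume."""

    A480: float
    A652: float
    A665: float
    A750: float = 0.0
    V_biomass: float = 1.5   # mL of culture centrifuged
    extract_volume: float = 1.5  # mL of methanol

    def __post_init__(self) -> None:
        if self.V_biomass <= 0:
            raise ValueError("V_biomass must be positive")
        if self.extract_volume <= 0:
            raise ValueError("extract_volume must be positive")


class PigmentPanel(NamedTuple):
    """Pigment concentrations in ug/mL."""

    chl_a: float
    chl_b: float
    carotenoids: float


@dataclass(frozen=True)
class LipidMeasurement:
    extract_mass: float   # mg
    sample_volume: float  # L

    def __post_init__(self) -> None:
        if self.extract_mass <= 0:
            raise ValueError("extract_mass must be positive")
        if self.sample_volume <= 0:
            raise ValueError("sample_volume must be positive")


class CorrectedOD(NamedTuple):
    value: float
    out_of_range: bool


def pigment_concentrations(panel: AbsorbancePanel) -> PigmentPanel:
    """Chlorophyll a/b and total carotenoid concentrations (ug/mL).

    Turbidity (A750) is subtracted from A480, A652 and A665 before applying
    the formulas.  Negative outputs (absorbance ratios outside the formulas'
    domain) are returned with a warning rather than rejected.
    """
    a480 = panel.A480 - panel.A750
    a652 = panel.A652 - panel.A750
    a665 = panel.A665 - panel.A750
    scale = panel.extract_volume / panel.V_biomass
    chl_a = scale * (CHL_A_COEFFS[0] * a652 + CHL_A_COEFFS[1] * a665)
    chl_b = scale * (CHL_B_COEFFS[0] * a652 + CHL_B_COEFFS[1] * a665)
    caro = scale * CAROTENOID_COEFF * a480
    result = PigmentPanel(chl_a=chl_a, chl_b=chl_b, carotenoids=caro)
    if min(result) < 0:
        warnings.warn(
            f"negative pigment concentration {result}; absorbance ratios are "
            "outside the formulas' domain",
            stacklevel=2,
        )
    return result


def total_lipid_concentration(m: LipidMeasurement) -> float:
    """Total lipid concentration in mg/L: extract mass over sample volume."""
    return m.extract_mass / m.sample_volume


def corrected_od(od_measured: float, dilution_factor: float = 1.0) -> CorrectedOD:
    """Dilution-corrected optical density.

    The spectrophotometer is linear below OD 0.8; a measured value at or
    above that threshold is returned with ``out_of_range=True`` rather than
    rejected.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    return CorrectedOD(
        value=od_measured * dilution_factor,
        out_of_range=od_measured >= OD_LINEAR_LIMIT,
    )
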