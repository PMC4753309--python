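"""Oxalate-extraction geochemistry and channel hydrodynamics.

Slides are extracted in acid ammonium oxalate (dissolving the
poorly-crystalline Fe(III)-oxides) and the extract analysed by ICP-OES.
Element concentrations (mg/L) convert to areal loadings (umol/cm^2)
through the extraction volume and slide area; oxyanion:Fe molar ratios
(As:Fe, P:Fe, W:Fe) are volume- and area-independent and track the
coupled biomineralization of Fe(III) and adsorbed oxyanions.  A
Reynolds number helper provides the hydrodynamic context of the
outflow channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import molar_mass

__all__ = [
    "ExtractionRecord",
    "RatioSeries",
    "HydrodynamicState",
    "areal_loading",
    "molar_ratio",
    "ratio_series",
    "reynolds_number",
]


@dataclass
class ExtractionRecord:
    """One slide's ICP element concentrations plus extraction geometry."""

    t: float                            # days of incubation
    concentrations: dict[str, float]    # element -> mg/L in the extract
    extraction_volume: float = 0.05     # L
    slide_area: float = 18.75           # cm^2 scraped
    site: str = ""

    def __post_init__(self) -> None:
        if self.extraction_volume <= 0:
            raise ValueError("extraction volume must be positive")
        if self.slide_area <= 0:
            raise ValueError("slide area must be positive")
        for el, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {el}")


@dataclass
class RatioSeries:
    """Molar-ratio time series for one element pair."""

    t: np.ndarray
    ratio: np.ndarray
    pair: tuple[str, str]

    def mean_se(self) -> tuple[float, float]:
        """Mean ratio and its standard error over time points."""
        r = self.ratio[~np.isnan(self.ratio)]
        if r.size == 0:
            return np.nan, np.nan
        se = float(np.std(r, ddof=1) / np.sqrt(r.size)) if r.size > 1 else 0.0
        return float(np.mean(r)), se


@dataclass
class HydrodynamicState:
    """Channel flow characterisation."""

    velocity: float                 # cm/s
    characteristic_length: float    # cm
    kinematic_viscosity: float      # cm^2/s
    reynolds: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.velocity, self.characteristic_length, self.kinematic_viscosity) <= 0:
            raise ValueError("all hydrodynamic quantities must be positive")
        self.reynolds = reynolds_number(
            self.velocity, self.characteristic_length, self.kinematic_viscosity
        )


def areal_loading(
    record: ExtractionRecord, element: str, molar_mass_g_mol: float | None = None
) -> float:
    """Areal loading of an element in umol/cm^2.

    mg/L x L = mg; mg / (g/mol) = mmol; x1000 = umol; / slide area.
    """
    mw = molar_mass_g_mol if molar_mass_g_mol is not None else molar_mass(element)
    conc = record.concentrations.get(element, 0.0)
    umol = conc * record.extraction_volume / mw * 1000.0
    return umol / record.slide_area


def molar_ratio(
    record: ExtractionRecord, numerator: str, denominator: str,
    molar_masses: dict | None = None,
) -> float | None:
    """Molar ratio of two extracted elements; ``None`` if denominator is 0.

    Extraction volume and slide area cancel, so the ratio only depends
    on concentrations and molar masses.
    """
    mw_num = molar_mass(numerator, molar_masses)
    mw_den = molar_mass(denominator, molar_masses)
    num = record.concentrations.get(numerator, 0.0) / mw_num
    den = record.concentrations.get(denominator, 0.0) / mw_den
    if den == 0:
        return None
    return num / den


def ratio_series(
    records: list[ExtractionRecord], numerator: str, denominator: str,
    molar_masses: dict | None = None,
) -> RatioSeries:
    """Per-timepoint molar ratios across a slide series."""
    t = np.array([r.t for r in records], dtype=float)
    ratios = np.array(
        [np.nan if (v := molar_ratio(r, numerator, denominator, molar_masses)) is None
         else v
         for r in records],
        dtype=float,
    )
    return RatioSeries(t=t, ratio=ratios, pair=(numerator, denominator))


def reynolds_number(
    velocity: float, characteristic_length: float, kinematic_viscosity: float
) -> float:
    """Re = v * L / nu (dimensionless)."""
    if kinematic_viscosity <= 0:
        raise ValueError("kinematic viscosity must be positive")
    return velocity * characteristic_length / kinematic_viscosity
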