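"""Carbon and electron balancing of steady-state gas fermentations.

Converts specific rates (mmol/gDCW/h) and broth concentrations into carbon
recoveries, normalized carbon distributions, electron (degree-of-reduction)
recoveries, and the headline ratios used to compare feed gases
(qCO2/qCO, qH2/qCO, molar acetate/ethanol).

Degree-of-reduction convention: reference states CO2, H2O and NH3, so
gamma = 4*c + h - 2*o - 3*n electrons per mole. CO2 carries zero available
electrons; CO and H2 each carry two; biomass CH1.8O0.5N0.2 carries 4.2 per
C-mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

from .config import (
    MW_ACETATE,
    MW_BDO,
    MW_ETHANOL,
    AnalysisConfig,
    DEFAULT_CONFIG,
)

__all__ = [
    "ChemicalSpecies",
    "SPECIES",
    "SpecificRates",
    "CarbonDistribution",
    "BrothSample",
    "biomass_from_od",
    "degree_of_reduction",
    "carbon_recovery",
    "normalize_distribution",
    "electron_recovery",
    "ratios",
]


@dataclass(frozen=True)
class ChemicalSpecies:
    """A compound with elemental composition used in balancing."""

    name: str
    c: float
    h: float
    o: float
    n: float = 0.0
    molar_mass: float = 0.0

    @property
    def gamma(self) -> float:
        """Degree of reduction, electrons per mole (CO2/H2O/NH3 reference)."""
        return 4.0 * self.c + self.h - 2.0 * self.o - 3.0 * self.n


def degree_of_reduction(species: ChemicalSpecies) -> float:
    """Electrons available per mole of ``species``."""
    return species.gamma


#: The species tracked by the pipeline. Acetate is balanced as the free acid
#: C2H4O2 (it is essentially fully dissociated in broth at pH 5, but proton
#: bookkeeping cancels in the degree-of-reduction balance).
SPECIES: Mapping[str, ChemicalSpecies] = {
    "co": ChemicalSpecies("co", 1, 0, 1, molar_mass=28.01),
    "co2": ChemicalSpecies("co2", 1, 0, 2, molar_mass=44.01),
    "h2": ChemicalSpecies("h2", 0, 2, 0, molar_mass=2.016),
    "ethanol": ChemicalSpecies("ethanol", 2, 6, 1, molar_mass=MW_ETHANOL),
    "acetate": ChemicalSpecies("acetate", 2, 4, 2, molar_mass=MW_ACETATE),
    "bdo": ChemicalSpecies("bdo", 4, 10, 2, molar_mass=MW_BDO),
}


@dataclass(frozen=True)
class SpecificRates:
    """Specific uptake/production rates of a steady-state culture.

    Uptake rates (q_co, q_h2) are positive for consumption; a negative q_h2
    means net H2 production (observed as "sub-zero" uptake on pure CO feeds
    and reported as-is, never clipped). Production rates (q_co2, q_etoh,
    q_acetate, q_bdo) are positive for secretion. All in mmol/gDCW/h;
    ``mu`` is the specific growth rate in 1/h.
    """

    q_co: float
    q_h2: float
    q_co2: float
    q_etoh: float
    q_acetate: float
    q_bdo: float
    mu: float
    std: Mapping[str, float] | None = field(default=None, compare=False)

    def scaled(self, factor: float) -> "SpecificRates":
        """All rates (including mu) multiplied by ``factor``."""
        return SpecificRates(
            q_co=self.q_co * factor,
            q_h2=self.q_h2 * factor,
            q_co2=self.q_co2 * factor,
            q_etoh=self.q_etoh * factor,
            q_acetate=self.q_acetate * factor,
            q_bdo=self.q_bdo * factor,
            mu=self.mu * factor,
        )


@dataclass(frozen=True)
class CarbonDistribution:
    """Percent of consumed carbon directed to each product pool.

    ``recovery`` is the raw carbon recovery in percent (products + biomass
    over CO consumed). For a raw distribution the fractions sum to
    ``recovery``; after :func:`normalize_distribution` they sum to 100.
    """

    co2: float
    ethanol: float
    acetate: float
    bdo: float
    biomass: float
    recovery: float

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "co2": self.co2,
            "ethanol": self.ethanol,
            "acetate": self.acetate,
            "bdo": self.bdo,
            "biomass": self.biomass,
        }

    def total(self) -> float:
        return sum(self.fractions.values())


@dataclass(frozen=True)
class BrothSample:
    """Steady-state broth composition (HPLC + OD observables)."""

    acetate_g_l: float
    ethanol_g_l: float
    bdo_g_l: float
    od600: float

    def __post_init__(self) -> None:
        for name in ("acetate_g_l", "ethanol_g_l", "bdo_g_l", "od600"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def biomass_from_od(od600: float, factor: float | None = None) -> float:
    """Dry cell weight (gDCW/L) from OD600 via the linear correlation.

    The default factor 0.21 gDCW/L per OD unit is the calibration for
    syngas-grown C. autoethanogenum.
    """
    if od600 < 0:
        raise ValueError("od600 must be non-negative")
    if factor is None:
        factor = DEFAULT_CONFIG.od_to_dcw
    return factor * od600


def carbon_recovery(
    rates: SpecificRates,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> CarbonDistribution:
    """Raw carbon distribution: C-mol flux to each pool as % of CO consumed.

    The biomass term is mu * C_X with C_X the biomass carbon content
    (mmol C per gDCW) from ``config.biomass``. Rates are already per gDCW,
    so the result is independent of the absolute biomass concentration.
    """
    if rates.q_co <= 0:
        raise ValueError("carbon recovery requires net CO uptake (q_co > 0)")
    c_in = rates.q_co  # 1 C per CO
    c_x = config.biomass.carbon_content
    frac = lambda x: 100.0 * x / c_in  # noqa: E731
    dist = CarbonDistribution(
        co2=frac(rates.q_co2),
        ethanol=frac(2.0 * rates.q_etoh),
        acetate=frac(2.0 * rates.q_acetate),
        bdo=frac(4.0 * rates.q_bdo),
        biomass=frac(rates.mu * c_x),
        recovery=0.0,
    )
    return replace(dist, recovery=dist.total())


def normalize_distribution(raw: CarbonDistribution) -> CarbonDistribution:
    """Scale fractions by 100/recovery so they sum to exactly 100."""
    if raw.recovery <= 0:
        raise ValueError("cannot normalize a distribution with zero recovery")
    s = 100.0 / raw.recovery
    return CarbonDistribution(
        co2=raw.co2 * s,
        ethanol=raw.ethanol * s,
        acetate=raw.acetate * s,
        bdo=raw.bdo * s,
        biomass=raw.biomass * s,
        recovery=100.0,
    )


def electron_recovery(
    rates: SpecificRates,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """Degree-of-reduction recovery, percent.

    Electrons out (ethanol, acetate, 2,3-BDO, biomass; CO2 carries none)
    over electrons in (CO and H2, 2 e- each). A negative q_h2 (net H2
    production) moves that term to the product side automatically through
    the signed sum.
    """
    e_in = SPECIES["co"].gamma * rates.q_co + SPECIES["h2"].gamma * rates.q_h2
    if e_in <= 0:
        raise ValueError("electron recovery requires net electron input")
    bio = config.biomass
    e_out = (
        SPECIES["ethanol"].gamma * rates.q_etoh
        + SPECIES["acetate"].gamma * rates.q_acetate
        + SPECIES["bdo"].gamma * rates.q_bdo
        + bio.degree_of_reduction * rates.mu * bio.carbon_content
    )
    if e_out == 0:
        warnings.warn(
            "no electron-carrying products: all consumed electrons are "
            "unaccounted for (missing H2 or product measurement?)",
            stacklevel=2,
        )
        return 0.0
    return 100.0 * e_out / e_in


def ratios(
    rates: SpecificRates,
    broth: BrothSample | None = None,
) -> dict[str, float]:
    """Headline comparison ratios.

    Returns qCO2/qCO and qH2/qCO always; if a broth sample with non-zero
    ethanol is given, also the molar acetate/ethanol ratio computed from the
    g/L concentrations via molar masses 60.05 and 46.07.
    """
    if rates.q_co <= 0:
        raise ValueError("ratios require net CO uptake (q_co > 0)")
    out = {
        "qco2_over_qco": rates.q_co2 / rates.q_co,
        "qh2_over_qco": rates.q_h2 / rates.q_co,
    }
    if broth is not None:
        if broth.ethanol_g_l <= 0:
            raise ValueError("molar acetate/ethanol ratio needs ethanol > 0")
        out["acetate_ethanol_molar"] = (broth.acetate_g_l / MW_ACETATE) / (
            broth.ethanol_g_l / MW_ETHANOL
        )
    return out
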