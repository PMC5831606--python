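"""Shared physical constants and analysis configuration.

Every constant that enters the gas-to-rate arithmetic is surfaced here so a
balance can be audited end to end: the ideal-gas molar volume used to convert
volumetric gas flows to molar flows, the Henry constant and first carbonate
dissociation pKa used for the dissolved-CO2 correction, the OD600-to-dry-cell
-weight factor, and the elemental composition assumed for biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Ideal-gas molar volume at 25 degC / 1 atm, mL/mmol (== L/mol).
MOLAR_VOLUME_25C = 24.465

#: Henry solubility of CO2 in water at 37 degC, mol/(L*atm).
HENRY_KH_CO2_37C = 0.0215

#: First dissociation pKa of carbonic acid (CO2(aq)/HCO3-).
PKA1_CO2 = 6.35

#: OD600 -> gDCW/L linear correlation factor for C. autoethanogenum.
OD_TO_DCW = 0.21

# Molar masses, g/mol
MW_ETHANOL = 46.07
MW_ACETATE = 60.05
MW_BDO = 90.12  # 2,3-butanediol, C4H10O2


@dataclass(frozen=True)
class BiomassComposition:
    """Per-C-mol elemental biomass formula CHhOoNn (c == 1)."""

    h: float = 1.8
    o: float = 0.5
    n: float = 0.2

    @property
    def molar_mass(self) -> float:
        """g per C-mol of ash-free biomass."""
        return 12.011 + 1.008 * self.h + 15.999 * self.o + 14.007 * self.n

    @property
    def carbon_content(self) -> float:
        """mmol carbon per gDCW."""
        return 1000.0 / self.molar_mass

    @property
    def degree_of_reduction(self) -> float:
        """Available electrons per C-mol (CO2/H2O/NH3 reference)."""
        return 4.0 + self.h - 2.0 * self.o - 3.0 * self.n


@dataclass(frozen=True)
class AnalysisConfig:
    """Conventions applied when turning raw observables into specific rates.

    Attributes
    ----------
    molar_volume:
        mL gas per mmol at the off-gas analyser conditions (default 25 degC,
        1 atm -> 24.465).
    henry_kh:
        CO2 Henry solubility, mol/(L*atm), at culture temperature.
    pka1:
        First carbonate pKa used for the bicarbonate share of dissolved CO2.
    include_bicarbonate:
        If False only the Henry (physically dissolved) term is exported with
        the broth; if True the HCO3- pool at culture pH is added.
    pressure_atm:
        Headspace total pressure.
    od_to_dcw:
        OD600 -> gDCW/L factor.
    biomass:
        Elemental biomass composition (carbon content, electrons per C-mol).
    """

    molar_volume: float = MOLAR_VOLUME_25C
    henry_kh: float = HENRY_KH_CO2_37C
    pka1: float = PKA1_CO2
    include_bicarbonate: bool = True
    pressure_atm: float = 1.0
    od_to_dcw: float = OD_TO_DCW
    biomass: BiomassComposition = field(default_factory=BiomassComposition)


DEFAULT_CONFIG = AnalysisConfig()
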