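"""Specific gas rates from chemostat feed and off-gas compositions.

The off-gas molar flow is inferred from the inert tracer (Ar or N2/Ar): the
tracer is neither consumed nor produced, so F_out = F_in * y_inert_in /
y_inert_out. Specific rates then follow from the molar flow difference of
each species, the liquid working volume, the ideal-gas molar volume and the
steady-state biomass concentration:

    q = (F_in*y_in - F_out*y_out) * 60 / (Vm * V_L * X)   [mmol/gDCW/h]

with F in mL/min, Vm in mL/mmol, V_L in L and X in gDCW/L. Two corrections
are applied when assembling totals from a time series: ethanol stripped into
the off-gas is added to the liquid-phase ethanol production, and CO2 leaving
dissolved in the broth (Henry solubility plus, optionally, bicarbonate at
culture pH) is added to the gaseous CO2 production.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal

import numpy as np
import pandas as pd

from .balances import BrothSample, SpecificRates, biomass_from_od
from .config import MW_ACETATE, MW_BDO, MW_ETHANOL, AnalysisConfig, DEFAULT_CONFIG

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import SyntheticDataset

__all__ = [
    "GasComposition",
    "OffGasSeries",
    "ChemostatCondition",
    "offgas_flow",
    "specific_rate",
    "ethanol_stripping_rate",
    "dissolved_co2_rate",
    "rates_from_series",
]

OFFGAS_COLUMNS = ["time_h", "y_co", "y_h2", "y_co2", "y_inert", "y_etoh"]
BROTH_COLUMNS = ["time_h", "acetate_g_l", "ethanol_g_l", "bdo_g_l", "od600"]


@dataclass(frozen=True)
class GasComposition:
    """Mole fractions of one gas stream."""

    y_co: float = 0.0
    y_h2: float = 0.0
    y_co2: float = 0.0
    y_inert: float = 0.0
    y_etoh: float = 0.0

    def __post_init__(self) -> None:
        for name, y in self.as_dict().items():
            if y < 0 or y > 1:
                raise ValueError(f"mole fraction {name}={y} outside [0, 1]")
        if self.total() > 1 + 1e-6:
            raise ValueError(f"mole fractions sum to {self.total()} > 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "y_co": self.y_co,
            "y_h2": self.y_h2,
            "y_co2": self.y_co2,
            "y_inert": self.y_inert,
            "y_etoh": self.y_etoh,
        }

    def total(self) -> float:
        return sum(self.as_dict().values())


class OffGasSeries:
    """Time series of off-gas compositions backed by a DataFrame.

    Columns: time_h, y_co, y_h2, y_co2, y_inert, y_etoh. Times must be
    strictly increasing and at least one row is required.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in OFFGAS_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"off-gas table missing columns {missing}")
        if len(frame) == 0:
            raise ValueError("off-gas series is empty")
        t = frame["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("off-gas timestamps must be strictly increasing")
        self.frame = frame.loc[:, OFFGAS_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_h"].to_numpy()

    def composition(self, i: int) -> GasComposition:
        row = self.frame.iloc[i]
        return GasComposition(
            y_co=row.y_co,
            y_h2=row.y_h2,
            y_co2=row.y_co2,
            y_inert=row.y_inert,
            y_etoh=row.y_etoh,
        )

    @classmethod
    def from_csv(cls, path) -> "OffGasSeries":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class ChemostatCondition:
    """Physical state of a steady-state chemostat culture."""

    dilution_rate: float  # 1/day
    working_volume_ml: float
    biomass: float  # gDCW/L
    gas_flow_in: float  # mL/min
    temperature: float = 37.0  # degC
    pressure: float = 1.0  # atm
    ph: float = 5.0

    def __post_init__(self) -> None:
        for name in ("dilution_rate", "working_volume_ml", "biomass", "gas_flow_in"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def growth_rate(self) -> float:
        """Steady-state specific growth rate mu = D/24, 1/h."""
        return self.dilution_rate / 24.0

    @property
    def dilution_rate_h(self) -> float:
        return self.dilution_rate / 24.0

    @property
    def working_volume_l(self) -> float:
        return self.working_volume_ml / 1000.0


def offgas_flow(f_in: float, y_inert_in: float, y_inert_out: float) -> float:
    """Off-gas volumetric flow (mL/min) from inert-tracer conservation."""
    if y_inert_in <= 0 or y_inert_out <= 0:
        raise ValueError(
            "inert-tracer flow estimation needs a strictly positive inert "
            "fraction in both feed and off-gas (the tracer is assumed to be "
            "neither consumed nor produced)"
        )
    return f_in * y_inert_in / y_inert_out


def specific_rate(
    f_in: float,
    f_out: float,
    y_in: float,
    y_out: float,
    cond: ChemostatCondition,
    molar_volume: float = DEFAULT_CONFIG.molar_volume,
    sign: Literal["uptake", "production"] = "uptake",
) -> float:
    """Specific rate of one gas species, mmol/gDCW/h.

    ``sign='uptake'`` returns in-minus-out (positive when consumed);
    ``sign='production'`` returns out-minus-in (positive when produced).
    """
    if molar_volume <= 0:
        raise ValueError("molar_volume must be positive")
    diff = f_in * y_in - f_out * y_out
    q = diff * 60.0 / (molar_volume * cond.working_volume_l * cond.biomass)
    if sign == "production":
        return -q
    if sign != "uptake":
        raise ValueError("sign must be 'uptake' or 'production'")
    return q


def ethanol_stripping_rate(
    f_out: float,
    y_etoh_out: float,
    cond: ChemostatCondition,
    molar_volume: float = DEFAULT_CONFIG.molar_volume,
) -> float:
    """Ethanol export via the off-gas stream, mmol/gDCW/h.

    Total ethanol production is the liquid-outflow term (D * c / X) plus
    this stripping term.
    """
    if y_etoh_out < 0:
        raise ValueError("y_etoh_out must be non-negative")
    return specific_rate(0.0, f_out, 0.0, y_etoh_out, cond, molar_volume, "production")


def dissolved_co2_concentration(
    y_co2_out: float,
    cond: ChemostatCondition,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """Total soluble CO2 in broth (CO2(aq) + optionally HCO3-), mmol/L.

    CO2(aq) follows Henry's law at the off-gas CO2 partial pressure;
    bicarbonate follows from the Henderson-Hasselbalch relation at culture
    pH (second dissociation neglected: carbonate is vanishing at pH 5-6).
    """
    p_co2 = y_co2_out * config.pressure_atm
    co2_aq = config.henry_kh * p_co2 * 1000.0  # mmol/L
    if config.include_bicarbonate:
        co2_aq *= 1.0 + 10.0 ** (cond.ph - config.pka1)
    return co2_aq


def dissolved_co2_rate(
    y_co2_out: float,
    cond: ChemostatCondition,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """CO2 leaving the reactor dissolved in broth outflow, mmol/gDCW/h."""
    c = dissolved_co2_concentration(y_co2_out, cond, config)
    return cond.dilution_rate_h * c / cond.biomass


def _series_gas_rates(
    feed: GasComposition,
    offgas: OffGasSeries,
    cond: ChemostatCondition,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Per-timepoint gas rates, vectorised over the series.

    Measured mole fractions are taken as-is (instrument noise means a row
    need not sum to exactly 1); the inert tracer handles the flow.
    """
    fr = offgas.frame
    y_inert = fr["y_inert"].to_numpy()
    if np.any(y_inert <= 0):
        raise ValueError(
            "off-gas inert fraction must stay positive for tracer-based "
            "flow estimation"
        )
    f_in = cond.gas_flow_in
    f_out = f_in * feed.y_inert / y_inert
    denom = config.molar_volume * cond.working_volume_l * cond.biomass
    per_t = pd.DataFrame(index=fr.index)
    per_t["q_co"] = (f_in * feed.y_co - f_out * fr["y_co"]) * 60.0 / denom
    per_t["q_h2"] = (f_in * feed.y_h2 - f_out * fr["y_h2"]) * 60.0 / denom
    per_t["q_co2_gas"] = (f_out * fr["y_co2"] - f_in * feed.y_co2) * 60.0 / denom
    c_diss = config.henry_kh * fr["y_co2"] * config.pressure_atm * 1000.0
    if config.include_bicarbonate:
        c_diss = c_diss * (1.0 + 10.0 ** (cond.ph - config.pka1))
    per_t["q_co2_liquid"] = cond.dilution_rate_h * c_diss / cond.biomass
    per_t["q_etoh_gas"] = f_out * fr["y_etoh"] * 60.0 / denom
    return per_t


def rates_from_series(
    dataset: "SyntheticDataset | None" = None,
    *,
    offgas: OffGasSeries | None = None,
    broth: pd.DataFrame | None = None,
    feed: GasComposition | None = None,
    condition: ChemostatCondition | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> SpecificRates:
    """Time-averaged steady-state specific rates from raw observables.

    Accepts either a :class:`~acetogas.synthetic_data.SyntheticDataset` (or
    any object with ``offgas``, ``broth``, ``feed`` and ``condition``
    attributes) or the four pieces passed explicitly. The biomass
    concentration entering the per-gDCW normalisation is derived from the
    observed OD600 (mean over the broth series) via the OD->DCW factor; the
    condition's nominal biomass is not used by the analysis.

    Per-timepoint gas rates are averaged arithmetically over the window and
    their standard deviation is reported in ``SpecificRates.std``. Negative
    mean uptake (net production, seen for H2 on CO-only feeds) is reported
    as-is with a warning, never clipped.
    """
    if dataset is not None:
        offgas = dataset.offgas
        broth = dataset.broth
        feed = dataset.feed
        condition = dataset.condition
    if offgas is None or broth is None or feed is None or condition is None:
        raise ValueError(
            "provide a dataset or all of offgas, broth, feed and condition"
        )
    if len(broth) == 0:
        raise ValueError("broth series is empty")

    x_meas = biomass_from_od(float(broth["od600"].mean()), config.od_to_dcw)
    cond = ChemostatCondition(
        dilution_rate=condition.dilution_rate,
        working_volume_ml=condition.working_volume_ml,
        biomass=x_meas,
        gas_flow_in=condition.gas_flow_in,
        temperature=condition.temperature,
        pressure=condition.pressure,
        ph=condition.ph,
    )

    per_t = _series_gas_rates(feed, offgas, cond, config)
    mean = per_t.mean()
    std = per_t.std(ddof=0)

    d_h = cond.dilution_rate_h
    q_etoh_liquid = (
        d_h * float(broth["ethanol_g_l"].mean()) / MW_ETHANOL * 1000.0 / x_meas
    )
    q_acetate = d_h * float(broth["acetate_g_l"].mean()) / MW_ACETATE * 1000.0 / x_meas
    q_bdo = d_h * float(broth["bdo_g_l"].mean()) / MW_BDO * 1000.0 / x_meas

    q_h2 = float(mean["q_h2"])
    if q_h2 < -std["q_h2"] - 1e-12 and q_h2 < 0:
        warnings.warn(
            "mean H2 uptake is negative (net H2 production); reporting the "
            "signed value without clipping",
            stacklevel=2,
        )
    return SpecificRates(
        q_co=float(mean["q_co"]),
        q_h2=q_h2,
        q_co2=float(mean["q_co2_gas"] + mean["q_co2_liquid"]),
        q_etoh=q_etoh_liquid + float(mean["q_etoh_gas"]),
        q_acetate=q_acetate,
        q_bdo=q_bdo,
        mu=cond.growth_rate,
        std={k: float(v) for k, v in std.items()},
    )


def broth_sample_from_series(broth: pd.DataFrame) -> BrothSample:
    """Mean broth composition over the steady-state window."""
    return BrothSample(
        acetate_g_l=float(broth["acetate_g_l"].mean()),
        ethanol_g_l=float(broth["ethanol_g_l"].mean()),
        bdo_g_l=float(broth["bdo_g_l"].mean()),
        od600=float(broth["od600"].mean()),
    )
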