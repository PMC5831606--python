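"""Synthetic steady-state chemostat datasets with known ground truth.

The generator emulates CO-limited chemostats of a gas-fermenting acetogen at
D ~ 1/day on three feed gases (CO/Ar, a high-H2 CO mix, and syngas), at a
low and a high steady-state biomass level. Given a ground-truth set of
specific rates it emits the raw observables the analysis pipeline consumes
-- off-gas mole-fraction time series, broth HPLC concentrations and OD600 --
by running the species mass balances forward:

* the inert tracer is conserved, fixing the off-gas molar flow;
* each species' outflow is inflow minus uptake (plus production) times
  biomass and working volume;
* a fixed fraction of produced ethanol leaves stripped in the off-gas, the
  rest accumulates to the steady-state broth concentration c = q*X/D;
* the gaseous CO2 outflow is solved (small fixed point) so that the gas
  term plus the dissolved CO2 carried out with the broth equals the true
  total CO2 production -- making the forward model the exact algebraic
  inverse of the rate calculator, so a noise-free dataset round-trips to
  the truth to machine precision.

Measurement noise is multiplicative Gaussian, independent per timepoint and
observable (defaults: 1% on gas fractions, 2% on HPLC, 3% on OD).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .balances import (
    SPECIES,
    CarbonDistribution,
    SpecificRates,
    carbon_recovery,
    normalize_distribution,
)
from .config import (
    MW_ACETATE,
    MW_BDO,
    MW_ETHANOL,
    AnalysisConfig,
    DEFAULT_CONFIG,
)
from .gas_balance import (
    BROTH_COLUMNS,
    OFFGAS_COLUMNS,
    ChemostatCondition,
    GasComposition,
    OffGasSeries,
    dissolved_co2_concentration,
)

__all__ = [
    "NoiseModel",
    "ConditionPreset",
    "GeneratorTruth",
    "SyntheticDataset",
    "condition_presets",
    "get_preset",
    "rate_profiles",
    "carbon_profiles",
    "truth_from_carbon_profile",
    "generate_chemostat",
]


@dataclass(frozen=True)
class NoiseModel:
    """Per-observable relative standard deviations (multiplicative Gaussian)."""

    gas: float = 0.01
    hplc: float = 0.02
    od: float = 0.03

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(gas=0.0, hplc=0.0, od=0.0)


@dataclass(frozen=True)
class ConditionPreset:
    """One study condition: feed gas, flow, volume, dilution and biomass."""

    name: str
    label: str  # co | syngas | high_h2_co
    feed: GasComposition
    gas_flow_in: float  # mL/min
    working_volume_ml: float
    dilution_rate: float  # 1/day
    biomass: float  # gDCW/L
    ph: float = 5.0
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if abs(self.feed.total() - 1.0) > 1e-9:
            raise ValueError("feed mole fractions must sum to 1")
        for attr in ("gas_flow_in", "working_volume_ml", "dilution_rate", "biomass"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")

    def condition(self) -> ChemostatCondition:
        return ChemostatCondition(
            dilution_rate=self.dilution_rate,
            working_volume_ml=self.working_volume_ml,
            biomass=self.biomass,
            gas_flow_in=self.gas_flow_in,
            temperature=self.temperature,
            ph=self.ph,
        )


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground truth behind a synthetic dataset."""

    specific_rates: SpecificRates
    carbon_fractions: CarbonDistribution | None = None
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    stripping_fraction: float = 0.1  # share of total ethanol leaving via gas

    @classmethod
    def from_rates(
        cls,
        rates: SpecificRates,
        noise_model: NoiseModel | None = None,
        seed: int = 0,
        stripping_fraction: float = 0.1,
        config: AnalysisConfig = DEFAULT_CONFIG,
    ) -> "GeneratorTruth":
        return cls(
            specific_rates=rates,
            carbon_fractions=normalize_distribution(carbon_recovery(rates, config)),
            noise_model=noise_model or NoiseModel(),
            seed=seed,
            stripping_fraction=stripping_fraction,
        )


@dataclass(frozen=True)
class SyntheticDataset:
    """Observables plus the truth that generated them."""

    preset: ConditionPreset
    truth: GeneratorTruth
    offgas: OffGasSeries
    broth: pd.DataFrame

    @property
    def condition(self) -> ChemostatCondition:
        return self.preset.condition()

    @property
    def feed(self) -> GasComposition:
        return self.preset.feed

    def offgas_csv(self) -> str:
        buf = io.StringIO()
        self.offgas.frame.to_csv(buf, index=False)
        return buf.getvalue()

    def broth_csv(self) -> str:
        buf = io.StringIO()
        self.broth.to_csv(buf, index=False)
        return buf.getvalue()

    def sidecar(self) -> dict:
        """YAML-serialisable preset + truth + seed record."""
        r = self.truth.specific_rates
        return {
            "preset": {
                "name": self.preset.name,
                "label": self.preset.label,
                "feed": self.preset.feed.as_dict(),
                "gas_flow_in_ml_min": self.preset.gas_flow_in,
                "working_volume_ml": self.preset.working_volume_ml,
                "dilution_rate_per_day": self.preset.dilution_rate,
                "biomass_gdcw_l": self.preset.biomass,
                "ph": self.preset.ph,
                "temperature_c": self.preset.temperature,
            },
            "truth": {
                "rates_mmol_gdcw_h": {
                    "q_co": r.q_co,
                    "q_h2": r.q_h2,
                    "q_co2": r.q_co2,
                    "q_etoh": r.q_etoh,
                    "q_acetate": r.q_acetate,
                    "q_bdo": r.q_bdo,
                    "mu_per_h": r.mu,
                },
                "carbon_fractions_pct": (
                    self.truth.carbon_fractions.fractions
                    if self.truth.carbon_fractions is not None
                    else None
                ),
                "stripping_fraction": self.truth.stripping_fraction,
                "noise": {
                    "gas": self.truth.noise_model.gas,
                    "hplc": self.truth.noise_model.hplc,
                    "od": self.truth.noise_model.od,
                },
            },
            "seed": self.truth.seed,
        }

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "offgas.csv").write_text(self.offgas_csv())
        (out / "broth.csv").write_text(self.broth_csv())
        (out / "dataset.yml").write_text(
            yaml.safe_dump(self.sidecar(), sort_keys=True)
        )


# --------------------------------------------------------------------------
# Study conditions
# --------------------------------------------------------------------------

_FEED_CO = GasComposition(y_co=0.60, y_inert=0.40)
_FEED_HIGH_H2 = GasComposition(y_co=0.15, y_h2=0.45, y_inert=0.40)
_FEED_SYNGAS = GasComposition(y_co=0.50, y_h2=0.20, y_co2=0.20, y_inert=0.10)

_V_ML = 750.0
_D = 1.0


def condition_presets() -> list[ConditionPreset]:
    """The six study conditions: three feed gases at low/high biomass.

    Feed compositions: CO ~60% CO/40% Ar; high-H2 CO ~15% CO/45% H2/40% Ar;
    syngas ~50% CO/20% H2/20% CO2/10% inert. Working volume 750 mL,
    D = 1.0/day throughout. Biomass setpoints 0.47/1.43 (CO), 0.46/1.45
    (high-H2 CO) and ~0.5/1.4 gDCW/L (syngas); the high-biomass high-H2 CO
    culture ran at 110 mL/min gas flow, the others at 46.5 mL/min.
    """
    mk = lambda name, label, feed, flow, x: ConditionPreset(  # noqa: E731
        name=name,
        label=label,
        feed=feed,
        gas_flow_in=flow,
        working_volume_ml=_V_ML,
        dilution_rate=_D,
        biomass=x,
    )
    return [
        mk("co_low", "co", _FEED_CO, 46.5, 0.47),
        mk("co_high", "co", _FEED_CO, 46.5, 1.43),
        mk("high_h2_co_low", "high_h2_co", _FEED_HIGH_H2, 46.5, 0.46),
        mk("high_h2_co_high", "high_h2_co", _FEED_HIGH_H2, 110.0, 1.45),
        mk("syngas_low", "syngas", _FEED_SYNGAS, 46.5, 0.50),
        mk("syngas_high", "syngas", _FEED_SYNGAS, 46.5, 1.40),
    ]


def get_preset(name: str) -> ConditionPreset:
    for p in condition_presets():
        if p.name == name:
            return p
    raise KeyError(f"unknown preset {name!r}")


_MU = _D / 24.0


def rate_profiles() -> dict[str, SpecificRates]:
    """Representative steady-state rate profiles per condition.

    The high-biomass profiles carry the reported headline ratios: on CO,
    qCO2/qCO = 0.69 with marginal net H2 production; on high-H2 CO,
    qH2/qCO = 1.44 and qCO2/qCO = 0.21 with H2 uptake ~30 mmol/gDCW/h and
    no 2,3-BDO; on syngas, qH2/qCO = 0.39. Absolute magnitudes are set so
    the emitted off-gas CO fraction matches the observed ~9% (high-H2 CO)
    and ~32% (syngas) levels and broth ethanol reaches ~11 g/L on
    high-H2 CO. Low-biomass profiles carry the same character with the
    highest specific ethanol rate on low-biomass high-H2 CO.
    """
    q = lambda co, h2, co2, et, ac, bdo: SpecificRates(  # noqa: E731
        q_co=co, q_h2=h2, q_co2=co2, q_etoh=et, q_acetate=ac, q_bdo=bdo, mu=_MU
    )
    return {
        "co_low": q(26.0, -0.20, 19.5, 1.5, 2.5, 0.05),
        "co_high": q(24.0, -0.24, 16.56, 2.2, 2.4, 0.10),
        "high_h2_co_low": q(23.0, 34.5, 3.45, 9.0, 0.9, 0.0),
        "high_h2_co_high": q(20.8, 29.952, 4.368, 7.5, 1.35, 0.0),
        "syngas_low": q(28.0, 11.0, 13.0, 3.0, 3.0, 0.10),
        "syngas_high": q(30.0, 11.7, 13.5, 3.6, 3.24, 0.15),
    }


def carbon_profiles() -> dict[str, dict[str, float]]:
    """Normalized carbon distributions (percent of consumed C, sum 100).

    The high-biomass CO and high-H2 CO profiles are the observed normalized
    distributions (CO: 61% CO2 / 15% ethanol / 18% acetate / 5.1% biomass /
    0.9% 2,3-BDO; high-H2 CO: 17% CO2 / 61% ethanol / 15% acetate / 6.8%
    biomass, remainder 2,3-BDO).
    """
    return {
        "co_high": {
            "co2": 61.0,
            "ethanol": 15.0,
            "acetate": 18.0,
            "biomass": 5.1,
            "bdo": 0.9,
        },
        "high_h2_co_high": {
            "co2": 17.0,
            "ethanol": 61.0,
            "acetate": 15.0,
            "biomass": 6.8,
            "bdo": 0.2,
        },
    }


# --------------------------------------------------------------------------
# Truth construction
# --------------------------------------------------------------------------


def truth_from_carbon_profile(
    preset: ConditionPreset,
    carbon_fractions: dict[str, float] | CarbonDistribution,
    q_co: float | None = None,
    h2_co_ratio: float | None = None,
    *,
    rtol: float = 1e-6,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
    stripping_fraction: float = 0.1,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> GeneratorTruth:
    """Absolute species rates from a normalized carbon distribution.

    The fractions (percent of consumed carbon to CO2, ethanol, acetate,
    2,3-BDO and biomass) must sum to 100; carbon then closes exactly at
    100% recovery by construction. Because the chemostat pins
    mu = D/24 and the biomass carbon content is fixed, a non-zero biomass
    fraction determines q_CO uniquely (q_co, if also supplied, must agree
    within ``rtol``); with a zero biomass fraction q_co is required.

    The H2/CO uptake ratio is solved from the degree-of-reduction balance
    when ``h2_co_ratio`` is None; an explicit ratio is checked against the
    electron balance and rejected with a surplus/deficit diagnostic when it
    does not close within ``rtol`` (relative to total electron input).
    """
    if isinstance(carbon_fractions, CarbonDistribution):
        fr = carbon_fractions.fractions
    else:
        fr = dict(carbon_fractions)
    for key in ("co2", "ethanol", "acetate", "bdo", "biomass"):
        fr.setdefault(key, 0.0)
        if fr[key] < 0:
            raise ValueError(f"carbon fraction {key} must be non-negative")
    total = sum(fr.values())
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"carbon fractions must sum to 100, got {total}")

    mu = preset.dilution_rate / 24.0
    c_x = config.biomass.carbon_content
    if fr["biomass"] > 0:
        q_co_implied = 100.0 * mu * c_x / fr["biomass"]
        if q_co is None:
            q_co = q_co_implied
        elif abs(q_co - q_co_implied) > rtol * q_co_implied:
            raise ValueError(
                f"q_co={q_co} inconsistent with biomass fraction "
                f"{fr['biomass']}% at mu={mu:.6g}/h (implies q_co="
                f"{q_co_implied:.6g})"
            )
    elif q_co is None:
        raise ValueError("q_co is required when the biomass fraction is zero")
    if q_co <= 0:
        raise ValueError("q_co must be positive")
    # growth follows the biomass fraction: equals D/24 when q_co was
    # inferred; zero for the degenerate no-biomass profiles
    mu = fr["biomass"] / 100.0 * q_co / c_x

    rates = SpecificRates(
        q_co=q_co,
        q_h2=0.0,
        q_co2=fr["co2"] / 100.0 * q_co,
        q_etoh=fr["ethanol"] / 100.0 * q_co / 2.0,
        q_acetate=fr["acetate"] / 100.0 * q_co / 2.0,
        q_bdo=fr["bdo"] / 100.0 * q_co / 4.0,
        mu=mu,
    )
    bio = config.biomass
    e_out = (
        SPECIES["ethanol"].gamma * rates.q_etoh
        + SPECIES["acetate"].gamma * rates.q_acetate
        + SPECIES["bdo"].gamma * rates.q_bdo
        + bio.degree_of_reduction * mu * c_x
    )
    q_h2_required = (e_out - SPECIES["co"].gamma * q_co) / SPECIES["h2"].gamma
    if h2_co_ratio is None:
        q_h2 = q_h2_required
    else:
        if h2_co_ratio < 0:
            raise ValueError("h2_co_ratio must be non-negative")
        q_h2 = h2_co_ratio * q_co
        e_in = SPECIES["co"].gamma * q_co + SPECIES["h2"].gamma * q_h2
        imbalance = e_in - e_out
        if abs(imbalance) > rtol * max(e_in, e_out):
            kind = "surplus" if imbalance > 0 else "deficit"
            raise ValueError(
                f"electron balance does not close at h2_co_ratio="
                f"{h2_co_ratio}: {kind} of {abs(imbalance):.6g} "
                f"mmol e-/gDCW/h (in {e_in:.6g}, out {e_out:.6g}); the "
                f"closing ratio is {q_h2_required / q_co:.6g}"
            )
    rates = replace(rates, q_h2=q_h2)
    return GeneratorTruth.from_rates(
        rates,
        noise_model=noise_model,
        seed=seed,
        stripping_fraction=stripping_fraction,
        config=config,
    )


# --------------------------------------------------------------------------
# Forward model
# --------------------------------------------------------------------------


def _steady_state_offgas(
    preset: ConditionPreset,
    rates: SpecificRates,
    stripping_fraction: float,
    config: AnalysisConfig,
) -> tuple[GasComposition, float]:
    """Noise-free off-gas composition and flow implied by the truth rates.

    The gaseous CO2 outflow is obtained by a fixed-point solve so that the
    gas term plus dissolved-CO2 broth export matches the true total CO2
    production rate.
    """
    cond = preset.condition()
    vm = config.molar_volume
    f_in = preset.gas_flow_in
    feed = preset.feed
    u = cond.biomass * cond.working_volume_l / 60.0  # mmol/min per unit q

    n_in = {k: f_in * y / vm for k, y in feed.as_dict().items()}
    n_out = {
        "y_co": n_in["y_co"] - rates.q_co * u,
        "y_h2": n_in["y_h2"] - rates.q_h2 * u,
        "y_inert": n_in["y_inert"],
        "y_etoh": n_in["y_etoh"] + stripping_fraction * rates.q_etoh * u,
    }
    if n_in["y_inert"] <= 0:
        raise ValueError("feed must contain inert tracer gas")

    # fixed point for gaseous CO2 (dissolved export depends on y_CO2_out)
    n_co2 = n_in["y_co2"] + rates.q_co2 * u
    for _ in range(100):
        n_tot = sum(n_out.values()) + n_co2
        y_co2 = n_co2 / n_tot
        q_diss = (
            cond.dilution_rate_h
            * dissolved_co2_concentration(y_co2, cond, config)
            / cond.biomass
        )
        n_co2_new = n_in["y_co2"] + (rates.q_co2 - q_diss) * u
        if abs(n_co2_new - n_co2) < 1e-15 * max(n_co2, 1.0):
            n_co2 = n_co2_new
            break
        n_co2 = n_co2_new
    n_out["y_co2"] = n_co2

    for key, val in n_out.items():
        if val < -1e-12:
            raise ValueError(
                f"truth rates imply negative off-gas flow for {key} "
                f"({val:.4g} mmol/min): unphysical rate set for this preset"
            )
        n_out[key] = max(val, 0.0)
    n_tot = sum(n_out.values())
    comp = GasComposition(**{k: v / n_tot for k, v in n_out.items()})
    return comp, n_tot * vm


def generate_chemostat(
    preset: ConditionPreset,
    truth: GeneratorTruth,
    n_timepoints: int = 50,
    seed: int | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> SyntheticDataset:
    """Emit a noisy steady-state dataset for ``preset`` under ``truth``.

    Timepoints are hourly; every observable fluctuates independently around
    its steady-state value with the truth's multiplicative noise model. A
    fixed seed yields a byte-identical dataset. ``seed=None`` uses
    ``truth.seed``.
    """
    if n_timepoints < 1:
        raise ValueError("need at least one timepoint")
    if seed is None:
        seed = truth.seed
    else:
        truth = replace(truth, seed=seed)
    rates = truth.specific_rates
    comp, _ = _steady_state_offgas(
        preset, rates, truth.stripping_fraction, config
    )

    cond = preset.condition()
    d_h = cond.dilution_rate_h
    x = cond.biomass
    liquid = 1.0 - truth.stripping_fraction
    conc = {
        "ethanol_g_l": liquid * rates.q_etoh * x / d_h * MW_ETHANOL / 1000.0,
        "acetate_g_l": rates.q_acetate * x / d_h * MW_ACETATE / 1000.0,
        "bdo_g_l": rates.q_bdo * x / d_h * MW_BDO / 1000.0,
    }
    od = x / config.od_to_dcw

    rng = np.random.default_rng(seed)
    times = np.arange(1, n_timepoints + 1, dtype=float)
    nm = truth.noise_model

    def jitter(value: float, sigma: float) -> np.ndarray:
        return value * (1.0 + sigma * rng.standard_normal(n_timepoints))

    offgas = pd.DataFrame({"time_h": times})
    for col, y in comp.as_dict().items():
        offgas[col] = jitter(y, nm.gas)
    offgas = offgas[OFFGAS_COLUMNS]

    broth = pd.DataFrame({"time_h": times})
    for col, c in conc.items():
        broth[col] = jitter(c, nm.hplc)
    broth["od600"] = jitter(od, nm.od)
    broth = broth[BROTH_COLUMNS]

    return SyntheticDataset(
        preset=preset,
        truth=truth,
        offgas=OffGasSeries(offgas),
        broth=broth,
    )
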