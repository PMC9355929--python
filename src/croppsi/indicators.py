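"""Per-system agronomic, economic and environmental indicators.

For each household x cropping-system observation the engine computes, on an
annual per-hectare basis:

* rice equivalent yield REY = sum over crops of Y_x * P_x / P_r, where P_r
  is the household's own aman paddy price and, for rice crops, Y_x includes
  straw converted to grain equivalent through the straw/grain price ratio;
* gross returns, cost of cultivation and net returns (BDT/ha/yr), straw
  value included for rice;
* agronomic energy input AEI (GJ/ha/yr): embedded energy of fertilizer
  nutrients, pesticide a.i. and diesel, plus human labor person-hours;
* total energy production TEP (GJ/ha/yr) from grain yields only — straw
  energy is deliberately excluded, mirroring the asymmetry of the source
  methodology (straw enters REY and gross returns but not TEP);
* net energy yield NEY = TEP - AEI and the derived efficiency indicators
  (energy efficiency, partial N and K2O productivity, benefit-cost ratio,
  partial GHG footprint, hired-labor energy productivity).

The partial GHG footprint covers input production/use emissions (CO2e of
fertilizer, pesticide and diesel) plus IPCC Tier-1 direct and indirect
fertilizer N2O; soil methane from flooded fields is never included.

Zero denominators yield masked (NaN) indicator values, never 0 or inf;
rows are retained so each indicator is dropped listwise on its own.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .coefficients import CoefficientTable, N2OFactors, default_coefficients
from .records import Crop, RICE_CROPS, SystemObservation
from .io import OBSERVATION_KEY

#: The seven indicators entering the multi-criteria performance index.
SEVEN_INDICATORS = [
    "rey",
    "pnp",
    "pkp",
    "energy_efficiency",
    "bcr",
    "ghg_footprint",
    "hlep",
]

#: Full column set of the indicator table.
INDICATOR_COLUMNS = [
    *OBSERVATION_KEY,
    "rey",
    "tep",
    "aei",
    "ney",
    "energy_efficiency",
    "pnp",
    "pkp",
    "bcr",
    "ghg_footprint",
    "hlep",
    "gross_returns",
    "cost",
    "net_returns",
    "n_rate_total",
    "k_rate_total",
    "labor_hired_total",
]

#: Kilograms per tonne, and MJ per GJ.
_KG_PER_T = 1000.0
_MJ_PER_GJ = 1000.0

#: Molecular-weight conversion from N2O-N to N2O.
_N2O_PER_N = 44.0 / 28.0


class MissingFactorError(KeyError):
    """The coefficient table lacks a factor for an input present in the data."""


def rice_equivalent_yield(obs: SystemObservation) -> float:
    """REY (t/ha/yr): all crop yields expressed as aman-rice mass via prices."""
    p_r = obs.rice_price_household
    if p_r <= 0:
        raise ValueError(
            f"household {obs.household_id!r}: aman price P_r={p_r} must be > 0"
        )
    total = 0.0
    for rec in obs.records:
        if rec.crop is Crop.FALLOW:
            continue
        y_x = rec.grain_yield
        if rec.crop in RICE_CROPS and rec.crop_price > 0:
            # Straw converted to grain equivalent through the price ratio.
            y_x += rec.straw_yield * rec.straw_price / rec.crop_price
        total += y_x * rec.crop_price / p_r
    return total


def economics(obs: SystemObservation) -> tuple[float, float, float]:
    """(gross returns, cost of cultivation, net returns) in BDT/ha/yr."""
    gross = 0.0
    cost = 0.0
    for rec in obs.records:
        gross += rec.grain_yield * rec.crop_price
        if rec.crop in RICE_CROPS:
            gross += rec.straw_yield * rec.straw_price
        cost += (
            rec.cost_inputs + rec.cost_labor + rec.cost_landprep + rec.cost_irrigation
        )
    return gross, cost, gross - cost


def agronomic_energy_input(obs: SystemObservation, table: CoefficientTable) -> float:
    """AEI (GJ/ha/yr): embedded input energy plus labor energy."""
    ef = table.energy_per_input
    for kind in ("n", "p2o5", "k2o", "pesticide", "diesel"):
        if kind not in ef:
            raise MissingFactorError(f"no energy factor for input {kind!r}")
    mj = 0.0
    for rec in obs.records:
        mj += (
            rec.n_rate * ef["n"]
            + rec.p_rate * ef["p2o5"]
            + rec.k_rate * ef["k2o"]
            + rec.pesticide * ef["pesticide"]
            + rec.fuel * ef["diesel"]
            + rec.labor_total * table.energy_labor
        )
    return mj / _MJ_PER_GJ


def total_energy_production(obs: SystemObservation, table: CoefficientTable) -> float:
    """TEP (GJ/ha/yr) from grain yields only (no straw energy)."""
    mj = 0.0
    for rec in obs.records:
        if rec.crop is Crop.FALLOW or rec.grain_yield == 0:
            continue
        factor = table.energy_grain_by_crop.get(rec.crop.value)
        if factor is None:
            raise MissingFactorError(
                f"no grain energy factor for crop {rec.crop.value!r}"
            )
        mj += rec.grain_yield * _KG_PER_T * factor
    return mj / _MJ_PER_GJ


def net_energy_yield(tep: float, aei: float) -> float:
    """NEY = TEP - AEI (GJ/ha/yr); may be negative."""
    return tep - aei


def n2o_co2e(n_rate: float, factors: N2OFactors) -> float:
    """Direct + indirect fertilizer N2O as kg CO2e/ha (IPCC Tier-1).

    N2O-N = N*EF1 (direct) + N*Frac_GASF*EF4 (volatilization)
    + N*Frac_LEACH*EF5 (leaching); converted by 44/28 and GWP100.
    """
    if n_rate < 0:
        raise ValueError(f"n_rate={n_rate} must be >= 0")
    n2o_n = n_rate * (
        factors.ef1
        + factors.frac_gasf * factors.ef4
        + factors.frac_leach * factors.ef5
    )
    return n2o_n * _N2O_PER_N * factors.gwp_n2o


def partial_ghg_emissions(obs: SystemObservation, table: CoefficientTable) -> float:
    """Input-embedded CO2e plus fertilizer N2O, kg CO2e/ha/yr.

    Soil methane from flooded fields is excluded by design.
    """
    gf = table.ghg_per_input
    kg = 0.0
    for rec in obs.records:
        kg += (
            rec.n_rate * gf["n"]
            + rec.p_rate * gf["p2o5"]
            + rec.k_rate * gf["k2o"]
            + rec.pesticide * gf["pesticide"]
            + rec.fuel * gf["diesel"]
        )
        kg += n2o_co2e(rec.n_rate, table.n2o_factors)
    return kg


def partial_ghg_footprint(obs: SystemObservation, table: CoefficientTable) -> float:
    """Partial GHG footprint, kg CO2e per GJ of energy production.

    Returns NaN (masked) when TEP is zero.
    """
    tep = total_energy_production(obs, table)
    if tep <= 0:
        return float("nan")
    return partial_ghg_emissions(obs, table) / tep


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_indicator_row(
    obs: SystemObservation, table: CoefficientTable
) -> dict[str, float | str]:
    """All indicators for one observation (masked values as NaN)."""
    rey = rice_equivalent_yield(obs)
    gross, cost, net = economics(obs)
    aei = agronomic_energy_input(obs, table)
    tep = total_energy_production(obs, table)
    ney = net_energy_yield(tep, aei)
    n_total = sum(r.n_rate for r in obs.records)
    k_total = sum(r.k_rate for r in obs.records)
    hired = sum(r.labor_hired for r in obs.records)
    return {
        "household_id": obs.household_id,
        "stratum": obs.stratum.value,
        "system": obs.system_label.value,
        "rey": rey,
        "tep": tep,
        "aei": aei,
        "ney": ney,
        "energy_efficiency": _safe_ratio(ney, aei) if aei > 0 else float("nan"),
        "pnp": _safe_ratio(tep, n_total),
        "pkp": _safe_ratio(tep, k_total),
        "bcr": _safe_ratio(gross, cost),
        "ghg_footprint": _safe_ratio(partial_ghg_emissions(obs, table), tep),
        "hlep": _safe_ratio(tep, hired),
        "gross_returns": gross,
        "cost": cost,
        "net_returns": net,
        "n_rate_total": n_total,
        "k_rate_total": k_total,
        "labor_hired_total": hired,
    }


def compute_indicators(
    survey: pd.DataFrame | list[SystemObservation],
    table: CoefficientTable | None = None,
) -> pd.DataFrame:
    """Indicator table (one row per household x system) from a survey table.

    Accepts either the tidy survey DataFrame or a list of typed
    observations; the DataFrame path is fully vectorized.
    """
    if table is None:
        table = default_coefficients()
    if isinstance(survey, list):
        return pd.DataFrame(
            [compute_indicator_row(obs, table) for obs in survey],
            columns=INDICATOR_COLUMNS,
        )
    df = survey
    if df.empty:
        return pd.DataFrame(columns=INDICATOR_COLUMNS)

    crops = df["crop"]
    present = set(crops.unique()) - {Crop.FALLOW.value}
    missing = present - set(table.energy_grain_by_crop)
    if missing:
        raise MissingFactorError(
            f"no grain energy factor for crop(s) {sorted(missing)!r}"
        )
    ef = table.energy_per_input
    gf = table.ghg_per_input

    is_rice = crops.isin([c.value for c in RICE_CROPS]).to_numpy()
    grain = df["grain_yield"].to_numpy(float)
    straw = df["straw_yield"].to_numpy(float)
    price = df["crop_price"].to_numpy(float)
    straw_price = df["straw_price"].to_numpy(float)

    ef_grain = crops.map(table.energy_grain_by_crop).fillna(0.0).to_numpy(float)
    row_energy_mj = (
        df["n_rate"].to_numpy(float) * ef["n"]
        + df["p_rate"].to_numpy(float) * ef["p2o5"]
        + df["k_rate"].to_numpy(float) * ef["k2o"]
        + df["pesticide"].to_numpy(float) * ef["pesticide"]
        + df["fuel"].to_numpy(float) * ef["diesel"]
        + df["labor_total"].to_numpy(float) * table.energy_labor
    )
    n2o_per_kg_n = n2o_co2e(1.0, table.n2o_factors)
    row_ghg = (
        df["n_rate"].to_numpy(float) * (gf["n"] + n2o_per_kg_n)
        + df["p_rate"].to_numpy(float) * gf["p2o5"]
        + df["k_rate"].to_numpy(float) * gf["k2o"]
        + df["pesticide"].to_numpy(float) * gf["pesticide"]
        + df["fuel"].to_numpy(float) * gf["diesel"]
    )
    work = pd.DataFrame(
        {
            "household_id": df["household_id"].to_numpy(),
            "stratum": df["stratum"].to_numpy(),
            "system": df["system"].to_numpy(),
            "rey_value": grain * price + np.where(is_rice, straw * straw_price, 0.0),
            "gross": grain * price + np.where(is_rice, straw * straw_price, 0.0),
            "cost": (
                df["cost_inputs"].to_numpy(float)
                + df["cost_labor"].to_numpy(float)
                + df["cost_landprep"].to_numpy(float)
                + df["cost_irrigation"].to_numpy(float)
            ),
            "tep_mj": grain * _KG_PER_T * ef_grain,
            "aei_mj": row_energy_mj,
            "ghg": row_ghg,
            "n_rate_total": df["n_rate"].to_numpy(float),
            "k_rate_total": df["k_rate"].to_numpy(float),
            "labor_hired_total": df["labor_hired"].to_numpy(float),
        }
    )
    agg = work.groupby(OBSERVATION_KEY, sort=True).sum(numeric_only=True)

    # P_r: the observation's own kharif2 aman price.
    aman_mask = (df["season"] == "kharif2") & (crops == Crop.AMAN_RICE.value)
    p_r = (
        df.loc[aman_mask]
        .groupby(OBSERVATION_KEY, sort=True)["crop_price"]
        .first()
        .reindex(agg.index)
    )
    if p_r.isna().any() or (p_r <= 0).any():
        bad = p_r.index[p_r.isna() | (p_r <= 0)].tolist()
        raise ValueError(f"missing or non-positive aman price P_r for {bad[:5]}")

    out = pd.DataFrame(index=agg.index)
    out["rey"] = agg["rey_value"] / p_r
    out["tep"] = agg["tep_mj"] / _MJ_PER_GJ
    out["aei"] = agg["aei_mj"] / _MJ_PER_GJ
    out["ney"] = out["tep"] - out["aei"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["energy_efficiency"] = np.where(
            out["aei"] > 0, out["ney"] / out["aei"], np.nan
        )
        out["pnp"] = np.where(
            agg["n_rate_total"] > 0, out["tep"] / agg["n_rate_total"], np.nan
        )
        out["pkp"] = np.where(
            agg["k_rate_total"] > 0, out["tep"] / agg["k_rate_total"], np.nan
        )
        out["bcr"] = np.where(agg["cost"] > 0, agg["gross"] / agg["cost"], np.nan)
        out["ghg_footprint"] = np.where(
            out["tep"] > 0, agg["ghg"] / out["tep"], np.nan
        )
        out["hlep"] = np.where(
            agg["labor_hired_total"] > 0,
            out["tep"] / agg["labor_hired_total"],
            np.nan,
        )
    out["gross_returns"] = agg["gross"]
    out["cost"] = agg["cost"]
    out["net_returns"] = agg["gross"] - agg["cost"]
    out["n_rate_total"] = agg["n_rate_total"]
    out["k_rate_total"] = agg["k_rate_total"]
    out["labor_hired_total"] = agg["labor_hired_total"]
    return out.reset_index()[INDICATOR_COLUMNS]


class IndicatorCalculator(BaseEstimator, TransformerMixin):
    """Stateless transformer: tidy survey table -> indicator table.

    Parameters
    ----------
    coefficients : CoefficientTable, optional
        Energy/GHG conversion factors; the packaged defaults when omitted.
    """

    def __init__(self, coefficients: CoefficientTable | None = None):
        self.coefficients = coefficients

    def fit(self, X: pd.DataFrame, y=None) -> "IndicatorCalculator":
        table = self.coefficients or default_coefficients()
        table.validate()
        self.coefficients_ = table
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "coefficients_"):
            self.fit(X)
        return compute_indicators(X, self.coefficients_)
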