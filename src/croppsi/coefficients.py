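"""Energy and GHG conversion-coefficient table.

Indicators are conditional on a coefficient table mapping each agronomic
input (fertilizer nutrients, pesticide active ingredient, diesel) to its
embedded energy (MJ/unit) and production/use GHG intensity (kg CO2e/unit),
plus grain energy contents and IPCC Tier-1 fertilizer-N2O factors.  A
literature-standard default table ships with the package; every factor can
be overridden from a YAML file.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

#: Input kinds every coefficient table must cover.
INPUT_KINDS = ("n", "p2o5", "k2o", "pesticide", "diesel")

#: Nutrient mass fraction of common fertilizer products, used when a survey
#: reports product mass (urea / triple superphosphate / muriate of potash)
#: instead of nutrient mass.
PRODUCT_NUTRIENT_FRACTION = {"urea": 0.46, "tsp": 0.46, "mop": 0.60}


class CoefficientError(ValueError):
    """Invalid or incomplete coefficient configuration."""


@dataclass(frozen=True)
class N2OFactors:
    """IPCC Tier-1 factors for fertilizer-derived direct + indirect N2O."""

    ef1: float = 0.01
    ef4: float = 0.010
    ef5: float = 0.0075
    frac_gasf: float = 0.10
    frac_leach: float = 0.30
    gwp_n2o: float = 265.0

    def validate(self) -> None:
        for name in ("ef1", "ef4", "ef5", "frac_gasf", "frac_leach"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CoefficientError(f"n2o factor {name}={v} outside [0, 1]")
        if self.gwp_n2o <= 0:
            raise CoefficientError(f"gwp_n2o={self.gwp_n2o} must be > 0")


@dataclass(frozen=True)
class CoefficientTable:
    """Energy (MJ/unit) and GHG (kg CO2e/unit) factors per input and output."""

    energy_per_input: dict[str, float] = field(default_factory=dict)
    energy_labor: float = 1.96
    energy_grain_by_crop: dict[str, float] = field(default_factory=dict)
    ghg_per_input: dict[str, float] = field(default_factory=dict)
    n2o_factors: N2OFactors = field(default_factory=N2OFactors)
    bdt_per_usd: float = 77.87

    @property
    def energy_rice_grain(self) -> float:
        """EF for rice grain (MJ/kg), shared by aman and boro paddy."""
        return self.energy_grain_by_crop["aman_rice"]

    @property
    def usd_per_bdt(self) -> float:
        return 1.0 / self.bdt_per_usd

    def validate(self) -> None:
        for kind in INPUT_KINDS:
            if kind not in self.energy_per_input:
                raise CoefficientError(f"missing energy factor for input {kind!r}")
            if kind not in self.ghg_per_input:
                raise CoefficientError(f"missing GHG factor for input {kind!r}")
        for name, mapping in (
            ("energy_per_input", self.energy_per_input),
            ("ghg_per_input", self.ghg_per_input),
            ("energy_grain_by_crop", self.energy_grain_by_crop),
        ):
            for key, value in mapping.items():
                if value <= 0:
                    raise CoefficientError(f"{name}[{key!r}] = {value} must be > 0")
        if self.energy_labor <= 0:
            raise CoefficientError("energy_labor must be > 0")
        if self.bdt_per_usd <= 0:
            raise CoefficientError("bdt_per_usd must be > 0")
        self.n2o_factors.validate()


_KNOWN_KEYS = {
    "energy_per_input",
    "energy_labor",
    "energy_grain_by_crop",
    "ghg_per_input",
    "n2o_factors",
    "bdt_per_usd",
}


def _table_from_mapping(raw: dict) -> CoefficientTable:
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        warnings.warn(
            f"ignoring unknown coefficient keys: {sorted(unknown)}", stacklevel=3
        )
    n2o_raw = raw.get("n2o_factors") or {}
    n2o_unknown = set(n2o_raw) - {f for f in N2OFactors.__dataclass_fields__}
    if n2o_unknown:
        warnings.warn(
            f"ignoring unknown n2o_factors keys: {sorted(n2o_unknown)}",
            stacklevel=3,
        )
        n2o_raw = {k: v for k, v in n2o_raw.items() if k not in n2o_unknown}
    table = CoefficientTable(
        energy_per_input=dict(raw.get("energy_per_input") or {}),
        energy_labor=float(raw.get("energy_labor", 1.96)),
        energy_grain_by_crop=dict(raw.get("energy_grain_by_crop") or {}),
        ghg_per_input=dict(raw.get("ghg_per_input") or {}),
        n2o_factors=N2OFactors(**n2o_raw),
        bdt_per_usd=float(raw.get("bdt_per_usd", 77.87)),
    )
    table.validate()
    return table


def default_coefficients() -> CoefficientTable:
    """The coefficient table shipped with the package."""
    text = (
        resources.files("croppsi")
        .joinpath("data/default_coefficients.yaml")
        .read_text()
    )
    return _table_from_mapping(yaml.safe_load(text))


def load_coefficients(path: str | Path | None = None) -> CoefficientTable:
    """Load a coefficient table from a YAML file.

    Keys missing from the file fall back to the packaged defaults (in
    particular the IPCC Tier-1 ``n2o_factors``).  Unknown keys raise a
    warning and are ignored; non-positive factors raise
    :class:`CoefficientError`.
    """
    if path is None:
        return default_coefficients()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    defaults = default_coefficients()
    # Merge user values over defaults so a partial file is usable.
    merged = {
        "energy_per_input": {
            **defaults.energy_per_input,
            **(raw.get("energy_per_input") or {}),
        },
        "energy_labor": raw.get("energy_labor", defaults.energy_labor),
        "energy_grain_by_crop": {
            **defaults.energy_grain_by_crop,
            **(raw.get("energy_grain_by_crop") or {}),
        },
        "ghg_per_input": {
            **defaults.ghg_per_input,
            **(raw.get("ghg_per_input") or {}),
        },
        "n2o_factors": raw.get("n2o_factors") or {},
        "bdt_per_usd": raw.get("bdt_per_usd", defaults.bdt_per_usd),
    }
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        warnings.warn(
            f"ignoring unknown coefficient keys: {sorted(unknown)}", stacklevel=2
        )
    n2o_raw = merged["n2o_factors"]
    n2o_known = {
        k: v for k, v in n2o_raw.items() if k in N2OFactors.__dataclass_fields__
    }
    if set(n2o_raw) - set(n2o_known):
        warnings.warn(
            f"ignoring unknown n2o_factors keys: {sorted(set(n2o_raw) - set(n2o_known))}",
            stacklevel=2,
        )
    table = CoefficientTable(
        energy_per_input=merged["energy_per_input"],
        energy_labor=float(merged["energy_labor"]),
        energy_grain_by_crop=merged["energy_grain_by_crop"],
        ghg_per_input=merged["ghg_per_input"],
        n2o_factors=replace(defaults.n2o_factors, **n2o_known),
        bdt_per_usd=float(merged["bdt_per_usd"]),
    )
    table.validate()
    return table
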