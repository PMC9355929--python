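"""Domain types for household cropping-system survey records.

The unit of analysis is a household x cropping-system x year bundle
(:class:`SystemObservation`) made of per-season :class:`CropSeasonRecord`
entries.  All systems in the study region are anchored on monsoon (kharif-2)
transplanted aman rice; the cropping system is named after the additional
rabi (dry winter) crop, if any.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields


class Stratum(str, enum.Enum):
    """Polder status of the household's land (embanked vs unprotected)."""

    WITHIN_POLDER = "within_polder"
    OUTSIDE_POLDER = "outside_polder"


class Season(str, enum.Enum):
    """The three annual cropping seasons of coastal Bangladesh."""

    RABI = "rabi"          # ~mid-Nov to mid-Mar, dry winter ("boro" season)
    KHARIF1 = "kharif1"    # ~mid-Mar to mid-Jul, pre-monsoon
    KHARIF2 = "kharif2"    # ~mid-Jul to mid-Nov, monsoon ("aman" season)


class Crop(str, enum.Enum):
    AMAN_RICE = "aman_rice"
    BORO_RICE = "boro_rice"
    MUNGBEAN = "mungbean"
    LATHYRUS = "lathyrus"
    GROUNDNUT = "groundnut"
    CHILI = "chili"
    FALLOW = "fallow"


#: Crops for which straw yield/price fields are meaningful.
RICE_CROPS = frozenset({Crop.AMAN_RICE, Crop.BORO_RICE})


class CroppingSystem(str, enum.Enum):
    """Annual rabi--kharif1--kharif2 sequences observed in the survey."""

    FFA = "FFA"  # fallow - fallow - aman (single-crop baseline)
    MFA = "MFA"  # mungbean - fallow - aman
    LFA = "LFA"  # lathyrus - fallow - aman
    GFA = "GFA"  # groundnut - fallow - aman
    BFA = "BFA"  # boro rice - fallow - aman (double rice)
    CFA = "CFA"  # chili - fallow - aman


#: The rabi crop implied by each system label.
SYSTEM_RABI_CROP = {
    CroppingSystem.FFA: Crop.FALLOW,
    CroppingSystem.MFA: Crop.MUNGBEAN,
    CroppingSystem.LFA: Crop.LATHYRUS,
    CroppingSystem.GFA: Crop.GROUNDNUT,
    CroppingSystem.BFA: Crop.BORO_RICE,
    CroppingSystem.CFA: Crop.CHILI,
}

#: Numeric per-hectare quantities carried by every crop-season record.
NUMERIC_FIELDS = (
    "grain_yield",      # t/ha
    "straw_yield",      # t/ha, rice only
    "crop_price",       # BDT/t
    "straw_price",      # BDT/t, rice only
    "n_rate",           # kg N/ha
    "p_rate",           # kg P2O5/ha
    "k_rate",           # kg K2O/ha
    "pesticide",        # kg a.i./ha
    "fuel",             # L diesel/ha (land preparation + irrigation pumping)
    "labor_total",      # person-hours/ha, family + hired
    "labor_hired",      # person-days/ha, hired only
    "cost_inputs",      # BDT/ha
    "cost_labor",       # BDT/ha
    "cost_landprep",    # BDT/ha
    "cost_irrigation",  # BDT/ha
)


class RecordValidationError(ValueError):
    """A record or observation violates a domain invariant."""


@dataclass
class CropSeasonRecord:
    """One crop grown by one household in one season (per-hectare basis)."""

    household_id: str
    stratum: Stratum
    season: Season
    crop: Crop
    grain_yield: float = 0.0
    straw_yield: float = 0.0
    crop_price: float = 0.0
    straw_price: float = 0.0
    n_rate: float = 0.0
    p_rate: float = 0.0
    k_rate: float = 0.0
    pesticide: float = 0.0
    fuel: float = 0.0
    labor_total: float = 0.0
    labor_hired: float = 0.0
    cost_inputs: float = 0.0
    cost_labor: float = 0.0
    cost_landprep: float = 0.0
    cost_irrigation: float = 0.0

    def __post_init__(self) -> None:
        self.stratum = Stratum(self.stratum)
        self.season = Season(self.season)
        self.crop = Crop(self.crop)

    def validate(self) -> None:
        for name in NUMERIC_FIELDS:
            value = getattr(self, name)
            if value < 0:
                raise RecordValidationError(
                    f"household {self.household_id!r}: {name}={value} < 0"
                )
        if self.crop is Crop.FALLOW:
            nonzero = [n for n in NUMERIC_FIELDS if getattr(self, n) != 0]
            if nonzero:
                raise RecordValidationError(
                    f"household {self.household_id!r}: fallow record has "
                    f"non-zero quantities {nonzero}"
                )
        if self.crop not in RICE_CROPS and (
            self.straw_yield != 0 or self.straw_price != 0
        ):
            raise RecordValidationError(
                f"household {self.household_id!r}: straw fields set for "
                f"non-rice crop {self.crop.value}"
            )


@dataclass
class SystemObservation:
    """A household x cropping-system annual bundle of season records."""

    household_id: str
    stratum: Stratum
    system_label: CroppingSystem
    records: list[CropSeasonRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stratum = Stratum(self.stratum)
        self.system_label = CroppingSystem(self.system_label)

    @property
    def aman_record(self) -> CropSeasonRecord:
        """The kharif-2 aman rice record (present in every valid system)."""
        for rec in self.records:
            if rec.season is Season.KHARIF2 and rec.crop is Crop.AMAN_RICE:
                return rec
        raise RecordValidationError(
            f"household {self.household_id!r} system {self.system_label.value}: "
            "no kharif2 aman rice record"
        )

    @property
    def rice_price_household(self) -> float:
        """P_r: the household's own aman paddy selling price (BDT/t)."""
        return self.aman_record.crop_price

    def validate(self) -> None:
        for rec in self.records:
            rec.validate()
        kharif2 = [r for r in self.records if r.season is Season.KHARIF2]
        if len(kharif2) != 1 or kharif2[0].crop is not Crop.AMAN_RICE:
            raise RecordValidationError(
                f"household {self.household_id!r} system "
                f"{self.system_label.value}: expected exactly one kharif2 "
                "aman rice record"
            )
        expected = SYSTEM_RABI_CROP[self.system_label]
        rabi = [r for r in self.records if r.season is Season.RABI]
        rabi_crops = {r.crop for r in rabi}
        if rabi and rabi_crops != {expected}:
            raise RecordValidationError(
                f"household {self.household_id!r}: rabi crop(s) "
                f"{sorted(c.value for c in rabi_crops)} inconsistent with "
                f"system {self.system_label.value}"
            )
        if self.rice_price_household <= 0:
            raise RecordValidationError(
                f"household {self.household_id!r}: aman price P_r must be > 0"
            )


def record_fields() -> list[str]:
    """Column order of the tidy survey table."""
    return [f.name for f in fields(CropSeasonRecord)]
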