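"""Tidy-CSV survey reader/writer.

The survey table has one row per household x cropping-system x season x
crop; the column dictionary is documented in ``docs/survey_columns.md``.
Lines starting with ``#`` are treated as provenance metadata and skipped on
read.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .records import (
    NUMERIC_FIELDS,
    CropSeasonRecord,
    CroppingSystem,
    RecordValidationError,
    Season,
    SystemObservation,
)
from .coefficients import PRODUCT_NUTRIENT_FRACTION

#: Canonical column order of the tidy survey table.
SURVEY_COLUMNS = [
    "household_id",
    "stratum",
    "system",
    "season",
    "crop",
    *NUMERIC_FIELDS,
]

#: Optional product-mass fertilizer columns (kg product/ha) accepted in
#: place of n_rate / p_rate / k_rate.
PRODUCT_COLUMNS = {"urea": "n_rate", "tsp": "p_rate", "mop": "k_rate"}

OBSERVATION_KEY = ["household_id", "stratum", "system"]


class SurveySchemaError(ValueError):
    """The survey file does not match the documented column dictionary."""


class SurveyValidationError(ValueError):
    """One or more rows violate domain invariants.

    Carries per-row diagnostics in :attr:`diagnostics`.
    """

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = diagnostics
        preview = "; ".join(diagnostics[:5])
        more = f" (+{len(diagnostics) - 5} more)" if len(diagnostics) > 5 else ""
        super().__init__(f"{len(diagnostics)} invalid row group(s): {preview}{more}")


def _apply_schema(df: pd.DataFrame, schema: dict[str, str] | None) -> pd.DataFrame:
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    if set(PRODUCT_COLUMNS) <= set(df.columns):
        # Product-mass mode: convert urea/TSP/MoP to nutrient mass.
        for product, nutrient in PRODUCT_COLUMNS.items():
            if nutrient not in df.columns:
                df[nutrient] = (
                    df[product].astype(float) * PRODUCT_NUTRIENT_FRACTION[product]
                )
        df = df.drop(columns=list(PRODUCT_COLUMNS))
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SurveySchemaError(f"survey file missing columns: {missing}")
    return df[SURVEY_COLUMNS]


def read_survey_frame(
    path: str | Path, schema: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read the tidy survey CSV into a validated DataFrame."""
    df = pd.read_csv(path, comment="#", dtype={"household_id": str})
    if df.empty and len(df.columns) <= 1:
        raise SurveySchemaError(f"{path}: not a survey CSV (no columns found)")
    df = _apply_schema(df, schema)
    validate_survey_frame(df)
    return df


def frame_to_observations(df: pd.DataFrame) -> list[SystemObservation]:
    """Group tidy survey rows into typed, validated observations."""
    observations: list[SystemObservation] = []
    diagnostics: list[str] = []
    for (household, stratum, system), group in df.groupby(
        OBSERVATION_KEY, sort=True
    ):
        try:
            records = [
                CropSeasonRecord(
                    household_id=str(row.household_id),
                    stratum=row.stratum,
                    season=row.season,
                    crop=row.crop,
                    **{f: float(getattr(row, f)) for f in NUMERIC_FIELDS},
                )
                for row in group.itertuples(index=False)
            ]
            obs = SystemObservation(
                household_id=str(household),
                stratum=stratum,
                system_label=CroppingSystem(system),
                records=records,
            )
            obs.validate()
        except (RecordValidationError, ValueError) as exc:
            diagnostics.append(str(exc))
            continue
        observations.append(obs)
    if diagnostics:
        raise SurveyValidationError(diagnostics)
    return observations


def observations_to_frame(observations: list[SystemObservation]) -> pd.DataFrame:
    """Flatten typed observations back to the tidy survey table."""
    rows = []
    for obs in observations:
        for rec in obs.records:
            rows.append(
                {
                    "household_id": rec.household_id,
                    "stratum": rec.stratum.value,
                    "system": obs.system_label.value,
                    "season": rec.season.value,
                    "crop": rec.crop.value,
                    **{f: getattr(rec, f) for f in NUMERIC_FIELDS},
                }
            )
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


def validate_survey_frame(df: pd.DataFrame) -> None:
    """Frame-level invariant checks with row-group diagnostics."""
    diagnostics: list[str] = []
    numeric = df[list(NUMERIC_FIELDS)]
    bad = numeric.lt(0).any(axis=1)
    for idx in df.index[bad]:
        diagnostics.append(
            f"household {df.at[idx, 'household_id']!r}: negative quantity in row {idx}"
        )
    kharif2 = df[df["season"] == Season.KHARIF2.value]
    per_obs = kharif2[kharif2["crop"] == "aman_rice"].groupby(OBSERVATION_KEY).size()
    all_obs = df.groupby(OBSERVATION_KEY).size()
    for key in all_obs.index:
        n_aman = per_obs.get(key, 0)
        if n_aman != 1:
            diagnostics.append(
                f"household {key[0]!r} system {key[2]}: expected exactly one "
                f"kharif2 aman rice record, found {n_aman}"
            )
    if diagnostics:
        raise SurveyValidationError(diagnostics)


def read_survey(
    path: str | Path, schema: dict[str, str] | None = None
) -> list[SystemObservation]:
    """Read a survey CSV into typed :class:`SystemObservation` objects."""
    return frame_to_observations(read_survey_frame(path, schema))


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    metadata: dict[str, object] | None = None,
) -> Path:
    """Write any result table as tidy CSV with optional ``#`` metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_table`."""
    return pd.read_csv(path, comment="#", dtype={"household_id": str})
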