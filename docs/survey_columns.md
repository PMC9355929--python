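# Survey column dictionary

The tidy survey table has **one row per household × cropping system ×
season × crop**.  Every cropping system covers the three annual seasons
(`rabi`, `kharif1`, `kharif2`), so a complete system observation is three
rows, with fallow seasons present as explicit all-zero rows.  Lines
starting with `#` are metadata and are skipped by the reader.

| column | type | unit | notes |
| --- | --- | --- | --- |
| `household_id` | str | — | opaque identifier |
| `stratum` | str | — | `within_polder` or `outside_polder` |
| `system` | str | — | `FFA`, `MFA`, `LFA`, `GFA`, `BFA`, `CFA` (named after the rabi crop; all systems end in kharif-2 aman rice) |
| `season` | str | — | `rabi`, `kharif1`, `kharif2` |
| `crop` | str | — | `aman_rice`, `boro_rice`, `mungbean`, `lathyrus`, `groundnut`, `chili`, `fallow` |
| `grain_yield` | float | t/ha | harvested product (paddy for rice, pods for groundnut, dry pods for chili) |
| `straw_yield` | float | t/ha | rice crops only, 0 otherwise |
| `crop_price` | float | BDT/t | household's own selling price; for the kharif-2 aman row this is P_r |
| `straw_price` | float | BDT/t | rice crops only |
| `n_rate` | float | kg N/ha | nutrient mass |
| `p_rate` | float | kg P₂O₅/ha | nutrient mass |
| `k_rate` | float | kg K₂O/ha | nutrient mass |
| `pesticide` | float | kg a.i./ha | active ingredient; convert from product mass before loading if your survey records formulations |
| `fuel` | float | L diesel/ha | land preparation + irrigation pumping |
| `labor_total` | float | person-hours/ha | family + hired |
| `labor_hired` | float | person-days/ha | hired only (denominator of hired-labor energy productivity) |
| `cost_inputs` | float | BDT/ha | seeds, fertilizer, pesticide |
| `cost_labor` | float | BDT/ha | hired labor payments |
| `cost_landprep` | float | BDT/ha | tillage / land preparation |
| `cost_irrigation` | float | BDT/ha | pumping / water charges |

## Product-mass fertilizer mode

If the survey records fertilizer as product mass, provide `urea`, `tsp`
and `mop` columns (kg product/ha) instead of `n_rate`/`p_rate`/`k_rate`;
the reader converts with the nutrient fractions 0.46 (urea → N), 0.46
(TSP → P₂O₅) and 0.60 (MoP → K₂O).

## Mapping external files

`read_survey(path, schema=...)` accepts a `{canonical_name: your_column}`
mapping, so externally produced tables (e.g. an export prepared from the
CIMMYT DataVerse survey deposit) only need a column-name dictionary, not a
format conversion.

## Validity rules

* all quantities ≥ 0; fallow rows are all-zero; straw fields only on rice
* every household × system has exactly one `kharif2` row and it is
  `aman_rice` with a positive price (the rice-equivalent denominator)
* the rabi crop must match the system label.
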