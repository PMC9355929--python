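"""Scope-for-improvement benchmarking against top-quintile performers.

For each stratum x system x indicator, the benchmark P_fy is the mean of
the best ceil(0.2 n) household values ("best" = largest, except for the
GHG footprint where smaller is better and the bottom quintile is used).
Each household's gap is

    scope (%) = (P_fy - A_FY) / A_FY * 100

where A_FY is the household's own value.  Cells with fewer than five
households are skipped, mirroring the small-sample guard of the source
analysis.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .indicators import SEVEN_INDICATORS
from .tradeoffs import DESIRABLE_DIRECTION

MIN_CELL_SIZE = 5


def top_quintile_benchmark(
    values: np.ndarray | list[float],
    direction: int = 1,
    min_n: int = MIN_CELL_SIZE,
) -> float:
    """P_fy: mean of the top-20th-percentile values.

    The top set has ceil(0.2 n) members; ties at the cutoff are all
    included.  ``direction=-1`` benchmarks the bottom quintile (used for
    lower-is-better indicators).  Returns NaN when fewer than ``min_n``
    finite values are available (cell skipped).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n < min_n:
        return float("nan")
    m = math.ceil(0.2 * n)
    ranked = np.sort(v)[::-1] if direction >= 0 else np.sort(v)
    cutoff = ranked[m - 1]
    if direction >= 0:
        top = v[v >= cutoff]
    else:
        top = v[v <= cutoff]
    return float(top.mean())


def scope(p_fy: float, a_fy: float) -> float:
    """Signed percent gap to the benchmark; NaN when A_FY is zero."""
    if a_fy == 0 or math.isnan(a_fy) or math.isnan(p_fy):
        return float("nan")
    return (p_fy - a_fy) / a_fy * 100.0


def compute_scope(
    indicators: pd.DataFrame,
    indicator_names: list[str] | None = None,
    directions: dict[str, int] | None = None,
    min_n: int = MIN_CELL_SIZE,
) -> pd.DataFrame:
    """Household-level scope table, long format.

    One row per household x system x indicator; benchmarks are computed
    within stratum x system.  For the GHG footprint the bottom-quintile
    benchmark is used and the magnitude of the (negative) scope is the
    potential reduction.
    """
    names = indicator_names or SEVEN_INDICATORS
    directions = directions or DESIRABLE_DIRECTION
    rows = []
    for (stratum, system), group in indicators.groupby(
        ["stratum", "system"], sort=True
    ):
        for name in names:
            values = group[name].to_numpy(float)
            p_fy = top_quintile_benchmark(
                values, directions.get(name, 1), min_n
            )
            if math.isnan(p_fy):
                continue  # cell skipped (too few households)
            with np.errstate(divide="ignore", invalid="ignore"):
                s = np.where(
                    (values == 0) | ~np.isfinite(values),
                    np.nan,
                    (p_fy - values) / values * 100.0,
                )
            rows.append(
                pd.DataFrame(
                    {
                        "household_id": group["household_id"],
                        "stratum": stratum,
                        "system": system,
                        "indicator": name,
                        "benchmark": p_fy,
                        "value": values,
                        "scope_percent": s,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "household_id", "stratum", "system", "indicator",
                "benchmark", "value", "scope_percent",
            ]
        )
    return pd.concat(rows, ignore_index=True)


def summarize_scope(
    scope_table: pd.DataFrame, confidence: float = 0.95
) -> pd.DataFrame:
    """Mean scope with t-based CI per stratum x system x indicator."""
    rows = []
    for (stratum, system, indicator), group in scope_table.groupby(
        ["stratum", "system", "indicator"], sort=True
    ):
        values = group["scope_percent"].dropna().to_numpy()
        n = len(values)
        if n == 0:
            continue
        mean = float(values.mean())
        if n >= 2:
            sem = values.std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
            ci_low, ci_high = mean - tcrit * sem, mean + tcrit * sem
        else:
            ci_low = ci_high = float("nan")
        rows.append(
            {
                "stratum": stratum,
                "system": system,
                "indicator": indicator,
                "n": n,
                "benchmark": float(group["benchmark"].iloc[0]),
                "mean_scope_percent": mean,
                "ci_low": ci_low,
                "ci_high": ci_high,
            }
        )
    return pd.DataFrame(rows)
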