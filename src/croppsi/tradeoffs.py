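"""Within-household synergy / trade-off analysis.

Each double-cropped system is compared with the same household's
single-aman baseline for every indicator:

    relative change (%) = (system value - baseline value) * 100 / baseline

A positive change in a higher-is-better indicator (or a negative change in
the GHG footprint, where lower is better) is a synergy; the opposite is a
trade-off.  Summaries report the mean household-level relative change with
a t-based 95% CI per stratum x system x indicator, alongside the relative
change of group means, which generally differs.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .indicators import SEVEN_INDICATORS

#: Desirable direction per indicator: +1 higher-is-better, -1 lower-is-better.
DESIRABLE_DIRECTION = {name: 1 for name in SEVEN_INDICATORS}
DESIRABLE_DIRECTION["ghg_footprint"] = -1

BASELINE_SYSTEM = "FFA"


def relative_change(system_value: float, baseline_value: float) -> float:
    """Percent change against the household's own baseline.

    Signed by the baseline (so a move from -1.0 to 1.0 is -200%); a zero
    baseline yields NaN (undefined), never +-inf.
    """
    if baseline_value == 0 or math.isnan(baseline_value):
        return float("nan")
    return (system_value - baseline_value) * 100.0 / baseline_value


def compute_relative_changes(
    indicators: pd.DataFrame,
    indicator_names: list[str] | None = None,
    baseline_system: str = BASELINE_SYSTEM,
) -> pd.DataFrame:
    """Household-level relative changes, long format.

    One row per household x system x indicator for every non-baseline
    system; households lacking a baseline observation are excluded (their
    ids are listed in the ``diagnostics`` attribute of the result).
    """
    names = indicator_names or SEVEN_INDICATORS
    key = ["household_id", "stratum"]
    base = indicators[indicators["system"] == baseline_system]
    others = indicators[indicators["system"] != baseline_system]
    merged = others.merge(
        base[key + names], on=key, how="left", suffixes=("", "_baseline"),
        indicator=True,
    )
    missing = merged.loc[merged["_merge"] != "both", "household_id"].unique()
    merged = merged[merged["_merge"] == "both"]
    rows = []
    for name in names:
        system_v = merged[name].to_numpy(float)
        base_v = merged[f"{name}_baseline"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            change = np.where(
                (base_v == 0) | np.isnan(base_v),
                np.nan,
                (system_v - base_v) * 100.0 / base_v,
            )
        rows.append(
            pd.DataFrame(
                {
                    "household_id": merged["household_id"],
                    "stratum": merged["stratum"],
                    "system": merged["system"],
                    "indicator": name,
                    "system_value": system_v,
                    "baseline_value": base_v,
                    "relative_change": change,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    out.attrs["diagnostics"] = [
        f"household {h!r}: no {baseline_system} baseline" for h in missing
    ]
    return out


def summarize_tradeoffs(
    changes: pd.DataFrame,
    directions: dict[str, int] | None = None,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Mean relative change with t-based CI and synergy/trade-off label.

    Cells (stratum x system x indicator) need >= 2 households for a CI;
    empty cells are omitted.
    """
    directions = directions or DESIRABLE_DIRECTION
    rows = []
    for (stratum, system, indicator), group in changes.groupby(
        ["stratum", "system", "indicator"], sort=True
    ):
        values = group["relative_change"].dropna().to_numpy()
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
        direction = directions.get(indicator, 1)
        label = "synergy" if mean * direction > 0 else (
            "trade-off" if mean * direction < 0 else "neutral"
        )
        rows.append(
            {
                "stratum": stratum,
                "system": system,
                "indicator": indicator,
                "n": n,
                "mean_relative_change": mean,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def relative_change_of_group_means(
    indicators: pd.DataFrame,
    indicator_names: list[str] | None = None,
    baseline_system: str = BASELINE_SYSTEM,
) -> pd.DataFrame:
    """Relative change computed on group means (contrast with the mean of
    household-level changes, which it generally does not equal)."""
    names = indicator_names or SEVEN_INDICATORS
    means = indicators.groupby(["stratum", "system"])[names].mean()
    rows = []
    for (stratum, system), row in means.iterrows():
        if system == baseline_system:
            continue
        base = means.loc[(stratum, baseline_system)]
        for name in names:
            rows.append(
                {
                    "stratum": stratum,
                    "system": system,
                    "indicator": name,
                    "relative_change_of_means": relative_change(
                        row[name], base[name]
                    ),
                }
            )
    return pd.DataFrame(rows)


def plot_tradeoffs(summary: pd.DataFrame, path: str) -> None:
    """Simple grouped bar chart of mean relative changes per stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = summary["stratum"].unique()
    fig, axes = plt.subplots(
        1, len(strata), figsize=(6 * len(strata), 4), squeeze=False
    )
    for ax, stratum in zip(axes[0], strata):
        sub = summary[summary["stratum"] == stratum]
        pivot = sub.pivot_table(
            index="indicator", columns="system", values="mean_relative_change"
        )
        pivot.plot.bar(ax=ax, legend=True)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_ylabel("relative change vs single aman (%)")
        ax.set_title(stratum)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
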