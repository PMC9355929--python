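"""One-way ANOVA with Tukey-Kramer mean separation and report assembly.

Group (least-squares) means per cropping system with 95% CIs based on the
pooled error mean square, an F-test, Tukey-Kramer pairwise comparisons for
the unbalanced design, and a compact letter display (groups sharing a
letter are not significantly different at alpha).  In a one-way layout the
LS means equal the arithmetic group means; the per-group sample size
enters through the standard error.
"""
from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .indicators import SEVEN_INDICATORS


@dataclass
class AnovaResult:
    f_value: float
    p_value: float
    df_between: int
    df_error: int
    mse: float
    groups: pd.DataFrame          # n, mean, ci_low, ci_high, letters
    pairwise: pd.DataFrame        # group1, group2, diff, q, p, significant
    alpha: float
    dropped: list[str]


def _compact_letters(
    order: list[str], nonsig_pairs: set[frozenset]
) -> dict[str, str]:
    """Compact letter display from the non-significance graph.

    Letters are maximal cliques of the graph whose vertices are groups and
    whose edges join pairs that are *not* significantly different, lettered
    in order of the best group they contain.  Guarantees: two groups share
    a letter iff their pair is non-significant.
    """
    n = len(order)
    cliques: list[tuple[str, ...]] = []
    # Exhaustive maximal-clique search; group counts here are tiny (<= 6).
    for size in range(n, 0, -1):
        for combo in itertools.combinations(order, size):
            if any(set(combo) <= set(c) for c in cliques):
                continue
            if all(
                frozenset(pair) in nonsig_pairs
                for pair in itertools.combinations(combo, 2)
            ):
                cliques.append(combo)
    # Letter cliques by the position of their best-ranked member.
    cliques.sort(key=lambda c: min(order.index(g) for g in c))
    letters: dict[str, str] = {g: "" for g in order}
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for letter, clique in zip(alphabet, cliques):
        for g in clique:
            letters[g] += letter
    return letters


def anova_tukey(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    alpha: float = 0.05,
    confidence: float = 0.95,
) -> AnovaResult:
    """One-way fixed-effects ANOVA with Tukey-Kramer letters.

    Masked (NaN) values are dropped; groups left with fewer than two
    observations are dropped with a warning.  CIs are
    ``mean +- t(1-(1-confidence)/2, df_error) * sqrt(MSE / n_g)``.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(groups)})
    df = df.dropna(subset=["value"])
    sizes = df.groupby("group").size()
    dropped = sorted(str(g) for g in sizes.index[sizes < 2])
    if dropped:
        warnings.warn(f"dropping groups with < 2 observations: {dropped}")
        df = df[~df["group"].isin(dropped)]
    labels = sorted(df["group"].unique(), key=str)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups with >= 2 observations")
    arrays = [df.loc[df["group"] == g, "value"].to_numpy() for g in labels]
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    n_total = int(ns.sum())
    grand = df["value"].mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_between = k - 1
    df_error = n_total - k
    mse = ss_within / df_error
    if mse == 0:
        f_value = np.inf if ss_between > 0 else 0.0
        p_value = 0.0 if ss_between > 0 else 1.0
    else:
        f_value = (ss_between / df_between) / mse
        p_value = float(sps.f.sf(f_value, df_between, df_error))

    # Tukey-Kramer pairwise comparisons (studentized range, unequal n).
    pair_rows = []
    nonsig = set()
    for (i, gi), (j, gj) in itertools.combinations(enumerate(labels), 2):
        diff = means[i] - means[j]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0:
            q = np.inf if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_error))
        significant = p < alpha
        if not significant:
            nonsig.add(frozenset((str(gi), str(gj))))
        pair_rows.append(
            {
                "group1": str(gi),
                "group2": str(gj),
                "diff": diff,
                "q": q,
                "p": p,
                "significant": significant,
            }
        )
    order = [str(g) for _, g in sorted(zip(-means, labels))]
    letters = _compact_letters(order, nonsig)

    tcrit = sps.t.ppf(0.5 + confidence / 2.0, df_error)
    half = tcrit * np.sqrt(mse / ns)
    group_table = pd.DataFrame(
        {
            "group": [str(g) for g in labels],
            "n": ns,
            "mean": means,
            "ci_low": means - half,
            "ci_high": means + half,
            "letters": [letters[str(g)] for g in labels],
        }
    )
    return AnovaResult(
        f_value=float(f_value),
        p_value=p_value,
        df_between=df_between,
        df_error=df_error,
        mse=mse,
        groups=group_table,
        pairwise=pd.DataFrame(pair_rows),
        alpha=alpha,
        dropped=dropped,
    )


# -- report assembly ------------------------------------------------------

def prevalence_percent(count: int, total: int) -> float:
    """Share of households practicing a system, one-decimal percent."""
    if total <= 0:
        raise ValueError("total must be > 0")
    return round(count / total * 100.0, 1)


def format_prevalence(count: int, total: int) -> str:
    """``"276 (92.9)"``-style count-and-percent cell."""
    return f"{count} ({prevalence_percent(count, total):.1f})"


def prevalence_table(survey: pd.DataFrame) -> pd.DataFrame:
    """System prevalence per stratum (count of households and % of total)."""
    obs = survey[["household_id", "stratum", "system"]].drop_duplicates()
    totals = obs.groupby("stratum")["household_id"].nunique()
    rows = []
    for (stratum, system), group in obs.groupby(["stratum", "system"]):
        count = group["household_id"].nunique()
        total = int(totals[stratum])
        rows.append(
            {
                "stratum": stratum,
                "system": system,
                "households": count,
                "total": total,
                "percent": prevalence_percent(count, total),
                "formatted": format_prevalence(count, total),
            }
        )
    return pd.DataFrame(rows)


def indicator_anova_table(
    indicators: pd.DataFrame,
    indicator_names: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group means, CIs, letters and F per stratum x indicator."""
    names = indicator_names or SEVEN_INDICATORS
    rows = []
    for stratum, sub in indicators.groupby("stratum"):
        for name in names:
            try:
                res = anova_tukey(sub[name], sub["system"], alpha=alpha)
            except ValueError:
                continue
            for rec in res.groups.to_dict("records"):
                rows.append(
                    {
                        "stratum": stratum,
                        "indicator": name,
                        "system": rec["group"],
                        "n": rec["n"],
                        "mean": rec["mean"],
                        "ci_low": rec["ci_low"],
                        "ci_high": rec["ci_high"],
                        "letters": rec["letters"],
                        "f_value": res.f_value,
                        "p_value": res.p_value,
                    }
                )
    return pd.DataFrame(rows)


def assemble_report(
    out_dir: str | Path,
    survey: pd.DataFrame | None = None,
    indicators: pd.DataFrame | None = None,
    tradeoff_summary: pd.DataFrame | None = None,
    index_models: dict | None = None,
    index_scores: pd.DataFrame | None = None,
    scope_summary: pd.DataFrame | None = None,
    metadata: dict | None = None,
) -> dict:
    """Write the report bundle (CSV tables + JSON summary).

    Missing stages are reported as explicit gaps rather than errors.
    """
    from .io import write_table  # local import to avoid cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"tables": {}, "gaps": [], "metadata": metadata or {}}

    def emit(name: str, table: pd.DataFrame | None):
        if table is None:
            summary["gaps"].append(name)
            return
        write_table(table, out_dir / f"{name}.csv", metadata=metadata)
        summary["tables"][name] = len(table)

    emit("prevalence", prevalence_table(survey) if survey is not None else None)
    emit(
        "indicator_groups",
        indicator_anova_table(indicators) if indicators is not None else None,
    )
    emit("tradeoffs", tradeoff_summary)
    emit("scope", scope_summary)
    emit("index_scores", index_scores)
    if index_models:
        loadings = pd.concat(
            {
                stratum: model.loadings.assign(
                    kmo_overall=model.kmo_overall,
                    proportion_variance=model.proportion_variance[0],
                    rmsr=model.rmsr,
                )
                for stratum, model in index_models.items()
            },
            names=["stratum", "indicator"],
        ).reset_index()
        emit("index_loadings", loadings)
    else:
        summary["gaps"].append("index_loadings")
    (out_dir / "report.json").write_text(json.dumps(summary, indent=2))
    return summary
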