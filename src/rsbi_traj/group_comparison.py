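"""Table-one machinery: omnibus tests across trajectory clusters.

Categorical variables are compared with the Pearson chi-square test (no
continuity correction — standard for r x c tables) and reported as
"n (%)".  Numeric variables are first screened for normality per group
(Shapiro-Wilk); if every group looks normal a one-way ANOVA is used and the
summary is mean +/- SD, otherwise the tie-corrected Kruskal-Wallis rank-sum
test with a median (Q1, Q3) summary.  Quartiles use linear interpolation
(the numpy default).  P-values render to three decimals, "<0.001" below.
No multiple-testing adjustment is applied.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "chi_square_test",
    "numeric_comparison",
    "comparison_report",
    "ComparisonRow",
    "format_p",
    "render_markdown",
]


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c table of non-negative integer counts.

    No continuity correction; df = (r-1)(c-1); p from the upper chi-square
    tail.  A zero row or column marginal is rejected with the offending
    index named.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    row_m = t.sum(axis=1)
    col_m = t.sum(axis=0)
    for i, m in enumerate(row_m):
        if m == 0:
            raise ValueError(f"degenerate table: row {i} has zero marginal")
    for j, m in enumerate(col_m):
        if m == 0:
            raise ValueError(f"degenerate table: column {j} has zero marginal")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


@dataclasses.dataclass
class ComparisonRow:
    """One rendered row of the group-comparison report."""

    variable: str
    var_type: str  # "categorical" | "numeric"
    test: str  # "chi-square" | "ANOVA" | "Kruskal-Wallis" | "degenerate"
    statistic: float
    p: float
    summaries: dict[str, str]  # per-group (and "overall") display strings
    note: str = ""


def _median_q1q3(x: np.ndarray) -> str:
    med = np.median(x)
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation (type 7)
    return f"{med:.2f} ({q1:.2f}, {q3:.2f})"


def _mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


def numeric_comparison(
    groups: Mapping[str, Sequence[float]],
    variable: str = "",
    alpha_normality: float = 0.05,
    route: str = "auto",
) -> ComparisonRow:
    """Normality-routed omnibus comparison of a numeric variable.

    Shapiro-Wilk per group at ``alpha_normality``; if every group passes,
    one-way ANOVA with mean +/- SD summaries, else Kruskal-Wallis with
    median (Q1, Q3) summaries.  ``route`` can force ``"anova"`` or
    ``"kruskal"`` regardless of the normality screen.  Groups with fewer
    than 3 values cannot be normality-tested and route the variable to
    Kruskal-Wallis with a warning.  A variable constant everywhere is
    reported as degenerate with p = 1 rather than crashing.
    """
    if route not in ("auto", "anova", "kruskal"):
        raise ValueError(f"route must be auto|anova|kruskal, got {route!r}")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    arrs = {k: a[~np.isnan(a)] for k, a in arrs.items()}
    arrs = {k: a for k, a in arrs.items() if len(a) > 0}
    if len(arrs) < 2:
        raise ValueError("need >=2 non-empty groups")

    pooled = np.concatenate(list(arrs.values()))
    if np.ptp(pooled) == 0:
        return ComparisonRow(
            variable, "numeric", "degenerate", 0.0, 1.0,
            {k: _median_q1q3(a) for k, a in arrs.items()},
            note="constant in all groups",
        )

    note = ""
    all_normal = route != "kruskal"
    for k, a in (arrs.items() if route == "auto" else {}.items()):
        if len(a) < 3:
            warnings.warn(
                f"{variable or 'variable'}: group {k!r} has <3 values; "
                "routing to Kruskal-Wallis"
            )
            note = f"group {k} too small for normality test"
            all_normal = False
            break
        if np.ptp(a) == 0:  # Shapiro undefined for constant input
            all_normal = False
            break
        if stats.shapiro(a).pvalue < alpha_normality:
            all_normal = False
            break

    if all_normal:
        stat, p = stats.f_oneway(*arrs.values())
        summaries = {k: _mean_sd(a) for k, a in arrs.items()}
        summaries["overall"] = _mean_sd(pooled)
        test = "ANOVA"
    else:
        try:
            stat, p = stats.kruskal(*arrs.values())
        except ValueError:  # all numbers identical within the used groups
            stat, p = 0.0, 1.0
        summaries = {k: _median_q1q3(a) for k, a in arrs.items()}
        summaries["overall"] = _median_q1q3(pooled)
        test = "Kruskal-Wallis"
    return ComparisonRow(
        variable, "numeric", test, float(stat), float(p), summaries, note
    )


def _categorical_row(
    values: pd.Series, assignments: pd.Series, variable: str
) -> ComparisonRow:
    clusters = sorted(assignments.unique())
    cats = sorted(values.dropna().unique())
    counts = np.zeros((len(cats), len(clusters)))
    for j, cl in enumerate(clusters):
        sub = values[assignments == cl]
        for i, cat in enumerate(cats):
            counts[i, j] = (sub == cat).sum()
    if counts.shape[0] < 2:
        return ComparisonRow(
            variable, "categorical", "degenerate", 0.0, 1.0,
            {cl: f"{int(counts[0, j])} (100)" for j, cl in enumerate(clusters)},
            note="single category",
        )
    stat, df, p = chi_square_test(counts)
    summaries = {}
    for j, cl in enumerate(clusters):
        n = counts[:, j].sum()
        parts = [
            f"{cat}: {int(c)} ({0 if n == 0 else round(100 * c / n):.0f}%)"
            for cat, c in zip(cats, counts[:, j])
        ]
        summaries[cl] = "; ".join(parts)
    return ComparisonRow(variable, "categorical", "chi-square", stat, p, summaries)


def comparison_report(
    covariates: pd.DataFrame,
    assignments: pd.Series,
    manifest: Mapping[str, str],
    outcomes: pd.DataFrame | None = None,
) -> tuple[list[ComparisonRow], list[str]]:
    """One comparison row per manifest variable, plus skipped variables.

    ``manifest`` maps variable name -> "categorical" | "numeric".  Variables
    are looked up in ``covariates`` first, then ``outcomes``; absent
    variables are listed in the skipped report instead of raising.
    """
    assignments = assignments.dropna()
    rows: list[ComparisonRow] = []
    skipped: list[str] = []
    for var, kind in manifest.items():
        if var in covariates.columns:
            vals = covariates[var]
        elif outcomes is not None and var in outcomes.columns:
            vals = outcomes[var]
        else:
            skipped.append(var)
            continue
        vals = vals.reindex(assignments.index)
        if kind == "categorical":
            rows.append(_categorical_row(vals, assignments, var))
        elif kind == "numeric":
            groups = {
                cl: vals[assignments == cl].to_numpy(dtype=float)
                for cl in sorted(assignments.unique())
            }
            rows.append(numeric_comparison(groups, variable=var))
        else:
            raise ValueError(f"manifest[{var!r}]: unknown type {kind!r}")
    return rows, skipped


def format_p(p: float) -> str:
    """Three decimals; '<0.001' below that (table-one style)."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def report_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of a comparison report."""
    recs = []
    for r in rows:
        rec = {
            "variable": r.variable,
            "type": r.var_type,
            "test": r.test,
            "statistic": r.statistic,
            "p": r.p,
            "p_display": format_p(r.p),
            "note": r.note,
        }
        rec.update({f"group_{k}": v for k, v in r.summaries.items()})
        recs.append(rec)
    return pd.DataFrame(recs)


def render_markdown(rows: Sequence[ComparisonRow]) -> str:
    """Human-readable comparison table mirroring the n (%) / median (Q1,Q3) style."""
    groups: list[str] = []
    for r in rows:
        for k in r.summaries:
            if k not in groups and k != "overall":
                groups.append(k)
    header = ["Variable"] + groups + ["Test", "p"]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "---|" * len(header)]
    for r in rows:
        cells = [r.variable]
        cells += [r.summaries.get(g, "") for g in groups]
        cells += [r.test, format_p(r.p)]
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    lines.append(
        "Footnotes: chi-square without continuity correction; quartiles by "
        "linear interpolation; ANOVA only when every group passes "
        "Shapiro-Wilk at 0.05, otherwise Kruskal-Wallis."
    )
    return "\n".join(lines)
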