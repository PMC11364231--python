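"""Stratified descriptive tables and headline summary statistics.

Reproduces the shape of the study's descriptive tables: every variable is
summarized as "% (n)" for categoricals or median [IQR] for continuous
measures, within overlapping strata (any-CHE / no-CHE plus each individual
threshold; any-IMP / no-IMP plus each poverty line). Percentages use the
full stratum size as denominator, including "unknown" responses, which are
counted but not printed as rows. Continuous variables are compared across
the binary any/none split with Welch's t-test (one-way ANOVA for k > 2
groups); categorical variables with a chi-square test of independence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ValidationError
from .toxicity import ToxicityConfig, as_bool

#: Categorical variables shown in the stratified tables (column -> title).
CATEGORICAL_VARS = {
    "sex": "Sex",
    "education": "Education",
    "region": "Region of Residence",
    "marital_status": "Marital Status",
    "occupation": "Occupation",
    "dependents_bracket": "Number of dependents in household",
    "insurance": "Insurance Status",
    "mechanism": "Mechanism of Injury",
    "hospitalized": "Requires hospitalization",
    "surgery": "Requires surgery",
}

#: Continuous variables (column -> title).
CONTINUOUS_VARS = {
    "age": "Age",
    "monthly_ae_income": "Household income (monthly adult equivalent) (TZS)",
    "oop": "Cost of hospital visit (TZS)",
}


def median_iqr(values) -> tuple[float, float]:
    """Sample median and interquartile range (Q3 - Q1, linear interpolation)."""
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size == 0:
        raise ValidationError("median_iqr requires at least one value")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return float(q2), float(q3 - q1)


def prevalence(n_true: int, denominator: int) -> float:
    """Percentage prevalence, 1 decimal place (e.g. 49 of 78 -> 62.8)."""
    if denominator <= 0:
        raise ValidationError("prevalence denominator must be positive")
    if n_true < 0 or n_true > denominator:
        raise ValidationError("count must lie in [0, denominator]")
    return round(100.0 * n_true / denominator, 1)


def ratio_of_medians(group_a, group_b) -> float:
    """median(a) / median(b), 2 decimal places."""
    med_a, _ = median_iqr(group_a)
    med_b, _ = median_iqr(group_b)
    if med_b == 0:
        raise AnalysisError("ratio_of_medians undefined: denominator median is 0")
    return round(med_a / med_b, 2)


def group_compare(values, groups) -> dict:
    """Compare a continuous variable across groups.

    Welch two-sample t-test for a binary grouping, one-way ANOVA for k > 2.
    Returns ``{"method", "statistic", "pvalue", "groups"}``.
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    samples = [g["value"].to_numpy(dtype=float) for _, g in df.groupby("group")]
    if len(samples) < 2:
        raise AnalysisError("group_compare needs at least two non-empty groups")
    if any(len(s) < 2 for s in samples):
        raise AnalysisError("every group needs at least two values")
    if len(samples) == 2:
        stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        method = "welch_t"
    else:
        stat, p = stats.f_oneway(*samples)
        method = "anova"
    return {
        "method": method,
        "statistic": float(stat),
        "pvalue": float(p),
        "groups": len(samples),
    }


def categorical_compare(labels, groups) -> dict:
    """Chi-square test of independence on the labels x groups contingency
    table (unknowns dropped from the test, kept in table denominators)."""
    df = pd.DataFrame({"label": labels, "group": groups}).dropna()
    table = pd.crosstab(df["label"], df["group"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise AnalysisError("chi-square needs a 2x2 or larger table")
    chi2, p, dof, _ = stats.chi2_contingency(table)
    return {"method": "chi2", "statistic": float(chi2), "pvalue": float(p), "dof": dof}


def p_stars(p: float) -> str:
    """Significance footnote convention: p<0.05*; p<0.01**; p<0.001***."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _strata_definitions(
    results: pd.DataFrame, stratifier: str, config: ToxicityConfig
) -> dict[str, pd.Series]:
    if stratifier == "che":
        strata = {"any_che": results["any_che"], "no_che": ~results["any_che"]}
        for label in config.che_labels:
            strata[label] = results[label]
    elif stratifier == "imp":
        eligible = ~results["imp_excluded"]
        any_imp = as_bool(results["any_imp"])
        strata = {"any_imp": any_imp & eligible, "no_imp": (~any_imp) & eligible}
        for label in config.imp_labels:
            strata[label] = as_bool(results[label]) & eligible
    else:
        raise ValidationError(f"unknown stratifier {stratifier!r} (use 'che'|'imp')")
    return strata


def attach_analysis_columns(
    cohort: pd.DataFrame, results: pd.DataFrame
) -> pd.DataFrame:
    """Join cohort covariates to toxicity results and derive the analysis
    variables (monthly adult-equivalent income, OOP)."""
    merged = cohort.merge(results, on="patient_id", validate="one_to_one")
    merged["monthly_ae_income"] = merged["annual_income"] / merged["h_a"] / 12.0
    return merged


def build_stratified_table(
    cohort: pd.DataFrame,
    results: pd.DataFrame,
    stratifier: str,
    config: ToxicityConfig | None = None,
) -> pd.DataFrame:
    """Long-format stratified table: one row per (variable, category, stratum).

    ``cohort`` is the merged encounters+households covariate table;
    ``results`` the output of :func:`fintox.toxicity.toxicity_table`.
    Income-missing patients are excluded from IMP strata. P-values compare
    the any-vs-none split only (the per-threshold strata overlap and are
    not independent).
    """
    config = config or ToxicityConfig()
    data = attach_analysis_columns(cohort, results)
    strata = _strata_definitions(data, stratifier, config)
    rows = []
    any_key, none_key = list(strata)[0], list(strata)[1]
    split = pd.Series(
        np.where(strata[any_key], "any", np.where(strata[none_key], "none", None)),
        index=data.index,
    )
    for col, title in CATEGORICAL_VARS.items():
        values = data[col].astype(str).str.lower()
        try:
            test = categorical_compare(
                values.where(values != "unknown"), split
            )
        except AnalysisError:
            test = {"method": "chi2", "statistic": np.nan, "pvalue": np.nan}
        categories = sorted(v for v in values.unique() if v != "unknown")
        for stratum, mask in strata.items():
            denom = int(mask.sum())
            for cat in categories:
                count = int(((values == cat) & mask).sum())
                rows.append(
                    {
                        "variable": title,
                        "category": cat,
                        "stratum": stratum,
                        "n": count,
                        "value": prevalence(count, denom) if denom else np.nan,
                        "kind": "percent",
                        "pvalue": test["pvalue"],
                        "method": test["method"],
                    }
                )
    for col, title in CONTINUOUS_VARS.items():
        try:
            test = group_compare(data[col], split)
        except AnalysisError:
            test = {"method": "welch_t", "statistic": np.nan, "pvalue": np.nan}
        for stratum, mask in strata.items():
            vals = data.loc[mask, col].dropna()
            if len(vals):
                med, iqr = median_iqr(vals)
            else:
                med = iqr = np.nan
            rows.append(
                {
                    "variable": title,
                    "category": "median_iqr",
                    "stratum": stratum,
                    "n": int(len(vals)),
                    "value": med,
                    "kind": "median",
                    "iqr": iqr,
                    "pvalue": test["pvalue"],
                    "method": test["method"],
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["stratum_sizes"] = {k: int(v.sum()) for k, v in strata.items()}
    return table


def overall_table(cohort: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    """Whole-sample descriptives (the unstratified Table-1 shape)."""
    data = attach_analysis_columns(cohort, results)
    n = len(data)
    rows = []
    for col, title in CATEGORICAL_VARS.items():
        values = data[col].astype(str).str.lower()
        for cat in sorted(v for v in values.unique() if v != "unknown"):
            count = int((values == cat).sum())
            rows.append(
                {
                    "variable": title,
                    "category": cat,
                    "n": count,
                    "value": prevalence(count, n),
                    "kind": "percent",
                }
            )
    for col, title in CONTINUOUS_VARS.items():
        med, iqr = median_iqr(data[col])
        rows.append(
            {
                "variable": title,
                "category": "median_iqr",
                "n": int(data[col].notna().sum()),
                "value": med,
                "iqr": iqr,
                "kind": "median",
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["n"] = n
    return table


def render_markdown_table(table: pd.DataFrame, title: str) -> str:
    """Markdown rendering of a (stratified) descriptive table."""
    lines = [f"### {title}", ""]
    sizes = table.attrs.get("stratum_sizes")
    if sizes:
        lines.append(
            "Strata: " + ", ".join(f"{k} (n={v})" for k, v in sizes.items())
        )
        lines.append("")
    has_stratum = "stratum" in table.columns
    header = ["Variable", "Category"]
    strata = list(table["stratum"].unique()) if has_stratum else ["overall"]
    header += strata
    if "pvalue" in table.columns:
        header.append("p-value")
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    group_cols = ["variable", "category"]
    for (var, cat), grp in table.groupby(group_cols, sort=False):
        cells = [var, str(cat)]
        for stratum in strata:
            sub = grp[grp["stratum"] == stratum] if has_stratum else grp
            if sub.empty:
                cells.append("")
                continue
            r = sub.iloc[0]
            if r["kind"] == "percent":
                cells.append(f"{r['value']:.1f} ({int(r['n'])})")
            else:
                cells.append(f"{r['value']:,.1f} [{r['iqr']:,.1f}]")
        if "pvalue" in table.columns:
            p = grp["pvalue"].iloc[0]
            cells.append("" if pd.isna(p) else f"{p:.3g}{p_stars(p)}")
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")
    lines.append(
        "All values are % (n) for categoricals and median [IQR] otherwise; "
        "unknown responses are included in percentage denominators. "
        "p<0.05\\*; p<0.01\\*\\*; p<0.001\\*\\*\\*"
    )
    return "\n".join(lines)
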