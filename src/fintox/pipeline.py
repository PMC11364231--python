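"""End-to-end run: costing -> toxicity -> stratified tables -> delays panel.

One entry point wires the stages together, writes every intermediate table,
and produces a machine-readable ``metrics.json`` plus a human-readable
markdown report whose numbers are read back from the metrics file (nothing
is recomputed at render time). Identical inputs and seed give a
byte-identical bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort_analysis as ca
from .costing import convert_tzs_to_usd, cost_cohort, load_fee_schedule
from .delays_model import delays_summary, profiles_frame, render_delays_panel
from .errors import ValidationError
from .toxicity import (
    CheThreshold,
    PovertyLine,
    ToxicityConfig,
    as_bool,
    toxicity_table,
)

log = logging.getLogger("fintox")


@dataclass
class RunConfig:
    """Paths and options for one pipeline run."""

    households: Path
    encounters: Path
    services: Path
    schedule: Path
    outdir: Path
    toxicity: ToxicityConfig = field(default_factory=ToxicityConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("households", "encounters", "services", "schedule"):
            path = Path(getattr(self, name))
            setattr(self, name, path)
            if not path.exists():
                raise ValidationError(f"{name} file not found: {path}")
        self.outdir = Path(self.outdir)


def toxicity_config_from_mapping(cfg: dict) -> ToxicityConfig:
    """Build a ToxicityConfig from a parsed YAML/JSON mapping."""
    kwargs: dict = {}
    if "thresholds" in cfg:
        kwargs["thresholds"] = tuple(
            CheThreshold(float(t["fraction"]), str(t["base"])) for t in cfg["thresholds"]
        )
    if "poverty_lines" in cfg:
        kwargs["poverty_lines"] = tuple(
            PovertyLine(
                str(l["label"]), float(l["amount"]), str(l["currency"]), str(l["period"])
            )
            for l in cfg["poverty_lines"]
        )
    for key in ("tzs_per_usd", "comparison", "imp_mode", "se_per_adult_equivalent"):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "percentile_window" in cfg:
        kwargs["percentile_window"] = tuple(cfg["percentile_window"])
    return ToxicityConfig(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration (paths + toxicity options)."""
    raw = yaml.safe_load(Path(path).read_text())
    tox = toxicity_config_from_mapping(raw.get("toxicity", {}))
    return RunConfig(
        households=raw["households"],
        encounters=raw["encounters"],
        services=raw["services"],
        schedule=raw["schedule"],
        outdir=raw.get("outdir", "fintox_out"),
        toxicity=tox,
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def compute_metrics(
    cohort: pd.DataFrame,
    results: pd.DataFrame,
    delays: dict[str, pd.DataFrame],
    rate: float,
) -> dict:
    """Headline quantities: prevalences (both IMP denominators), USD
    conversions, income/cost median ratios between toxic and non-toxic
    strata, and audit counts."""
    data = ca.attach_analysis_columns(cohort, results)
    n = len(data)
    n_income_missing = int(data["imp_excluded"].sum())
    n_imp_eligible = n - n_income_missing
    any_che = int(data["any_che"].sum())
    any_imp = int(as_bool(data["any_imp"]).sum())

    med_oop, iqr_oop = ca.median_iqr(data["oop"])
    med_inc, iqr_inc = ca.median_iqr(data["monthly_ae_income"])

    che_mask = data["any_che"].astype(bool)
    imp_mask = as_bool(data["any_imp"]) & ~data["imp_excluded"]
    noimp_mask = ~as_bool(data["any_imp"], missing=True) & ~data["imp_excluded"]

    def safe_ratio(a, b):
        try:
            return ca.ratio_of_medians(a, b)
        except Exception:
            return None

    metrics = {
        "n_patients": n,
        "n_income_missing": n_income_missing,
        "any_che_count": any_che,
        "any_che_pct": ca.prevalence(any_che, n),
        "any_imp_count": any_imp,
        "any_imp_pct_full_denominator": ca.prevalence(any_imp, n),
        "any_imp_pct_eligible_denominator": (
            ca.prevalence(any_imp, n_imp_eligible) if n_imp_eligible else None
        ),
        "che_flag_counts": {
            c: int(data[c].sum()) for c in results.columns if c.startswith("che_")
        },
        "imp_flag_counts": {
            c: int(as_bool(data[c]).sum())
            for c in results.columns
            if c.startswith("imp_") and c != "imp_excluded"
        },
        "median_oop_tzs": round(med_oop, 1),
        "median_oop_iqr_tzs": round(iqr_oop, 1),
        "median_oop_usd": convert_tzs_to_usd(med_oop, rate, rounded=True),
        "median_monthly_ae_income_tzs": round(med_inc, 1),
        "median_monthly_ae_income_iqr_tzs": round(iqr_inc, 1),
        "median_monthly_ae_income_usd": convert_tzs_to_usd(med_inc, rate, rounded=True),
        "income_ratio_nonche_vs_che": safe_ratio(
            data.loc[~che_mask, "monthly_ae_income"],
            data.loc[che_mask, "monthly_ae_income"],
        ),
        "income_ratio_nonimp_vs_imp": safe_ratio(
            data.loc[noimp_mask, "monthly_ae_income"],
            data.loc[imp_mask, "monthly_ae_income"],
        ),
        "cost_ratio_che_vs_nonche": safe_ratio(
            data.loc[che_mask, "oop"], data.loc[~che_mask, "oop"]
        ),
        "cost_ratio_imp_vs_nonimp": safe_ratio(
            data.loc[imp_mask, "oop"], data.loc[noimp_mask, "oop"]
        ),
        "subsistence_expenditure_tzs": round(
            float(results.attrs.get("subsistence_expenditure", float("nan"))), 1
        ),
        "tzs_per_usd": rate,
        "delays": {
            strat: {
                "median_oop_ratio": summary.attrs.get("median_oop_ratio"),
                "stratum_sizes": dict(
                    zip(summary["stratum"], summary["n"].astype(int))
                ),
            }
            for strat, summary in delays.items()
        },
    }
    return metrics


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.outdir``.

    Returns the bundle as a dict of in-memory objects (tables, metrics,
    report text) mirroring the files written.
    """
    logging.basicConfig(level=config.log_level)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        schedule = load_fee_schedule(config.schedule)
        households = pd.read_csv(config.households)
        encounters = pd.read_csv(config.encounters)
        services = pd.read_csv(config.services)
        log.info(
            "loaded %d patients, %d service rows, %d fee items",
            len(encounters), len(services), len(schedule),
        )

        stage = "costing"
        costs = cost_cohort(schedule, encounters, services)

        stage = "toxicity"
        results = toxicity_table(households, costs, config.toxicity)
        log.info(
            "classified %d patients (%d excluded from IMP for missing income)",
            len(results), int(results["imp_excluded"].sum()),
        )

        stage = "tables"
        cohort = encounters.merge(households, on="patient_id", validate="one_to_one")
        table1 = ca.overall_table(cohort, results)
        table2 = ca.build_stratified_table(cohort, results, "che", config.toxicity)
        table3 = ca.build_stratified_table(cohort, results, "imp", config.toxicity)

        stage = "delays"
        profiles = profiles_frame(encounters)
        delays = {
            strat: delays_summary(profiles, results, strat, config.toxicity)
            for strat in ("che", "imp")
        }

        stage = "metrics"
        metrics = compute_metrics(cohort, results, delays, config.toxicity.tzs_per_usd)
        metrics["seed"] = config.seed
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    costs.to_csv(outdir / "costs.csv", index=False)
    results.to_csv(outdir / "toxicity.csv", index=False)
    table1.to_csv(outdir / "table1_overall.csv", index=False)
    table2.to_csv(outdir / "table2_che.csv", index=False)
    table3.to_csv(outdir / "table3_imp.csv", index=False)
    for strat, summary in delays.items():
        summary.to_csv(outdir / f"delays_{strat}.csv", index=False)
    (outdir / "metrics.json").write_text(
        json.dumps(metrics, indent=2, sort_keys=True) + "\n"
    )

    bundle = {
        "costs": costs,
        "results": results,
        "table1": table1,
        "table2": table2,
        "table3": table3,
        "delays": delays,
        "metrics": metrics,
    }
    report = render_report(bundle)
    (outdir / "report.md").write_text(report)
    bundle["report"] = report
    return bundle


def render_report(bundle: dict) -> str:
    """Markdown report: headline sentence, the three tables, delays panel.

    Every number is read from the bundle's metrics dict; a partial bundle
    lists its missing sections instead of failing.
    """
    required = ("metrics", "table1", "table2", "table3", "delays")
    missing = [k for k in required if k not in bundle]
    if missing:
        return (
            "# Financial toxicity report (incomplete)\n\n"
            f"Missing sections: {', '.join(missing)}\n"
        )
    m = bundle["metrics"]
    lines = ["# Financial toxicity of acute injury care", ""]
    if m["n_patients"] == 0:
        lines.append("**n=0 patients — nothing to report.**")
        return "\n".join(lines)
    lines.append(
        f"Of {m['n_patients']} patients, {m['any_che_pct']}% "
        f"(n = {m['any_che_count']}) experienced some form of catastrophic "
        f"health expenditure and {m['any_imp_pct_full_denominator']}% "
        f"(n = {m['any_imp_count']}) an impoverishing expense. The median "
        f"out-of-pocket cost was {m['median_oop_tzs']:,} TZS "
        f"(${m['median_oop_usd']:.0f} USD) against a median monthly "
        f"adult-equivalent household income of "
        f"{m['median_monthly_ae_income_tzs']:,} TZS "
        f"(${m['median_monthly_ae_income_usd']:.0f} USD)."
    )
    lines.append("")
    if m["income_ratio_nonche_vs_che"] is not None:
        lines.append(
            f"Median monthly adult-equivalent income was "
            f"{m['income_ratio_nonche_vs_che']} times smaller in households "
            f"with catastrophic expenditure than without; "
            f"{m['income_ratio_nonimp_vs_imp']} times smaller with "
            f"impoverishment than without."
        )
        lines.append("")
    lines.append(ca.render_markdown_table(bundle["table1"], "Overall sample"))
    lines.append("")
    lines.append(
        ca.render_markdown_table(bundle["table2"], "Stratified by CHE status")
    )
    lines.append("")
    lines.append(
        ca.render_markdown_table(bundle["table3"], "Stratified by IMP status")
    )
    lines.append("")
    lines.append(render_delays_panel(bundle["delays"]))
    lines.append("")
    return "\n".join(lines)
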