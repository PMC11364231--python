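"""Catastrophic health expenditure (CHE) and impoverishment (IMP) classification.

WHO-style financial-protection indicators applied per patient:

* **CHE** — out-of-pocket (OOP) spending at or above a fraction of the
  household's annual total expenditure (``x = 0.10`` or ``0.25`` of TE) or of
  its non-subsistence expenditure (``x = 0.40`` of NSE). A patient crossing
  any one threshold has experienced a catastrophic health expense.
* **IMP** — post-OOP per-adult-equivalent income below a poverty line
  (Tanzanian national line of 49,320 TZS/month, or the $1.90 and $3.20
  per-person-per-day international lines). Crossing any line counts as an
  impoverishing expense.

Subsistence expenditure (SE) is the mean annual food spending of the
households in the 45th–55th percentiles of consumption (ranked by total
expenditure); NSE = max(TE - SE, 0). Household size is converted to adult
equivalents with the OECD-modified scale (1 / 0.5 / 0.3 for the first adult,
each further adult, and each child under 14).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import JoinError, ValidationError

DEFAULT_TZS_PER_USD = 2339.0

#: Days per year and months per year used to annualize poverty lines.
DAYS_PER_YEAR = 365
MONTHS_PER_YEAR = 12


@dataclass(frozen=True)
class Household:
    """Household finances and composition for one patient.

    Money fields are annual TZS; ``annual_income`` may be NaN when the
    respondent declined (``income_missing``), which excludes the patient from
    impoverishment classification but not from the cohort.
    """

    n_adults: int
    n_children: int
    annual_income: float
    annual_total_expenditure: float
    annual_food_expenditure: float
    income_missing: bool = False
    n_dependents: int | None = None

    def __post_init__(self) -> None:
        if self.n_adults < 1:
            raise ValidationError("household must contain at least one adult")
        if self.n_children < 0:
            raise ValidationError("n_children must be non-negative")
        if self.annual_total_expenditure < 0 or self.annual_food_expenditure < 0:
            raise ValidationError("expenditures must be non-negative")
        if self.annual_food_expenditure > self.annual_total_expenditure:
            raise ValidationError(
                "food expenditure cannot exceed total expenditure"
            )
        if not self.income_missing and (
            np.isnan(self.annual_income) or self.annual_income < 0
        ):
            raise ValidationError("annual income must be non-negative when present")


@dataclass(frozen=True)
class CheThreshold:
    """One CHE rule: OOP vs ``fraction`` of base ``TE`` or ``NSE``."""

    fraction: float
    base: str  # "TE" | "NSE"

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValidationError("CHE threshold fraction must be in (0, 1)")
        if self.base not in ("TE", "NSE"):
            raise ValidationError("CHE threshold base must be 'TE' or 'NSE'")

    @property
    def label(self) -> str:
        return f"che_{round(self.fraction * 100):d}_{self.base.lower()}"


@dataclass(frozen=True)
class PovertyLine:
    """A poverty line in its native currency and period."""

    label: str
    amount: float
    currency: str  # "TZS" | "USD"
    period: str  # "per_month" | "per_day" (per person)

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValidationError("poverty line amount must be non-negative")
        if self.currency not in ("TZS", "USD"):
            raise ValidationError(f"unknown currency {self.currency!r}")
        if self.period not in ("per_month", "per_day"):
            raise ValidationError(f"unknown period {self.period!r}")


def default_che_thresholds() -> tuple[CheThreshold, ...]:
    return (
        CheThreshold(0.10, "TE"),
        CheThreshold(0.25, "TE"),
        CheThreshold(0.40, "NSE"),
    )


def default_poverty_lines() -> tuple[PovertyLine, ...]:
    return (
        PovertyLine("national", 49_320.0, "TZS", "per_month"),
        PovertyLine("usd190", 1.90, "USD", "per_day"),
        PovertyLine("usd320", 3.20, "USD", "per_day"),
    )


@dataclass(frozen=True)
class ToxicityConfig:
    """Thresholds, poverty lines and conventions for classification."""

    thresholds: tuple[CheThreshold, ...] = field(
        default_factory=default_che_thresholds
    )
    poverty_lines: tuple[PovertyLine, ...] = field(
        default_factory=default_poverty_lines
    )
    tzs_per_usd: float = DEFAULT_TZS_PER_USD
    comparison: str = "ge"  # "ge" (table convention) or "gt"
    imp_mode: str = "absolute"  # "absolute" | "newly_poor"
    percentile_window: tuple[float, float] = (45.0, 55.0)
    se_per_adult_equivalent: bool = False

    def __post_init__(self) -> None:
        if self.comparison not in ("ge", "gt"):
            raise ValidationError("comparison must be 'ge' or 'gt'")
        if self.imp_mode not in ("absolute", "newly_poor"):
            raise ValidationError("imp_mode must be 'absolute' or 'newly_poor'")
        if self.tzs_per_usd <= 0:
            raise ValidationError("tzs_per_usd must be positive")
        lo, hi = self.percentile_window
        if not 0 <= lo <= hi <= 100:
            raise ValidationError("percentile window must satisfy 0<=lo<=hi<=100")

    @property
    def che_labels(self) -> list[str]:
        return [t.label for t in self.thresholds]

    @property
    def imp_labels(self) -> list[str]:
        return [f"imp_{l.label}" for l in self.poverty_lines]



def as_bool(series: pd.Series, missing: bool = False) -> pd.Series:
    """Nullable flag column -> plain bool, mapping NA to ``missing``."""
    return series.map(lambda v: missing if pd.isna(v) else bool(v))


def adult_equivalents(n_adults: int, n_children: int) -> float:
    """OECD-modified household size: 1 + 0.5*(adults-1) + 0.3*children."""
    if n_adults < 1:
        raise ValidationError("adult_equivalents requires at least one adult")
    if n_children < 0:
        raise ValidationError("n_children must be non-negative")
    return 1.0 + 0.5 * (n_adults - 1) + 0.3 * n_children


def subsistence_expenditure(
    households: pd.DataFrame,
    window: tuple[float, float] = (45.0, 55.0),
    per_adult_equivalent: bool = False,
) -> float:
    """Mean annual food spending of households in the consumption window.

    Households are ranked by annual total expenditure (stable order for
    ties); the percentile rank of the i-th of n is ``100*(i - 0.5)/n`` and
    the closed window ``[lo, hi]`` selects the middle-consumption households.
    If the window is empty the household nearest the median is used, so the
    estimate is defined for any non-empty cohort.

    With ``per_adult_equivalent`` the food spending of each selected
    household is first divided by its OECD-modified size (off by default:
    subsistence is a per-household amount).
    """
    required = {"annual_total_expenditure", "annual_food_expenditure"}
    if not required <= set(households.columns):
        raise ValidationError(f"households table needs columns {sorted(required)}")
    df = households.dropna(subset=["annual_total_expenditure"])
    n = len(df)
    if n == 0:
        raise ValidationError("subsistence_expenditure: no usable households")
    order = np.argsort(df["annual_total_expenditure"].to_numpy(), kind="stable")
    pct = 100.0 * (np.arange(1, n + 1) - 0.5) / n
    lo, hi = window
    mask = (pct >= lo) & (pct <= hi)
    if not mask.any():
        mask = np.zeros(n, dtype=bool)
        mask[np.argmin(np.abs(pct - 50.0))] = True
    selected = df.iloc[order[mask]]
    food = selected["annual_food_expenditure"].to_numpy(dtype=float)
    if per_adult_equivalent:
        ha = np.array(
            [
                adult_equivalents(int(a), int(c))
                for a, c in zip(selected["n_adults"], selected["n_children"])
            ]
        )
        food = food / ha
    return float(food.mean())


def non_subsistence_expenditure(te: float, se: float) -> float:
    """NSE = max(TE - SE, 0); capacity to pay after basic needs."""
    if te < 0 or se < 0:
        raise ValidationError("TE and SE must be non-negative")
    return max(te - se, 0.0)


def _exceeds(oop: float, cutoff: float, comparison: str) -> bool:
    if cutoff == 0.0:
        # A zero capacity-to-pay threshold is catastrophic only for actual
        # spending; zero-cost patients are never flagged.
        return oop > 0.0
    return oop >= cutoff if comparison == "ge" else oop > cutoff


def classify_che(
    oop: float,
    te: float,
    nse: float,
    config: ToxicityConfig | None = None,
) -> tuple[dict[str, bool], bool]:
    """Flag each CHE threshold and their disjunction for one patient."""
    config = config or ToxicityConfig()
    if min(oop, te, nse) < 0:
        raise ValidationError("classify_che inputs must be non-negative")
    base_value = {"TE": te, "NSE": nse}
    flags = {
        t.label: _exceeds(oop, t.fraction * base_value[t.base], config.comparison)
        for t in config.thresholds
    }
    return flags, any(flags.values())


def normalize_poverty_line(
    line: PovertyLine, tzs_per_usd: float = DEFAULT_TZS_PER_USD
) -> float:
    """Annual TZS per adult equivalent: x12 monthly lines, x365 daily lines,
    x rate for USD lines."""
    if tzs_per_usd <= 0:
        raise ValidationError("conversion rate must be positive")
    amount = line.amount
    if line.currency == "USD":
        amount *= tzs_per_usd
    if line.period == "per_month":
        return amount * MONTHS_PER_YEAR
    return amount * DAYS_PER_YEAR


def classify_imp(
    household: Household,
    oop: float,
    config: ToxicityConfig | None = None,
) -> tuple[dict[str, bool | None], bool | None]:
    """Flag each poverty line and their disjunction for one patient.

    Remaining income after OOP is floored at zero and divided by the
    OECD-modified household size before comparison with each annualized
    line. A household with missing income gets ``None`` flags (excluded
    from impoverishment, not an error). In ``newly_poor`` mode a flag also
    requires the pre-OOP per-adult-equivalent income to be at or above the
    line.
    """
    config = config or ToxicityConfig()
    if oop < 0:
        raise ValidationError("OOP must be non-negative")
    if household.income_missing:
        return {label: None for label in config.imp_labels}, None
    ha = adult_equivalents(household.n_adults, household.n_children)
    pre = household.annual_income / ha
    post = max(household.annual_income - oop, 0.0) / ha
    flags: dict[str, bool | None] = {}
    for line in config.poverty_lines:
        z = normalize_poverty_line(line, config.tzs_per_usd)
        below = post < z
        if config.imp_mode == "newly_poor":
            below = below and pre >= z
        flags[f"imp_{line.label}"] = below
    return flags, any(v for v in flags.values())


def toxicity_table(
    households: pd.DataFrame,
    costs: pd.DataFrame,
    config: ToxicityConfig | None = None,
) -> pd.DataFrame:
    """Classify every patient in a cohort.

    ``households`` needs patient_id, n_adults, n_children, annual_income,
    annual_total_expenditure, annual_food_expenditure, income_missing;
    ``costs`` needs patient_id and total_oop. Subsistence expenditure is
    estimated once from the full cohort and applied to every patient.
    Returns one row per patient with oop, te, nse, h_a, the per-threshold
    and per-line flags, any_che / any_imp, and imp_excluded.
    """
    config = config or ToxicityConfig()
    hh_ids = set(households["patient_id"].astype(str))
    cost_ids = set(costs["patient_id"].astype(str))
    if hh_ids != cost_ids:
        stray = sorted((hh_ids ^ cost_ids))[:10]
        raise JoinError(
            f"household and cost tables disagree on patient ids: {stray}"
        )
    merged = households.merge(costs[["patient_id", "total_oop"]], on="patient_id")
    se = subsistence_expenditure(
        merged,
        window=config.percentile_window,
        per_adult_equivalent=config.se_per_adult_equivalent,
    )
    rows = []
    for row in merged.itertuples(index=False):
        missing = bool(row.income_missing)
        hh = Household(
            n_adults=int(row.n_adults),
            n_children=int(row.n_children),
            annual_income=float("nan") if missing else float(row.annual_income),
            annual_total_expenditure=float(row.annual_total_expenditure),
            annual_food_expenditure=float(row.annual_food_expenditure),
            income_missing=missing,
        )
        oop = float(row.total_oop)
        te = hh.annual_total_expenditure
        nse = non_subsistence_expenditure(te, se)
        che_flags, any_che = classify_che(oop, te, nse, config)
        imp_flags, any_imp = classify_imp(hh, oop, config)
        rows.append(
            {
                "patient_id": str(row.patient_id),
                "oop": oop,
                "te": te,
                "nse": nse,
                "h_a": adult_equivalents(hh.n_adults, hh.n_children),
                **che_flags,
                "any_che": any_che,
                **imp_flags,
                "any_imp": any_imp,
                "imp_excluded": missing,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["subsistence_expenditure"] = se
    return out
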