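"""Reproducible synthetic injury cohorts for end-to-end pipeline testing.

The study's registry data are not public, so every downstream stage is
exercised on generated cohorts whose marginals emulate the published sample:
83.3% male, 66.7% road-traffic injury, 83.3% uninsured, dependents brackets
47.4/37.2/15.4% (0-2 / 3-5 / 6+), median monthly adult-equivalent income
98,387 TZS with IQR 136,842 TZS, 80.8% hospitalized, 48.7% undergoing
surgery, 2.6% in-hospital deaths, and a median itemized OOP cost near
476,793 TZS under the bundled (synthetic) fee schedule.

Income is lognormal — the standard family for incomes — with sigma solved in
closed form from the median/IQR: IQR/median = 2*sinh(z75*sigma) where z75 is
the 75th-percentile normal quantile. Service intensity (imaging, procedures,
consumables, stay length) rises with hospitalization and surgery, inducing
the observed association between surgical burden and financial toxicity.

When ``target_any_che`` is set, each patient's cost breakdown is rescaled
(all six components by one factor, so additivity is untouched) so that
exactly ``round(target * n)`` patients cross at least one CHE threshold;
the emitted ground-truth labels are the toxicity module's classification of
the rescaled costs. In this mode the rescaled costs table — not a re-costing
of the service list — is the canonical OOP input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .costing import FeeSchedule, cost_cohort, default_fee_schedule
from .errors import GenerationError, ValidationError
from .toxicity import ToxicityConfig, adult_equivalents, toxicity_table

MECHANISMS = ("rti", "fall", "blunt", "other")
DEPENDENT_BRACKETS = ("0-2", "3-5", "6+")
EDUCATION_LEVELS = ("0-4 years", "5-10 years", "11+ years")
REGIONS = ("moshi_rural", "moshi_urban", "other")
MARITAL = ("single", "married", "partner_widowed_separated")
OCCUPATIONS = ("farmer", "self_employed", "skilled", "other")
TIME_TO_CARE = ("minutes", "hours", "longer")

_SURGICAL_CODES = (
    "surg_debridement_exfix",
    "surg_orif",
    "surg_laparotomy",
    "surg_tracheostomy",
)


def lognormal_sigma_from_iqr(median: float, iqr: float) -> float:
    """Closed-form lognormal dispersion: IQR/median = 2*sinh(z75*sigma)."""
    if median <= 0 or iqr <= 0:
        raise ValidationError("median and IQR must be positive")
    z75 = norm.ppf(0.75)
    return math.asinh(iqr / (2.0 * median)) / z75


def _norm(probs) -> "np.ndarray":
    """Exact renormalization of a near-simplex built from rounded percentages."""
    arr = np.asarray(probs, dtype=float)
    return arr / arr.sum()


@dataclass(frozen=True)
class CohortParams:
    """Generator knobs; defaults are the published sample's marginals."""

    n_patients: int = 78
    seed: int = 0
    prop_male: float = 0.833
    mechanism_probs: tuple[float, ...] = (0.667, 0.167, 0.103, 0.064)
    prop_uninsured: float = 0.833
    income_median_monthly_ae: float = 98_387.1
    income_iqr_monthly_ae: float = 136_842.1
    dependents_probs: tuple[float, ...] = (0.474, 0.372, 0.154)
    oop_median_target: float = 476_792.7
    prop_hospitalized: float = 0.808
    prop_surgery: float = 0.487
    prop_death: float = 0.026
    prop_income_missing: float = 2 / 78  # two respondents declined
    education_probs: tuple[float, ...] = (0.064, 0.564, 0.346, 0.026)  # +unknown
    region_probs: tuple[float, ...] = (0.615, 0.038, 0.346, 0.001)  # +unknown
    marital_probs: tuple[float, ...] = (0.372, 0.474, 0.154)
    occupation_probs: tuple[float, ...] = (0.359, 0.231, 0.282, 0.128)
    target_any_che: float | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for name in (
            "mechanism_probs",
            "dependents_probs",
            "education_probs",
            "region_probs",
            "marital_probs",
            "occupation_probs",
        ):
            probs = getattr(self, name)
            # slack of 5e-3 admits simplexes built from published rounded
            # percentages (e.g. 66.7/16.7/10.3/6.4 sums to 100.1); draws
            # renormalize exactly
            if abs(sum(probs) - 1.0) > 5e-3 or min(probs) < 0:
                raise ValidationError(f"{name} must be a probability simplex")
        for name in (
            "prop_male",
            "prop_uninsured",
            "prop_hospitalized",
            "prop_surgery",
            "prop_death",
            "prop_income_missing",
        ):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.target_any_che is not None and not 0 <= self.target_any_che <= 1:
            raise ValidationError("target_any_che must lie in [0, 1]")


@dataclass
class Cohort:
    """Generated cohort bundle: the three pipeline input tables plus the
    canonical costs and (optionally) ground-truth toxicity labels."""

    households: pd.DataFrame
    encounters: pd.DataFrame
    services: pd.DataFrame
    costs: pd.DataFrame
    labels: pd.DataFrame | None
    params: CohortParams


def _draw_household(rng: np.random.Generator, params: CohortParams):
    bracket = DEPENDENT_BRACKETS[
        rng.choice(len(DEPENDENT_BRACKETS), p=_norm(params.dependents_probs))
    ]
    if bracket == "0-2":
        n_dep = int(rng.integers(0, 3))
    elif bracket == "3-5":
        n_dep = int(rng.integers(3, 6))
    else:
        n_dep = 6 + int(rng.poisson(1.0))
    # dependents split into children (<14) and dependent adults; one
    # breadwinner plus possibly a spouse on top
    n_children = int(rng.binomial(n_dep, 0.6))
    n_adults = 1 + (n_dep - n_children) + int(rng.binomial(1, 0.6))
    return bracket, n_dep, n_adults, n_children


def _draw_services(
    rng: np.random.Generator, pid: str, mech: str, hospitalized: bool, surgery: bool
) -> list[dict]:
    """Service list for one encounter; intensity scales with acuity."""
    rows: list[dict] = []

    def add(category, code, variant=None, laterality=None, quantity=1):
        rows.append(
            {
                "patient_id": pid,
                "category": category,
                "code_or_modality": code,
                "variant": variant,
                "laterality": laterality,
                "quantity": quantity,
            }
        )

    if surgery:
        add("consult_specialist", "consult_surgery")
        add("procedure_surgical", _SURGICAL_CODES[rng.choice(len(_SURGICAL_CODES))])
    if rng.random() < 0.15:
        add("consult_generalist", "consult_gp")
    if hospitalized and rng.random() < 0.25:
        add("consult_therapy", "consult_physio")
    # imaging: x-ray is near-universal for trauma; cross-sectional imaging
    # concentrates in road-traffic / blunt mechanisms
    if rng.random() < 0.75:
        lat = rng.choice(["unilateral", "bilateral", "unknown"], p=[0.55, 0.25, 0.2])
        add("imaging", "xray", laterality=str(lat))
    if mech in ("rti", "blunt") and rng.random() < 0.45:
        variant = rng.choice(["head", "body"], p=[0.6, 0.4])
        add("imaging", "ct", variant=str(variant))
    if rng.random() < 0.08:
        add("imaging", "mri", variant="unknown")
    if rng.random() < 0.20:
        add("imaging", "uss", variant="fast")
    if hospitalized:
        if rng.random() < 0.6:
            add("procedure_nonsurgical", "proc_fluids", quantity=1 + int(rng.poisson(1)))
        if rng.random() < 0.2:
            add("procedure_nonsurgical", "proc_oxygen")
        if surgery and rng.random() < 0.3:
            add("procedure_nonsurgical", "proc_transfusion")
            add("consumable", "cons_blood_unit", quantity=1 + int(rng.poisson(0.5)))
        add("consumable", "cons_saline", quantity=1 + int(rng.poisson(2)))
        if rng.random() < 0.5:
            add("consumable", "cons_dressing_kit", quantity=1 + int(rng.poisson(1)))
    return rows


def _min_che_trigger(
    te: float, nse: float, config: ToxicityConfig
) -> float:
    """Smallest OOP that crosses at least one CHE threshold (ge comparison).

    Returns 0.0 when any threshold base is zero, in which case any positive
    OOP triggers and only a zero OOP stays negative.
    """
    cutoffs = []
    for t in config.thresholds:
        base = te if t.base == "TE" else nse
        cutoffs.append(t.fraction * base)
    return min(cutoffs)


def generate_cohort(
    params: CohortParams, schedule: FeeSchedule | None = None
) -> Cohort:
    """Draw a full synthetic cohort; bitwise-deterministic given the seed."""
    schedule = schedule or default_fee_schedule()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    sigma = lognormal_sigma_from_iqr(
        params.income_median_monthly_ae, params.income_iqr_monthly_ae
    )
    mu = math.log(params.income_median_monthly_ae)

    hh_rows, enc_rows, svc_rows = [], [], []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        bracket, n_dep, n_adults, n_children = _draw_household(rng, params)
        ha = adult_equivalents(n_adults, n_children)
        monthly_ae_income = float(rng.lognormal(mu, sigma))
        annual_income = monthly_ae_income * 12.0 * ha
        income_missing = bool(rng.random() < params.prop_income_missing)
        # expenditure tracks income in a cash-constrained setting
        te = annual_income * float(rng.lognormal(math.log(0.85), 0.30))
        food_share = float(rng.beta(9.0, 11.0))  # mean 0.45
        food = te * food_share

        sex = "male" if rng.random() < params.prop_male else "female"
        age = 18 + int(rng.gamma(2.0, 8.3))
        mech = MECHANISMS[rng.choice(len(MECHANISMS), p=_norm(params.mechanism_probs))]
        education = (EDUCATION_LEVELS + ("unknown",))[
            rng.choice(4, p=_norm(params.education_probs))
        ]
        region = (REGIONS + ("unknown",))[rng.choice(4, p=_norm(params.region_probs))]
        marital = MARITAL[rng.choice(3, p=_norm(params.marital_probs))]
        occupation = OCCUPATIONS[rng.choice(4, p=_norm(params.occupation_probs))]
        uninsured = bool(rng.random() < params.prop_uninsured)
        died = bool(rng.random() < params.prop_death)
        hospitalized = bool(rng.random() < params.prop_hospitalized) or died
        surgery = bool(rng.random() < params.prop_surgery)
        if hospitalized:
            days_general = 1 + int(rng.poisson(2.5)) + (int(rng.poisson(2.0)) if surgery else 0)
            days_icu = int(rng.poisson(1.5)) if (died or rng.random() < 0.08) else 0
        else:
            days_general = days_icu = 0
        # Three-Delays fields: transfers (Delay 2) rise with surgical need,
        # Delay-1 factors with being uninsured
        transfers = int(rng.poisson(0.35 + 0.9 * surgery + 0.25 * hospitalized))
        time_to_care = (TIME_TO_CARE + ("unknown",))[
            rng.choice(4, p=(0.88, 0.07, 0.02, 0.03))
        ]
        delay1_cost_concern = bool(rng.random() < (0.55 if uninsured else 0.25))
        delay1_low_severity = bool(rng.random() < 0.3)
        delay1_no_agency = bool(rng.random() < 0.15)

        hh_rows.append(
            {
                "patient_id": pid,
                "n_adults": n_adults,
                "n_children": n_children,
                "n_dependents": n_dep,
                "dependents_bracket": bracket,
                "annual_income": float("nan") if income_missing else annual_income,
                "annual_total_expenditure": te,
                "annual_food_expenditure": food,
                "income_missing": income_missing,
            }
        )
        enc_rows.append(
            {
                "patient_id": pid,
                "age": age,
                "sex": sex,
                "education": education,
                "region": region,
                "marital_status": marital,
                "occupation": occupation,
                "insurance": "uninsured" if uninsured else "nhif",
                "mechanism": mech,
                "hospitalized": hospitalized,
                "surgery": surgery,
                "days_general": days_general,
                "days_icu": days_icu,
                "died": died,
                "num_transfers": transfers,
                "surgery_after_transfer": bool(surgery and transfers > 0),
                "time_to_care": time_to_care,
                "delay1_cost_concern": delay1_cost_concern,
                "delay1_low_severity": delay1_low_severity,
                "delay1_no_agency": delay1_no_agency,
            }
        )
        svc_rows.extend(_draw_services(rng, pid, mech, hospitalized, surgery))

    households = pd.DataFrame(hh_rows)
    encounters = pd.DataFrame(enc_rows)
    services = pd.DataFrame(
        svc_rows,
        columns=[
            "patient_id",
            "category",
            "code_or_modality",
            "variant",
            "laterality",
            "quantity",
        ],
    )
    costs = cost_cohort(schedule, encounters, services)

    config = ToxicityConfig()
    if params.target_any_che is not None:
        costs = _rescale_to_target(
            households, costs, params.target_any_che, config
        )
    labels = toxicity_table(households, costs, config)
    return Cohort(households, encounters, services, costs, labels, params)


def _rescale_to_target(
    households: pd.DataFrame,
    costs: pd.DataFrame,
    target: float,
    config: ToxicityConfig,
) -> pd.DataFrame:
    """Scale per-patient cost breakdowns so exactly round(target*n) patients
    cross >= 1 CHE threshold. Patients already closest to (or past) their
    trigger become the positives, minimizing distortion."""
    from .toxicity import non_subsistence_expenditure, subsistence_expenditure

    n = len(costs)
    k = round(target * n)
    se = subsistence_expenditure(households, window=config.percentile_window)
    merged = households.merge(costs, on="patient_id")
    triggers = np.array(
        [
            _min_che_trigger(
                row.annual_total_expenditure,
                non_subsistence_expenditure(row.annual_total_expenditure, se),
                config,
            )
            for row in merged.itertuples(index=False)
        ]
    )
    oop = merged["total_oop"].to_numpy(dtype=float)
    if k > 0 and np.all(triggers == 0) and np.all(oop == 0):
        raise GenerationError(
            "target_any_che infeasible: all costs and thresholds are zero"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            triggers > 0,
            oop / np.where(triggers > 0, triggers, 1.0),
            np.where(oop > 0, np.inf, 0.0),
        )
    positive_idx = np.argsort(-ratio, kind="stable")[:k]
    want = np.zeros(n, dtype=bool)
    want[positive_idx] = True

    factors = np.ones(n)
    for i in range(n):
        if want[i]:
            if triggers[i] == 0:
                if oop[i] == 0:
                    raise GenerationError(
                        f"cannot make zero-cost patient "
                        f"{merged['patient_id'].iloc[i]} CHE-positive"
                    )
            elif oop[i] < triggers[i]:
                # small relative margin so the scaled OOP clears the
                # threshold despite float rounding
                factors[i] = triggers[i] * (1.0 + 1e-9) / oop[i] if oop[i] > 0 else 0.0
                if oop[i] == 0:
                    raise GenerationError(
                        f"cannot rescale zero-cost patient "
                        f"{merged['patient_id'].iloc[i]} to a CHE positive"
                    )
        else:
            if triggers[i] == 0:
                factors[i] = 0.0  # only a zero OOP stays negative
            elif oop[i] >= triggers[i]:
                factors[i] = 0.9 * triggers[i] / oop[i]

    out = costs.copy()
    component_cols = [c for c in costs.columns if c != "patient_id"]
    out[component_cols] = out[component_cols].to_numpy() * factors[:, None]
    return out


def write_fixture(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write households/encounters/services (+ costs, labels, manifest) as
    the delimited-text dialects the pipeline reads."""
    if len(cohort.households) == 0:
        raise GenerationError("refusing to write an empty cohort")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("households", "encounters", "services", "costs"):
        df = getattr(cohort, name)
        paths[name] = outdir / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    if cohort.labels is not None:
        paths["labels"] = outdir / "labels.csv"
        cohort.labels.to_csv(paths["labels"], index=False)
    manifest = {"params": asdict(cohort.params), "n_patients": len(cohort.households)}
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def read_fixture(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read back the three cohort tables written by :func:`write_fixture`."""
    outdir = Path(outdir)
    return (
        pd.read_csv(outdir / "households.csv"),
        pd.read_csv(outdir / "encounters.csv"),
        pd.read_csv(outdir / "services.csv"),
    )
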