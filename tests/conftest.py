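import pandas as pd
import pytest

from fintox.costing import FeeItem, FeeSchedule, default_fee_schedule


@pytest.fixture(scope="session")
def schedule() -> FeeSchedule:
    """Small hand-written schedule with known prices for arithmetic checks."""
    return FeeSchedule(
        [
            FeeItem("consult_em", "consult_specialist", 25_000),
            FeeItem("consult_surgery", "consult_specialist", 30_000),
            FeeItem("consult_gp", "consult_generalist", 12_000),
            FeeItem("proc_fluids", "procedure_nonsurgical", 10_000),
            FeeItem("surg_orif", "procedure_surgical", 450_000),
            FeeItem("img_xray_uni", "imaging", 50_000, modality="xray", variant="unilateral"),
            FeeItem("img_xray_bil", "imaging", 80_000, modality="xray", variant="bilateral"),
            FeeItem("img_mri_a", "imaging", 100_000, modality="mri", variant="head"),
            FeeItem("img_mri_b", "imaging", 300_000, modality="mri", variant="spine"),
            FeeItem("adm_general", "admission_day", 10_000, ward="general"),
            FeeItem("adm_icu", "admission_day", 50_000, ward="icu"),
            FeeItem("cons_saline", "consumable", 8_000),
            FeeItem("death_certificate", "death_expense", 5_000),
            FeeItem("death_morgue_transport", "death_expense", 3_000),
            FeeItem("death_body_bag", "death_expense", 2_000),
        ]
    )


@pytest.fixture(scope="session")
def bundled_schedule() -> FeeSchedule:
    return default_fee_schedule()


def make_households(rows) -> pd.DataFrame:
    """Households table from (income, te, food, adults, children[, missing])."""
    out = []
    for i, r in enumerate(rows):
        income, te, food, adults, children = r[:5]
        missing = bool(r[5]) if len(r) > 5 else False
        out.append(
            {
                "patient_id": f"P{i + 1:04d}",
                "n_adults": adults,
                "n_children": children,
                "n_dependents": adults - 1 + children,
                "dependents_bracket": "0-2",
                "annual_income": float("nan") if missing else income,
                "annual_total_expenditure": te,
                "annual_food_expenditure": food,
                "income_missing": missing,
            }
        )
    return pd.DataFrame(out)


def make_costs(oops) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(len(oops))],
            "total_oop": list(oops),
        }
    )
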