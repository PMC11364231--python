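"""Three-Delays encoding of the prehospital pathway, stratified by toxicity.

The Three Delays framework decomposes access to emergency care into the
decision to seek care (Delay 1: perceived severity, cost concern, patient
agency), reaching an appropriate facility (Delay 2: facility transfers), and
receiving care on arrival (Delay 3: time to care, recorded on the ordinal
scale minutes / hours / longer). The registry's delay-1 items are an
extensible, partial enumeration of the questionnaire's factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .toxicity import ToxicityConfig, as_bool

TIME_TO_CARE_LEVELS = ("minutes", "hours", "longer")

DELAY1_FACTORS = (
    "delay1_cost_concern",
    "delay1_low_severity",
    "delay1_no_agency",
)


@dataclass(frozen=True)
class DelayProfile:
    """One patient's position in the Three-Delays framework."""

    patient_id: str
    delay1_factors: frozenset[str]
    transfers: int
    surgery_after_transfer: bool
    time_to_care: str  # one of TIME_TO_CARE_LEVELS or "unknown"

    def __post_init__(self) -> None:
        if self.transfers < 0:
            raise ValidationError("transfer count must be non-negative")
        if self.time_to_care not in TIME_TO_CARE_LEVELS + ("unknown",):
            raise ValidationError(
                f"time_to_care must be one of {TIME_TO_CARE_LEVELS} or 'unknown'"
            )


def classify_delays(encounter: pd.Series | dict) -> DelayProfile:
    """Deterministic mapping of raw registry fields to a delay profile.

    Missing time-to-care or factor fields become explicit unknown/absent
    markers rather than errors.
    """
    enc = dict(encounter)
    transfers = enc.get("num_transfers", 0)
    transfers = 0 if pd.isna(transfers) else int(transfers)
    if transfers < 0:
        raise ValidationError(
            f"patient {enc.get('patient_id')}: negative transfer count"
        )
    ttc = enc.get("time_to_care")
    if ttc is None or (isinstance(ttc, float) and np.isnan(ttc)):
        ttc = "unknown"
    factors = frozenset(f for f in DELAY1_FACTORS if bool(enc.get(f, False)))
    return DelayProfile(
        patient_id=str(enc.get("patient_id", "")),
        delay1_factors=factors,
        transfers=transfers,
        surgery_after_transfer=bool(enc.get("surgery_after_transfer", False)),
        time_to_care=str(ttc).lower(),
    )


def profiles_frame(encounters: pd.DataFrame) -> pd.DataFrame:
    """Vector form of :func:`classify_delays` over a cohort."""
    profiles = [classify_delays(row) for _, row in encounters.iterrows()]
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in profiles],
            "transfers": [p.transfers for p in profiles],
            "surgery_after_transfer": [p.surgery_after_transfer for p in profiles],
            "time_to_care": [p.time_to_care for p in profiles],
            **{
                f: [f in p.delay1_factors for p in profiles]
                for f in DELAY1_FACTORS
            },
        }
    )


def delays_summary(
    profiles: pd.DataFrame,
    results: pd.DataFrame,
    stratifier: str = "che",
    config: ToxicityConfig | None = None,
) -> pd.DataFrame:
    """Per-stratum delay summary (the three-column figure panel, as a table).

    Strata are any/none for the chosen toxicity indicator. For each stratum:
    n, mean and median transfer counts, % with surgery after a transfer,
    each delay-1 factor's frequency, the time-to-care distribution over
    known levels, and median OOP. The any/none median-OOP ratio is stored in
    ``attrs["median_oop_ratio"]``. Empty strata render with n=0.
    """
    config = config or ToxicityConfig()
    if stratifier == "che":
        flag = results["any_che"].astype(bool)
        eligible = pd.Series(True, index=results.index)
    elif stratifier == "imp":
        flag = as_bool(results["any_imp"])
        eligible = ~results["imp_excluded"]
    else:
        raise ValidationError(f"unknown stratifier {stratifier!r} (use 'che'|'imp')")
    merged = profiles.merge(
        results[["patient_id", "oop"]].assign(flag=flag, eligible=eligible),
        on="patient_id",
        validate="one_to_one",
    )
    rows = []
    for name, mask in (
        (f"any_{stratifier}", merged["flag"] & merged["eligible"]),
        (f"no_{stratifier}", ~merged["flag"] & merged["eligible"]),
    ):
        sub = merged[mask]
        n = len(sub)
        row: dict = {"stratum": name, "n": n}
        if n:
            row["mean_transfers"] = float(sub["transfers"].mean())
            row["median_transfers"] = float(sub["transfers"].median())
            row["pct_surgery_after_transfer"] = round(
                100.0 * sub["surgery_after_transfer"].mean(), 1
            )
            for f in DELAY1_FACTORS:
                row[f"pct_{f}"] = round(100.0 * sub[f].mean(), 1)
            known = sub[sub["time_to_care"].isin(TIME_TO_CARE_LEVELS)]
            for level in TIME_TO_CARE_LEVELS:
                row[f"pct_time_{level}"] = (
                    round(100.0 * (known["time_to_care"] == level).mean(), 1)
                    if len(known)
                    else np.nan
                )
            row["median_oop"] = float(sub["oop"].median())
        else:
            row.update(
                {
                    c: np.nan
                    for c in (
                        ["mean_transfers", "median_transfers",
                         "pct_surgery_after_transfer", "median_oop"]
                        + [f"pct_{f}" for f in DELAY1_FACTORS]
                        + [f"pct_time_{l}" for l in TIME_TO_CARE_LEVELS]
                    )
                }
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    med_any, med_none = out["median_oop"].iloc[0], out["median_oop"].iloc[1]
    out.attrs["median_oop_ratio"] = (
        round(med_any / med_none, 2)
        if med_none and not np.isnan(med_none) and med_none > 0
        else np.nan
    )
    return out


def render_delays_panel(summaries: dict[str, pd.DataFrame]) -> str:
    """Markdown panel mirroring the three-delays figure layout, one block
    per stratifier."""
    lines = ["### Three Delays, stratified by financial toxicity", ""]
    for stratifier, summary in summaries.items():
        lines.append(f"#### Stratified by {stratifier.upper()}")
        lines.append("")
        lines.append(
            f"Median OOP ratio (toxic / non-toxic): "
            f"{summary.attrs.get('median_oop_ratio')}"
        )
        lines.append("")
        cols = list(summary.columns)
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * len(cols))
        for _, row in summary.iterrows():
            cells = [
                "" if pd.isna(v) else (f"{v:g}" if isinstance(v, float) else str(v))
                for v in row
            ]
            lines.append("| " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)
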