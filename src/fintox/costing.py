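"""Itemized out-of-pocket (OOP) hospital costing from a fee schedule.

Each encounter's OOP expense is assembled from an itemized price list:
consultation fees (every encounter is charged at least the emergency-physician
consult), procedural fees (surgical procedures carry the procedural fee only),
imaging, ward accommodation by length of stay and acuity (general ward at the
basic shared-ward rate vs. ICU), consumables, and — for in-hospital deaths —
the death certificate, morgue transport and body bag. All amounts are
Tanzanian shillings (TZS) at citizen rates, pre-insurance-reimbursement.

Substitution rules for incompletely documented imaging: when the subtype of an
MRI or ultrasound is unknown, the arithmetic mean over all schedule items of
that modality is charged; when laterality (unilateral vs. bilateral) is
unknown, the mean of the unilateral and bilateral prices is charged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .errors import SchemaError, UnresolvableItemError, ValidationError

#: Literal token used in service files for an unknown variant/laterality.
#: An unknown is an explicit marker, distinct from "not applicable" (empty).
UNKNOWN = "unknown"

#: Code of the mandatory emergency-physician consultation. Every encounter
#: is charged this fee exactly once, whether or not it appears in the
#: service list.
EM_CONSULT_CODE = "consult_em"

CATEGORIES = frozenset(
    {
        "consult_specialist",
        "consult_generalist",
        "consult_therapy",
        "procedure_nonsurgical",
        "procedure_surgical",
        "imaging",
        "admission_day",
        "consumable",
        "death_expense",
    }
)

IMAGING_MODALITIES = frozenset({"xray", "ct", "mri", "uss"})

#: Cost-breakdown component each fee category contributes to.
_CATEGORY_COMPONENT = {
    "consult_specialist": "consultations",
    "consult_generalist": "consultations",
    "consult_therapy": "consultations",
    "procedure_nonsurgical": "procedures",
    "procedure_surgical": "procedures",
    "imaging": "imaging",
    "admission_day": "stay",
    "consumable": "consumables",
    "death_expense": "death",
}

_SCHEDULE_COLUMNS = ["code", "category", "unit_cost_tzs", "modality", "variant", "ward"]


@dataclass(frozen=True)
class FeeItem:
    """One line of the hospital price list."""

    code: str
    category: str
    unit_cost: float
    modality: str | None = None
    variant: str | None = None
    ward: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"fee item {self.code!r}: unknown category {self.category!r}"
            )
        if not math.isfinite(self.unit_cost) or self.unit_cost < 0:
            raise ValidationError(
                f"fee item {self.code!r}: unit cost must be a non-negative "
                f"number, got {self.unit_cost!r}"
            )
        if self.category == "imaging" and not self.modality:
            raise ValidationError(f"imaging item {self.code!r} lacks a modality")
        if self.category == "admission_day" and self.ward not in ("icu", "general"):
            raise ValidationError(
                f"admission item {self.code!r}: ward must be 'icu' or 'general'"
            )


@dataclass(frozen=True)
class ServiceRecord:
    """One service consumed by a patient, in the long-format cohort file.

    ``code_or_modality`` is a schedule code for non-imaging services and an
    imaging modality (xray/ct/mri/uss) for imaging. ``variant`` and
    ``laterality`` are ``None`` when not applicable and :data:`UNKNOWN` when
    the registry did not record them.
    """

    category: str
    code_or_modality: str
    variant: str | None = None
    laterality: str | None = None
    quantity: int = 1

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"service: unknown category {self.category!r}")
        if self.quantity < 1:
            raise ValidationError(
                f"service {self.code_or_modality!r}: quantity must be >= 1"
            )


@dataclass(frozen=True)
class Stay:
    """Length of stay split by ward acuity."""

    days_general: int = 0
    days_icu: int = 0

    def __post_init__(self) -> None:
        if self.days_general < 0 or self.days_icu < 0:
            raise ValidationError("stay days must be non-negative")

    @property
    def total_days(self) -> int:
        return self.days_general + self.days_icu


@dataclass(frozen=True)
class Encounter:
    """Everything needed to cost one patient's hospital visit."""

    patient_id: str
    services: tuple[ServiceRecord, ...] = ()
    stay: Stay = Stay()
    died: bool = False


@dataclass(frozen=True)
class CostBreakdown:
    """Per-category OOP components, TZS. ``total_oop`` is their exact sum."""

    consultations: float = 0.0
    procedures: float = 0.0
    imaging: float = 0.0
    stay: float = 0.0
    consumables: float = 0.0
    death: float = 0.0

    COMPONENTS = (
        "consultations",
        "procedures",
        "imaging",
        "stay",
        "consumables",
        "death",
    )

    def __post_init__(self) -> None:
        for name in self.COMPONENTS:
            if getattr(self, name) < 0:
                raise ValidationError(f"cost component {name} is negative")

    @property
    def total_oop(self) -> float:
        return sum(getattr(self, name) for name in self.COMPONENTS)

    def scaled(self, factor: float) -> "CostBreakdown":
        """Every component multiplied by ``factor`` (>= 0); additivity holds."""
        if factor < 0:
            raise ValidationError("scale factor must be non-negative")
        return replace(
            self, **{name: getattr(self, name) * factor for name in self.COMPONENTS}
        )

    def to_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in self.COMPONENTS}
        d["total_oop"] = self.total_oop
        return d


class FeeSchedule:
    """Validated collection of :class:`FeeItem`, indexed by code and category."""

    def __init__(self, items: list[FeeItem]):
        self._by_code: dict[str, FeeItem] = {}
        for item in items:
            if item.code in self._by_code:
                raise ValidationError(f"duplicate fee-schedule code {item.code!r}")
            self._by_code[item.code] = item

    def __len__(self) -> int:
        return len(self._by_code)

    def __iter__(self):
        return iter(self._by_code.values())

    def item(self, code: str) -> FeeItem:
        try:
            return self._by_code[code]
        except KeyError:
            raise UnresolvableItemError(
                f"code {code!r} not in fee schedule"
            ) from None

    def items_in_category(self, category: str) -> list[FeeItem]:
        return [i for i in self if i.category == category]

    def imaging_items(self, modality: str) -> list[FeeItem]:
        return [
            i for i in self if i.category == "imaging" and i.modality == modality
        ]

    def admission_rate(self, ward: str) -> float:
        rates = [i for i in self if i.category == "admission_day" and i.ward == ward]
        if not rates:
            raise UnresolvableItemError(f"no admission_day rate for ward {ward!r}")
        # basic shared-ward policy: cheapest listed rate for the ward
        return min(i.unit_cost for i in rates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "code": i.code,
                    "category": i.category,
                    "unit_cost_tzs": i.unit_cost,
                    "modality": i.modality,
                    "variant": i.variant,
                    "ward": i.ward,
                }
                for i in self
            ],
            columns=_SCHEDULE_COLUMNS,
        )


def _clean(value) -> str | None:
    """NaN/empty CSV cell -> None, else stripped string."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def load_fee_schedule(path: str | Path) -> FeeSchedule:
    """Read a comma-delimited fee schedule with header
    ``code,category,unit_cost_tzs,modality,variant,ward``."""
    df = pd.read_csv(path, comment="#")
    missing = set(_SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(
            f"fee schedule {path}: missing column(s) {sorted(missing)}"
        )
    items = []
    for row in df.itertuples(index=False):
        cost = float(row.unit_cost_tzs)
        if cost < 0:
            raise ValidationError(
                f"fee schedule {path}: negative unit_cost_tzs for "
                f"code {row.code!r}"
            )
        items.append(
            FeeItem(
                code=str(row.code),
                category=str(row.category),
                unit_cost=cost,
                modality=_clean(row.modality),
                variant=_clean(row.variant),
                ward=_clean(row.ward),
            )
        )
    return FeeSchedule(items)


def default_fee_schedule() -> FeeSchedule:
    """The bundled schedule of SYNTHETIC prices (see data/default_fee_schedule.csv).

    These are placeholder values for self-contained runs and tests; analyses
    of real encounters must supply the hospital's actual price list.
    """
    return load_fee_schedule(Path(__file__).parent / "data" / "default_fee_schedule.csv")


def _is_unknown(token: str | None) -> bool:
    return token is not None and token.lower() == UNKNOWN


def resolve_item_cost(schedule: FeeSchedule, svc: ServiceRecord) -> float:
    """Price one service record, applying the imaging substitution rules.

    Non-imaging services resolve by exact code. Imaging resolves by modality,
    then by variant (subtype) and laterality; an unknown subtype is charged
    the mean over the modality's items, an unknown laterality the mean of the
    unilateral and bilateral prices. The substituted price always lies within
    [min, max] of the averaged candidates. The result is multiplied by
    ``quantity``.
    """
    if svc.category == "imaging":
        modality = svc.code_or_modality.lower()
        candidates = schedule.imaging_items(modality)
        if not candidates:
            raise UnresolvableItemError(
                f"no imaging items with modality {modality!r} in schedule"
            )
        if svc.variant is not None and not _is_unknown(svc.variant):
            candidates = [i for i in candidates if i.variant == svc.variant]
        elif svc.laterality is not None and not _is_unknown(svc.laterality):
            lat = [i for i in candidates if i.variant == svc.laterality]
            candidates = lat or candidates
        elif _is_unknown(svc.laterality):
            lat = [
                i for i in candidates if i.variant in ("unilateral", "bilateral")
            ]
            candidates = lat or candidates
        # unknown variant: keep all modality items and average them
        if not candidates:
            raise UnresolvableItemError(
                f"no {modality!r} item with variant {svc.variant!r} in schedule"
            )
        unit = sum(i.unit_cost for i in candidates) / len(candidates)
    else:
        item = schedule.item(svc.code_or_modality)
        if item.category != svc.category:
            raise UnresolvableItemError(
                f"service {svc.code_or_modality!r} recorded as {svc.category!r} "
                f"but scheduled as {item.category!r}"
            )
        unit = item.unit_cost
    return unit * svc.quantity


def compute_stay_cost(schedule: FeeSchedule, stay: Stay) -> float:
    """days_general x basic shared-ward rate + days_icu x ICU rate."""
    cost = 0.0
    if stay.days_general:
        cost += stay.days_general * schedule.admission_rate("general")
    if stay.days_icu:
        cost += stay.days_icu * schedule.admission_rate("icu")
    return cost


def compute_death_cost(schedule: FeeSchedule, died: bool) -> float:
    """Death certificate + morgue transport + body bag for in-hospital deaths."""
    if not died:
        return 0.0
    items = schedule.items_in_category("death_expense")
    if len(items) < 3:
        raise UnresolvableItemError(
            "schedule must list the three death-expense items (certificate, "
            f"morgue transport, body bag); found {len(items)}"
        )
    return sum(i.unit_cost for i in items)


def compute_oop(schedule: FeeSchedule, encounter: Encounter) -> CostBreakdown:
    """Full itemized OOP breakdown for one encounter.

    The emergency-physician consult is always charged; stay and death costs
    come from the encounter's :class:`Stay` and vital status, everything else
    from the service list.
    """
    components = {name: 0.0 for name in CostBreakdown.COMPONENTS}
    components["consultations"] = schedule.item(EM_CONSULT_CODE).unit_cost
    for svc in encounter.services:
        if svc.category in ("admission_day", "death_expense"):
            raise ValidationError(
                f"patient {encounter.patient_id}: {svc.category} is costed from "
                "the stay/vital-status fields, not the service list"
            )
        try:
            cost = resolve_item_cost(schedule, svc)
        except UnresolvableItemError as exc:
            raise UnresolvableItemError(
                f"patient {encounter.patient_id}, service "
                f"{svc.code_or_modality!r}: {exc}"
            ) from exc
        components[_CATEGORY_COMPONENT[svc.category]] += cost
    components["stay"] = compute_stay_cost(schedule, encounter.stay)
    try:
        components["death"] = compute_death_cost(schedule, encounter.died)
    except UnresolvableItemError as exc:
        raise UnresolvableItemError(
            f"patient {encounter.patient_id}: {exc}"
        ) from exc
    return CostBreakdown(**components)


def encounters_from_frames(
    encounters: pd.DataFrame, services: pd.DataFrame
) -> list[Encounter]:
    """Assemble :class:`Encounter` objects from the two cohort tables."""
    svc_by_patient: dict[str, list[ServiceRecord]] = {}
    for row in services.itertuples(index=False):
        svc_by_patient.setdefault(str(row.patient_id), []).append(
            ServiceRecord(
                category=str(row.category),
                code_or_modality=str(row.code_or_modality),
                variant=_clean(row.variant),
                laterality=_clean(row.laterality),
                quantity=int(row.quantity) if not pd.isna(row.quantity) else 1,
            )
        )
    out = []
    for row in encounters.itertuples(index=False):
        pid = str(row.patient_id)
        out.append(
            Encounter(
                patient_id=pid,
                services=tuple(svc_by_patient.get(pid, ())),
                stay=Stay(int(row.days_general), int(row.days_icu)),
                died=bool(row.died),
            )
        )
    return out


def cost_cohort(
    schedule: FeeSchedule, encounters: pd.DataFrame, services: pd.DataFrame
) -> pd.DataFrame:
    """One CostBreakdown row per patient, indexed like the encounters table."""
    rows = []
    for enc in encounters_from_frames(encounters, services):
        breakdown = compute_oop(schedule, enc)
        rows.append({"patient_id": enc.patient_id, **breakdown.to_dict()})
    return pd.DataFrame(
        rows, columns=["patient_id", *CostBreakdown.COMPONENTS, "total_oop"]
    )


def convert_tzs_to_usd(
    amount_tzs: float, rate: float = 2339.0, rounded: bool = False
) -> float:
    """TZS -> USD at ``rate`` TZS per USD; ``rounded`` gives the nearest
    integer dollar used for headline reporting, otherwise 2 decimals."""
    if rate <= 0:
        raise ValidationError(f"conversion rate must be positive, got {rate}")
    usd = amount_tzs / rate
    return float(round(usd)) if rounded else round(usd, 2)
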