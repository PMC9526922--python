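"""Relational domain model for tiered diagnostic-network planning.

The model links five kinds of entities:

* **tiers** — ordered levels of a national health system (rank 1 = lowest,
  e.g. Primary health centers, Secondary district hospitals, Tertiary
  referral hospitals);
* **conditions**, each split into three *condition-levels* (triage,
  management of the uncomplicated condition, management of the condition
  with complications), every condition-level being assigned to the tier
  where that care is delivered;
* **medicines**, assigned to the condition-levels they treat;
* **diagnostics** (laboratory tests and imaging examinations), indicated
  either for condition-levels directly (diagnosis, monitoring,
  co-morbidity work-up) or for medicines (toxicity monitoring, dose
  adjustment, companion diagnostics);
* **formats** — concrete realizations of a diagnostic (rapid diagnostic
  test, automated analyzer, ...), each carrying the minimum tier at which
  its infrastructure demands allow it to operate, plus the equipment items
  (with capital-cost intervals in USD) it requires.

Instances are immutable value objects; relational and cross-table rules
are *not* enforced at construction time — they are reported as data by
:func:`dxnet.validation.validate_model`, so that partially broken inputs
can be loaded, diagnosed and repaired.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

#: Condition-levels in canonical order: identify-and-refer, then management
#: of the uncomplicated condition, then management with complications.
LEVELS: tuple[str, ...] = ("triage", "uncomplicated", "complicated")

Level = Literal["triage", "uncomplicated", "complicated"]

#: Laboratory disciplines plus radiology (the single imaging discipline).
DISCIPLINES: tuple[str, ...] = (
    "chemistry",
    "microbiology",
    "hematology",
    "coagulation",
    "molecular",
    "transfusion",
    "toxicology",
    "anatomic pathology",
    "immunology",
    "flow cytometry",
    "radiology",
)

Discipline = Literal[
    "chemistry",
    "microbiology",
    "hematology",
    "coagulation",
    "molecular",
    "transfusion",
    "toxicology",
    "anatomic pathology",
    "immunology",
    "flow cytometry",
    "radiology",
]

Modality = Literal["laboratory", "imaging"]

#: Indication classes that target a condition-level.
CONDITION_CLASSES: tuple[str, ...] = ("diagnosis", "monitoring", "comorbidity")
#: Indication classes that target a medicine.
MEDICINE_CLASSES: tuple[str, ...] = ("toxicity", "dose_adjustment", "companion")

IndicationClass = Literal[
    "diagnosis", "monitoring", "comorbidity", "toxicity", "dose_adjustment", "companion"
]


class _Record(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class Tier(_Record):
    """An ordered facility level; comparison of tiers is comparison of ranks."""

    id: str
    name: str
    rank: int


class Condition(_Record):
    id: str
    name: str
    gbd_term: Optional[str] = None
    source_lists: tuple[str, ...] = ()


class ConditionLevel(_Record):
    condition_id: str
    level: Level
    definition: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.condition_id, self.level)


class CareAssignment(_Record):
    """Where care for one condition-level is delivered (one tier each)."""

    condition_id: str
    level: Level
    tier_id: str


class Medicine(_Record):
    id: str
    name: str
    eml_note: Optional[str] = None


class MedicineAssignment(_Record):
    medicine_id: str
    condition_id: str
    level: Level


class Diagnostic(_Record):
    """A unique test or examination, identified by analyte/exam, not format.

    ``sendout_eligible`` controls whether a specimen can be transported to a
    higher tier when infrastructure blocks on-site placement; it defaults to
    true for laboratory diagnostics and is forced to false for imaging
    (patients, not specimens, travel for imaging).
    """

    id: str
    name: str
    discipline: Discipline
    modality: Modality
    sendout_eligible: Optional[bool] = None

    @model_validator(mode="before")
    @classmethod
    def _default_sendout(cls, data):
        if isinstance(data, dict) and data.get("sendout_eligible") is None:
            data = dict(data)
            data["sendout_eligible"] = data.get("modality") == "laboratory"
        return data


class DiagnosticIndication(_Record):
    """Medical justification for a diagnostic.

    Targets exactly one of a condition-level (``condition_id`` + ``level``)
    or a medicine (``medicine_id``); the indication class must match the
    target kind (diagnosis/monitoring/comorbidity for conditions,
    toxicity/dose_adjustment/companion for medicines).
    """

    diagnostic_id: str
    condition_id: Optional[str] = None
    level: Optional[Level] = None
    medicine_id: Optional[str] = None
    indication_class: IndicationClass

    @property
    def targets_condition(self) -> bool:
        return self.condition_id is not None

    @property
    def targets_medicine(self) -> bool:
        return self.medicine_id is not None


class CostInterval(_Record):
    """A [low, high] capital-cost range in USD; degenerate (low == high) allowed."""

    low: float
    high: float

    def __add__(self, other: "CostInterval") -> "CostInterval":
        return CostInterval(low=self.low + other.low, high=self.high + other.high)

    @property
    def midpoint(self) -> float:
        return (self.low + self.high) / 2.0

    @classmethod
    def zero(cls) -> "CostInterval":
        return cls(low=0.0, high=0.0)


class Format(_Record):
    """A concrete realization of a diagnostic with an infrastructure floor."""

    id: str
    diagnostic_id: str
    name: str
    min_tier_id: str
    equipment_ids: tuple[str, ...] = ()


class EquipmentItem(_Record):
    id: str
    name: str
    cost: CostInterval
    workforce_note: str = ""


def _level_order(level: str) -> int:
    return LEVELS.index(level) if level in LEVELS else len(LEVELS)


class ModelInstance(BaseModel):
    """A complete relational model instance.

    Collections are stored as tuples in canonical order (tiers by rank,
    everything else by its natural key), so two instances built from the
    same rows in any order compare equal.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    tiers: tuple[Tier, ...] = ()
    conditions: tuple[Condition, ...] = ()
    condition_levels: tuple[ConditionLevel, ...] = ()
    care_assignments: tuple[CareAssignment, ...] = ()
    medicines: tuple[Medicine, ...] = ()
    medicine_assignments: tuple[MedicineAssignment, ...] = ()
    diagnostics: tuple[Diagnostic, ...] = ()
    indications: tuple[DiagnosticIndication, ...] = ()
    formats: tuple[Format, ...] = ()
    equipment: tuple[EquipmentItem, ...] = ()

    @field_validator("tiers", mode="after")
    @classmethod
    def _sort_tiers(cls, v):
        return tuple(sorted(v, key=lambda t: (t.rank, t.id)))

    @field_validator("conditions", "medicines", "diagnostics", "formats", "equipment", mode="after")
    @classmethod
    def _sort_by_id(cls, v):
        return tuple(sorted(v, key=lambda r: r.id))

    @field_validator("condition_levels", "care_assignments", mode="after")
    @classmethod
    def _sort_by_condition_level(cls, v):
        return tuple(sorted(v, key=lambda r: (r.condition_id, _level_order(r.level))))

    @field_validator("medicine_assignments", mode="after")
    @classmethod
    def _sort_medicine_assignments(cls, v):
        return tuple(sorted(v, key=lambda r: (r.medicine_id, r.condition_id, _level_order(r.level))))

    @field_validator("indications", mode="after")
    @classmethod
    def _sort_indications(cls, v):
        return tuple(
            sorted(
                v,
                key=lambda r: (
                    r.diagnostic_id,
                    r.condition_id or "",
                    _level_order(r.level) if r.level else -1,
                    r.medicine_id or "",
                    r.indication_class,
                ),
            )
        )


class ModelIndex:
    """Lookup tables over a :class:`ModelInstance` (built once, read many).

    Kept separate from the frozen value object so that instances stay
    cheap, hashable-by-content data while traversals stay O(1).
    """

    def __init__(self, m: ModelInstance):
        self.model = m
        self.tier_by_id: dict[str, Tier] = {t.id: t for t in m.tiers}
        self.condition_by_id: dict[str, Condition] = {c.id: c for c in m.conditions}
        self.medicine_by_id: dict[str, Medicine] = {x.id: x for x in m.medicines}
        self.diagnostic_by_id: dict[str, Diagnostic] = {d.id: d for d in m.diagnostics}
        self.format_by_id: dict[str, Format] = {f.id: f for f in m.formats}
        self.equipment_by_id: dict[str, EquipmentItem] = {e.id: e for e in m.equipment}
        self.care_tier: dict[tuple[str, str], str] = {
            (a.condition_id, a.level): a.tier_id for a in m.care_assignments
        }
        self.formats_of: dict[str, list[Format]] = {}
        for f in m.formats:
            self.formats_of.setdefault(f.diagnostic_id, []).append(f)
        self.indications_of: dict[str, list[DiagnosticIndication]] = {}
        for ind in m.indications:
            self.indications_of.setdefault(ind.diagnostic_id, []).append(ind)
        self.assignments_of_medicine: dict[str, list[MedicineAssignment]] = {}
        for ma in m.medicine_assignments:
            self.assignments_of_medicine.setdefault(ma.medicine_id, []).append(ma)

    def rank(self, tier_id: str) -> int:
        return self.tier_by_id[tier_id].rank

    def tiers_ascending(self) -> tuple[Tier, ...]:
        return self.model.tiers

    def min_tier(self, tier_ids) -> Tier:
        """Lowest-rank tier among ``tier_ids`` (ids must exist)."""
        return min((self.tier_by_id[t] for t in tier_ids), key=lambda t: t.rank)
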