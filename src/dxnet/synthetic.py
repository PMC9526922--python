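"""Seeded synthetic model instances for download-free testing.

The generator emulates the relational shape of a national
diagnostic-network model: an ordered tier set, conditions split into the
three care levels with care tiers that never decrease from triage to
complicated management, medicines anchored to condition-levels,
diagnostics split between laboratory disciplines and imaging, one or
more formats per diagnostic with minimum tiers spread over the whole
tier range (so on-site, send-out and referral branches all occur), and
equipment with USD cost intervals.

Defaults mirror the exemplar study scale: 3 tiers, 20 conditions, 111
diagnostics, ~12% imaging, and a modest share of purely
medication-related indications. Instances are referentially intact by
construction — identical seeds give identical instances.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import (
    CONDITION_CLASSES,
    DISCIPLINES,
    LEVELS,
    MEDICINE_CLASSES,
    CareAssignment,
    Condition,
    ConditionLevel,
    CostInterval,
    Diagnostic,
    DiagnosticIndication,
    EquipmentItem,
    Format,
    Medicine,
    MedicineAssignment,
    ModelInstance,
)
from .validation import validate_model

_LAB_DISCIPLINES = tuple(d for d in DISCIPLINES if d != "radiology")


class SyntheticSpec(BaseModel):
    """Parameters of a synthetic instance (all randomness from ``seed``)."""

    model_config = ConfigDict(frozen=True)

    n_tiers: int = Field(default=3, ge=2)
    n_conditions: int = Field(default=20, ge=1)
    n_diagnostics: int = Field(default=111, ge=1)
    n_medicines: int = Field(default=40, ge=1)
    max_formats_per_diagnostic: int = Field(default=3, ge=1)
    p_imaging: float = Field(default=0.12, ge=0.0, le=1.0)
    p_medicine_indication: float = Field(default=0.15, ge=0.0, le=1.0)
    p_sendout_ineligible: float = Field(default=0.05, ge=0.0, le=1.0)
    cost_range: tuple[float, float] = (100.0, 500_000.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_costs(self):
        lo, hi = self.cost_range
        if not (0 <= lo <= hi):
            raise ValueError(f"cost_range {self.cost_range} must satisfy 0 <= low <= high")
        return self


def generate_synthetic(spec: SyntheticSpec) -> ModelInstance:
    """Generate a valid random instance according to ``spec``."""
    rng = np.random.default_rng(spec.seed)

    tiers = tuple(
        dict(id=f"tier{r}", name=f"Tier {r}", rank=r) for r in range(1, spec.n_tiers + 1)
    )
    tier_ids = [t["id"] for t in tiers]

    conditions = [f"cond_{i:03d}" for i in range(1, spec.n_conditions + 1)]
    condition_levels = [(c, lvl) for c in conditions for lvl in LEVELS]

    # care tiers never decrease from triage to complicated management
    care = {}
    for c in conditions:
        ranks = sorted(int(r) for r in rng.integers(1, spec.n_tiers + 1, size=3))
        for lvl, r in zip(LEVELS, ranks):
            care[(c, lvl)] = tier_ids[r - 1]

    medicines = [f"med_{i:03d}" for i in range(1, spec.n_medicines + 1)]
    med_assignments: set[tuple[str, str, str]] = set()
    for m in medicines:
        for _ in range(int(rng.integers(1, 3))):
            c = conditions[int(rng.integers(0, len(conditions)))]
            lvl = LEVELS[int(rng.integers(1, 3))]  # medicines treat, not triage
            med_assignments.add((m, c, lvl))

    n_equipment = max(3, spec.n_diagnostics // 3)
    lo, hi = spec.cost_range
    equipment = []
    for i in range(1, n_equipment + 1):
        a, b = sorted(float(x) for x in rng.uniform(lo, hi, size=2))
        equipment.append(dict(id=f"eq_{i:03d}", name=f"Equipment {i:03d}", low=a, high=b))

    diagnostics, formats, indications = [], [], []
    for i in range(1, spec.n_diagnostics + 1):
        d_id = f"diag_{i:03d}"
        imaging = bool(rng.random() < spec.p_imaging)
        if imaging:
            discipline, modality, sendout = "radiology", "imaging", False
        else:
            discipline = _LAB_DISCIPLINES[int(rng.integers(0, len(_LAB_DISCIPLINES)))]
            modality = "laboratory"
            sendout = bool(rng.random() >= spec.p_sendout_ineligible)
        diagnostics.append(
            dict(id=d_id, discipline=discipline, modality=modality, sendout=sendout)
        )

        n_formats = int(rng.integers(1, spec.max_formats_per_diagnostic + 1))
        for j in range(1, n_formats + 1):
            min_tier = tier_ids[int(rng.integers(0, spec.n_tiers))]
            n_eq = int(rng.integers(0, 3))
            eq_ids = tuple(
                equipment[k]["id"]
                for k in sorted(rng.choice(n_equipment, size=min(n_eq, n_equipment), replace=False).tolist())
            )
            formats.append(
                dict(id=f"{d_id}_f{j}", diagnostic_id=d_id, min_tier_id=min_tier, equipment_ids=eq_ids)
            )

        n_ind = int(rng.integers(1, 4))
        for _ in range(n_ind):
            if rng.random() < spec.p_medicine_indication:
                med = medicines[int(rng.integers(0, len(medicines)))]
                cls = MEDICINE_CLASSES[int(rng.integers(0, len(MEDICINE_CLASSES)))]
                indications.append(dict(diagnostic_id=d_id, medicine_id=med, cls=cls))
            else:
                c, lvl = condition_levels[int(rng.integers(0, len(condition_levels)))]
                cls = CONDITION_CLASSES[int(rng.integers(0, len(CONDITION_CLASSES)))]
                indications.append(dict(diagnostic_id=d_id, condition_id=c, level=lvl, cls=cls))

    instance = ModelInstance(
        tiers=tuple(dict(id=t["id"], name=t["name"], rank=t["rank"]) for t in tiers),
        conditions=tuple(
            Condition(id=c, name=f"Condition {c.split('_')[1]}") for c in conditions
        ),
        condition_levels=tuple(
            ConditionLevel(condition_id=c, level=lvl) for c, lvl in condition_levels
        ),
        care_assignments=tuple(
            CareAssignment(condition_id=c, level=lvl, tier_id=care[(c, lvl)])
            for c, lvl in condition_levels
        ),
        medicines=tuple(Medicine(id=m, name=f"Medicine {m.split('_')[1]}") for m in medicines),
        medicine_assignments=tuple(
            MedicineAssignment(medicine_id=m, condition_id=c, level=lvl)
            for m, c, lvl in sorted(med_assignments)
        ),
        diagnostics=tuple(
            Diagnostic(
                id=d["id"],
                name=f"Diagnostic {d['id'].split('_')[1]}",
                discipline=d["discipline"],
                modality=d["modality"],
                sendout_eligible=d["sendout"],
            )
            for d in diagnostics
        ),
        indications=tuple(
            DiagnosticIndication(
                diagnostic_id=r["diagnostic_id"],
                condition_id=r.get("condition_id"),
                level=r.get("level"),
                medicine_id=r.get("medicine_id"),
                indication_class=r["cls"],
            )
            for r in indications
        ),
        formats=tuple(
            Format(
                id=f["id"],
                diagnostic_id=f["diagnostic_id"],
                name=f"format {f['id']}",
                min_tier_id=f["min_tier_id"],
                equipment_ids=f["equipment_ids"],
            )
            for f in formats
        ),
        equipment=tuple(
            EquipmentItem(id=e["id"], name=e["name"], cost=CostInterval(low=e["low"], high=e["high"]))
            for e in equipment
        ),
    )
    violations = validate_model(instance)
    if violations:  # generator contract: never emits an invalid instance
        raise RuntimeError(f"synthetic generator produced an invalid instance: {violations[:5]}")
    return instance
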