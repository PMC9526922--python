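"""Builders and independent brute-force oracles shared by the tests.

The oracles deliberately work straight off the raw relational tables
(no ModelIndex, no placement code) so they stay independent of the
implementation paths they check.
"""

from __future__ import annotations

from dxnet import (
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
    Tier,
)

THREE_TIERS = (
    Tier(id="primary", name="Primary", rank=1),
    Tier(id="secondary", name="Secondary", rank=2),
    Tier(id="tertiary", name="Tertiary", rank=3),
)


def build_instance(
    *,
    tiers=THREE_TIERS,
    conditions=(),
    care=(),
    medicines=(),
    medicine_assignments=(),
    diagnostics=(),
    indications=(),
    formats=(),
    equipment=(),
) -> ModelInstance:
    """Compact builder: conditions as ids, care as (cond, level, tier),
    medicines as ids, the rest as record kwargs dicts."""
    cond_objs = tuple(Condition(id=c, name=c.replace("_", " ")) for c in conditions)
    levels = tuple(
        ConditionLevel(condition_id=c, level=lvl)
        for c in conditions
        for lvl in ("triage", "uncomplicated", "complicated")
    )
    care_objs = tuple(
        CareAssignment(condition_id=c, level=lvl, tier_id=t) for c, lvl, t in care
    )
    med_objs = tuple(Medicine(id=m, name=m) for m in medicines)
    ma_objs = tuple(MedicineAssignment(**kw) for kw in medicine_assignments)
    diag_objs = tuple(Diagnostic(**kw) for kw in diagnostics)
    ind_objs = tuple(DiagnosticIndication(**kw) for kw in indications)
    fmt_objs = tuple(Format(**kw) for kw in formats)
    eq_objs = tuple(
        EquipmentItem(id=e["id"], name=e.get("name", e["id"]), cost=CostInterval(low=e["low"], high=e["high"]))
        for e in equipment
    )
    return ModelInstance(
        tiers=tiers,
        conditions=cond_objs,
        condition_levels=levels,
        care_assignments=care_objs,
        medicines=med_objs,
        medicine_assignments=ma_objs,
        diagnostics=diag_objs,
        indications=ind_objs,
        formats=fmt_objs,
        equipment=eq_objs,
    )


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_desired_rank(m: ModelInstance, diagnostic_id: str) -> int:
    """Exhaustive enumeration of the expanded indication -> care-tier set."""
    rank = {t.id: t.rank for t in m.tiers}
    care = {(a.condition_id, a.level): a.tier_id for a in m.care_assignments}
    ranks = []
    for ind in m.indications:
        if ind.diagnostic_id != diagnostic_id:
            continue
        if ind.condition_id is not None:
            ranks.append(rank[care[(ind.condition_id, ind.level)]])
        else:
            for ma in m.medicine_assignments:
                if ma.medicine_id == ind.medicine_id:
                    ranks.append(rank[care[(ma.condition_id, ma.level)]])
    return min(ranks)


def brute_feasible_rank(m: ModelInstance, diagnostic_id: str) -> int:
    rank = {t.id: t.rank for t in m.tiers}
    return min(rank[f.min_tier_id] for f in m.formats if f.diagnostic_id == diagnostic_id)


def brute_performing_rank(m: ModelInstance, diagnostic_id: str) -> int:
    return max(brute_desired_rank(m, diagnostic_id), brute_feasible_rank(m, diagnostic_id))


def brute_condition_diagnostics(m: ModelInstance, condition_id: str) -> set[str]:
    meds = {ma.medicine_id for ma in m.medicine_assignments if ma.condition_id == condition_id}
    out = set()
    for ind in m.indications:
        if ind.condition_id == condition_id:
            out.add(ind.diagnostic_id)
        elif ind.medicine_id in meds:
            out.add(ind.diagnostic_id)
    return out
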