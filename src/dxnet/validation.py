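"""Relational validation of a model instance.

``validate_model`` is total: it never raises on a well-typed
:class:`~dxnet.model.ModelInstance`, and reports every broken invariant as
a :class:`Violation` value (empty report = valid model). Each violation
carries a stable machine-readable ``code`` and a human-readable message
naming the offending row, so CSV transcription errors can be fixed one by
one.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

from .model import CONDITION_CLASSES, MEDICINE_CLASSES, ModelInstance


@dataclass(frozen=True)
class Violation:
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


def _duplicates(ids) -> list[str]:
    return sorted(k for k, n in Counter(ids).items() if n > 1)


def validate_model(m: ModelInstance) -> list[Violation]:
    """Check all single-table and cross-table invariants; violations are data."""
    out: list[Violation] = []

    # --- tiers -----------------------------------------------------------
    if len(m.tiers) < 2:
        out.append(Violation("tier_count", f"model has {len(m.tiers)} tiers; at least 2 required"))
    for dup in _duplicates(t.id for t in m.tiers):
        out.append(Violation("duplicate_id", f"duplicate tier id {dup!r}"))
    for dup in _duplicates(t.rank for t in m.tiers):
        out.append(Violation("duplicate_rank", f"duplicate tier rank {dup}"))
    ranks = sorted(t.rank for t in m.tiers)
    if ranks and ranks != list(range(1, len(ranks) + 1)):
        out.append(Violation("rank_gap", f"tier ranks {ranks} do not form 1..{len(ranks)}"))
    tier_ids = {t.id for t in m.tiers}

    # --- simple id-keyed collections ------------------------------------
    for label, coll in (
        ("condition", m.conditions),
        ("medicine", m.medicines),
        ("diagnostic", m.diagnostics),
        ("format", m.formats),
        ("equipment", m.equipment),
    ):
        for dup in _duplicates(r.id for r in coll):
            out.append(Violation("duplicate_id", f"duplicate {label} id {dup!r}"))
    for c in m.conditions:
        if not c.name.strip():
            out.append(Violation("empty_name", f"condition {c.id!r} has an empty name"))

    condition_ids = {c.id for c in m.conditions}
    medicine_ids = {x.id for x in m.medicines}
    diagnostic_ids = {d.id for d in m.diagnostics}
    equipment_ids = {e.id for e in m.equipment}

    # --- condition-levels and care assignments --------------------------
    for dup in _duplicates((cl.condition_id, cl.level) for cl in m.condition_levels):
        out.append(Violation("duplicate_condition_level", f"condition-level {dup} defined twice"))
    for cl in m.condition_levels:
        if cl.condition_id not in condition_ids:
            out.append(
                Violation(
                    "dangling_ref",
                    f"condition-level ({cl.condition_id!r}, {cl.level}) references unknown condition",
                )
            )
    level_keys = {(cl.condition_id, cl.level) for cl in m.condition_levels}

    care_count = Counter((a.condition_id, a.level) for a in m.care_assignments)
    for a in m.care_assignments:
        if (a.condition_id, a.level) not in level_keys:
            out.append(
                Violation(
                    "dangling_ref",
                    f"care assignment references unknown condition-level ({a.condition_id!r}, {a.level})",
                )
            )
        if a.tier_id not in tier_ids:
            out.append(
                Violation(
                    "dangling_ref",
                    f"care assignment for ({a.condition_id!r}, {a.level}) references unknown tier {a.tier_id!r}",
                )
            )
    for key, n in sorted(care_count.items()):
        if n > 1:
            out.append(Violation("ambiguous_care_tier", f"condition-level {key} has {n} care assignments"))
    for key in sorted(level_keys - set(care_count)):
        out.append(Violation("missing_care_assignment", f"condition-level {key} has no care assignment"))

    # --- medicines -------------------------------------------------------
    for ma in m.medicine_assignments:
        if ma.medicine_id not in medicine_ids:
            out.append(Violation("dangling_ref", f"medicine assignment references unknown medicine {ma.medicine_id!r}"))
        if (ma.condition_id, ma.level) not in level_keys:
            out.append(
                Violation(
                    "dangling_ref",
                    f"medicine {ma.medicine_id!r} assigned to unknown condition-level ({ma.condition_id!r}, {ma.level})",
                )
            )
    anchored = {ma.medicine_id for ma in m.medicine_assignments}

    # --- diagnostics ------------------------------------------------------
    for d in m.diagnostics:
        imaging = d.modality == "imaging"
        if imaging != (d.discipline == "radiology"):
            out.append(
                Violation(
                    "modality_discipline_mismatch",
                    f"diagnostic {d.id!r}: modality {d.modality!r} inconsistent with discipline {d.discipline!r}",
                )
            )
        if imaging and d.sendout_eligible:
            out.append(
                Violation("imaging_sendout", f"imaging diagnostic {d.id!r} cannot be send-out eligible")
            )

    # --- indications ------------------------------------------------------
    indicated: set[str] = set()
    for ind in m.indications:
        if ind.diagnostic_id not in diagnostic_ids:
            out.append(Violation("dangling_ref", f"indication references unknown diagnostic {ind.diagnostic_id!r}"))
        indicated.add(ind.diagnostic_id)
        has_condition = ind.condition_id is not None or ind.level is not None
        has_medicine = ind.medicine_id is not None
        if has_condition == has_medicine:
            out.append(
                Violation(
                    "indication_target",
                    f"indication for {ind.diagnostic_id!r} must target exactly one of a condition-level or a medicine",
                )
            )
            continue
        if has_condition:
            if ind.condition_id is None or ind.level is None:
                out.append(
                    Violation(
                        "indication_target",
                        f"condition indication for {ind.diagnostic_id!r} needs both condition and level",
                    )
                )
            elif (ind.condition_id, ind.level) not in level_keys:
                out.append(
                    Violation(
                        "dangling_ref",
                        f"indication for {ind.diagnostic_id!r} references unknown condition-level "
                        f"({ind.condition_id!r}, {ind.level})",
                    )
                )
            if ind.indication_class not in CONDITION_CLASSES:
                out.append(
                    Violation(
                        "indication_class_mismatch",
                        f"indication for {ind.diagnostic_id!r}: class {ind.indication_class!r} "
                        f"not valid for a condition target",
                    )
                )
        else:
            if ind.medicine_id not in medicine_ids:
                out.append(
                    Violation(
                        "dangling_ref",
                        f"indication for {ind.diagnostic_id!r} references unknown medicine {ind.medicine_id!r}",
                    )
                )
            elif ind.medicine_id not in anchored:
                out.append(
                    Violation(
                        "unanchored_medicine",
                        f"indication for {ind.diagnostic_id!r} targets medicine {ind.medicine_id!r}, "
                        f"which has no condition-level assignment",
                    )
                )
            if ind.indication_class not in MEDICINE_CLASSES:
                out.append(
                    Violation(
                        "indication_class_mismatch",
                        f"indication for {ind.diagnostic_id!r}: class {ind.indication_class!r} "
                        f"not valid for a medicine target",
                    )
                )

    # --- formats ----------------------------------------------------------
    realized: set[str] = set()
    for f in m.formats:
        if f.diagnostic_id not in diagnostic_ids:
            out.append(Violation("dangling_ref", f"format {f.id!r} references unknown diagnostic {f.diagnostic_id!r}"))
        realized.add(f.diagnostic_id)
        if f.min_tier_id not in tier_ids:
            out.append(Violation("dangling_ref", f"format {f.id!r} references unknown tier {f.min_tier_id!r}"))
        for eq in f.equipment_ids:
            if eq not in equipment_ids:
                out.append(Violation("dangling_ref", f"format {f.id!r} references unknown equipment {eq!r}"))

    for d in m.diagnostics:
        if d.id not in indicated:
            out.append(Violation("unindicated_diagnostic", f"diagnostic {d.id!r} has no indication"))
        if d.id not in realized:
            out.append(Violation("unrealizable_diagnostic", f"diagnostic {d.id!r} has no format"))

    # --- equipment costs --------------------------------------------------
    for e in m.equipment:
        if e.cost.low < 0 or e.cost.low > e.cost.high:
            out.append(
                Violation(
                    "invalid_cost_interval",
                    f"equipment {e.id!r} cost interval [{e.cost.low}, {e.cost.high}] must satisfy 0 <= low <= high",
                )
            )

    return out
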