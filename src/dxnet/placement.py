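"""Tier placement of diagnostics.

The placement rule has two halves:

* the **desired tier** of a diagnostic is the lowest-ranked tier at which
  a patient might receive medical management dependent on its result —
  the minimum care tier over all condition-levels the diagnostic is
  indicated for, where medicine-targeted indications (toxicity
  monitoring, dose adjustment, companion testing) inherit the care tiers
  of every condition-level the medicine is assigned to treat;
* the **feasible tier** is the infrastructure floor — the lowest minimum
  tier over the diagnostic's formats (a rapid-test format may be feasible
  at a health center while an automated-analyzer format of the same
  analyte needs a district hospital).

The **performing tier** is the higher of the two. When infrastructure
forces a laboratory test above its desired tier, the network relies on
specimen transport ("send-out" testing) from every tier in between; for
imaging, or laboratory tests flagged send-out-ineligible (e.g. unstable
specimens), the patient is referred instead.
"""

from __future__ import annotations

from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict

from .model import Diagnostic, Format, ModelIndex, ModelInstance, Tier

Mode = Literal["on_site", "send_out", "referral"]


class PlacementError(ValueError):
    """A diagnostic that cannot be placed (unindicated, unrealizable, ...)."""


class PlanError(ValueError):
    """Aggregated per-diagnostic placement failures for a whole model."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(errors))


class Justification(BaseModel):
    """One indication that attains a diagnostic's desired tier.

    For medicine-targeted indications, ``medicine_id`` is set and
    ``condition_id``/``level`` name the condition-level (via the
    medicine's assignment) whose care tier was inherited.
    """

    model_config = ConfigDict(frozen=True)

    indication_class: str
    condition_id: str
    level: str
    medicine_id: Optional[str] = None


class Placement(BaseModel):
    model_config = ConfigDict(frozen=True)

    diagnostic_id: str
    desired_tier_id: str
    feasible_tier_id: str
    performing_tier_id: str
    mode: Mode
    origin_tier_ids: tuple[str, ...]  # tiers needing transport/referral upward
    justification: tuple[Justification, ...]
    chosen_format_id: str


class NetworkPlan(BaseModel):
    """One placement per diagnostic of a model instance."""

    model_config = ConfigDict(frozen=True)

    model: ModelInstance
    placements: tuple[Placement, ...]

    def placement_of(self, diagnostic_id: str) -> Placement:
        for p in self.placements:
            if p.diagnostic_id == diagnostic_id:
                return p
        raise KeyError(diagnostic_id)


def _as_index(m: Union[ModelInstance, ModelIndex]) -> ModelIndex:
    return m if isinstance(m, ModelIndex) else ModelIndex(m)


def _care_tier(ix: ModelIndex, condition_id: str, level: str) -> str:
    try:
        return ix.care_tier[(condition_id, level)]
    except KeyError:
        raise PlacementError(
            f"no care assignment for condition-level ({condition_id!r}, {level})"
        ) from None


def desired_tier(
    d: Union[str, Diagnostic], m: Union[ModelInstance, ModelIndex]
) -> tuple[Tier, tuple[Justification, ...]]:
    """Lowest care tier with a medical justification for ``d``.

    Returns the tier together with every (condition-level, indication
    class) pair attaining it. Raises :class:`PlacementError` for a
    diagnostic with no indication, or with a medicine-targeted indication
    whose medicine is assigned to no condition-level.
    """
    ix = _as_index(m)
    diag = ix.diagnostic_by_id[d] if isinstance(d, str) else d
    indications = ix.indications_of.get(diag.id, [])
    if not indications:
        raise PlacementError(f"unindicated diagnostic {diag.id!r}")

    candidates: list[tuple[int, str, Justification]] = []
    for ind in indications:
        if ind.targets_condition:
            tier_id = _care_tier(ix, ind.condition_id, ind.level)
            candidates.append(
                (
                    ix.rank(tier_id),
                    tier_id,
                    Justification(
                        indication_class=ind.indication_class,
                        condition_id=ind.condition_id,
                        level=ind.level,
                    ),
                )
            )
        else:
            assignments = ix.assignments_of_medicine.get(ind.medicine_id, [])
            if not assignments:
                raise PlacementError(
                    f"unanchored medicine {ind.medicine_id!r} indicated for {diag.id!r}"
                )
            for ma in assignments:
                tier_id = _care_tier(ix, ma.condition_id, ma.level)
                candidates.append(
                    (
                        ix.rank(tier_id),
                        tier_id,
                        Justification(
                            indication_class=ind.indication_class,
                            condition_id=ma.condition_id,
                            level=ma.level,
                            medicine_id=ind.medicine_id,
                        ),
                    )
                )

    best_rank = min(rank for rank, _, _ in candidates)
    tier = next(ix.tier_by_id[tid] for rank, tid, _ in candidates if rank == best_rank)
    just = tuple(
        sorted(
            {j for rank, _, j in candidates if rank == best_rank},
            key=lambda j: (j.condition_id, j.level, j.medicine_id or "", j.indication_class),
        )
    )
    return tier, just


def feasible_tier(d: Union[str, Diagnostic], m: Union[ModelInstance, ModelIndex]) -> Tier:
    """Lowest tier at which any format of ``d`` can physically operate."""
    ix = _as_index(m)
    diag = ix.diagnostic_by_id[d] if isinstance(d, str) else d
    formats = ix.formats_of.get(diag.id, [])
    if not formats:
        raise PlacementError(f"unrealizable diagnostic {diag.id!r} (no format)")
    return ix.min_tier(f.min_tier_id for f in formats)


def _equipment_midpoint(ix: ModelIndex, f: Format) -> float:
    total = 0.0
    for eq in f.equipment_ids:
        item = ix.equipment_by_id.get(eq)
        if item is not None:
            total += item.cost.midpoint
    return total


def choose_format(
    d: Union[str, Diagnostic], performing: Tier, m: Union[ModelInstance, ModelIndex]
) -> Format:
    """Deterministically pick the format used at the performing tier.

    Among formats operable at the performing tier: lowest minimum tier
    first, then cheapest equipment (sum of cost-interval midpoints), then
    lexicographic format name, then id.
    """
    ix = _as_index(m)
    diag = ix.diagnostic_by_id[d] if isinstance(d, str) else d
    operable = [
        f
        for f in ix.formats_of.get(diag.id, [])
        if ix.rank(f.min_tier_id) <= performing.rank
    ]
    if not operable:
        raise PlacementError(
            f"no format of {diag.id!r} operable at tier {performing.id!r}"
        )
    return min(
        operable,
        key=lambda f: (ix.rank(f.min_tier_id), _equipment_midpoint(ix, f), f.name, f.id),
    )


def place_diagnostic(
    d: Union[str, Diagnostic], m: Union[ModelInstance, ModelIndex]
) -> Placement:
    """Resolve one diagnostic's performing tier and delivery mode."""
    ix = _as_index(m)
    diag = ix.diagnostic_by_id[d] if isinstance(d, str) else d
    desired, just = desired_tier(diag, ix)
    feasible = feasible_tier(diag, ix)
    performing = desired if desired.rank >= feasible.rank else feasible

    if performing.rank == desired.rank:
        mode: Mode = "on_site"
    elif diag.modality == "laboratory" and diag.sendout_eligible:
        mode = "send_out"
    else:
        mode = "referral"

    origin = tuple(
        t.id for t in ix.tiers_ascending() if desired.rank <= t.rank < performing.rank
    )
    fmt = choose_format(diag, performing, ix)
    return Placement(
        diagnostic_id=diag.id,
        desired_tier_id=desired.id,
        feasible_tier_id=feasible.id,
        performing_tier_id=performing.id,
        mode=mode,
        origin_tier_ids=origin,
        justification=just,
        chosen_format_id=fmt.id,
    )


def build_plan(m: ModelInstance) -> NetworkPlan:
    """Place every diagnostic; aggregate per-diagnostic failures.

    Deterministic: placements are emitted in diagnostic-id order and do
    not depend on input row order (the instance is canonically sorted).
    """
    ix = ModelIndex(m)
    placements: list[Placement] = []
    errors: list[str] = []
    for diag in m.diagnostics:
        try:
            placements.append(place_diagnostic(diag, ix))
        except PlacementError as exc:
            errors.append(str(exc))
    if errors:
        raise PlanError(errors)
    return NetworkPlan(model=m, placements=tuple(placements))


def justifying_condition_levels(
    d: Union[str, Diagnostic], m: Union[ModelInstance, ModelIndex]
) -> set[tuple[str, str]]:
    """All condition-levels with an indication path to ``d`` (direct or
    through a medicine the diagnostic is indicated for)."""
    ix = _as_index(m)
    diag = ix.diagnostic_by_id[d] if isinstance(d, str) else d
    out: set[tuple[str, str]] = set()
    for ind in ix.indications_of.get(diag.id, []):
        if ind.targets_condition:
            out.add((ind.condition_id, ind.level))
        else:
            for ma in ix.assignments_of_medicine.get(ind.medicine_id, []):
                out.add((ma.condition_id, ma.level))
    return out
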