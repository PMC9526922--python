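"""What-if scenarios: move care between tiers, diff the resulting plans.

Health systems evolve: a ministry may decentralize management of
uncomplicated diabetes to health centers, or consolidate complicated
trauma care upward. Each such move changes where diagnostics are
medically justified, and hence the whole placement template. Scenarios
here are pure: ``reassign_care`` returns a new model instance and never
mutates its input, so what-if sweeps can be run in batch.

A scenario file is a JSON or YAML list of moves, applied in order::

    - {condition: diabetes, level: uncomplicated, new_tier: primary}
    - {condition: tuberculosis, level: complicated, new_tier: secondary}
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
import yaml

from .model import CareAssignment, ModelInstance
from .placement import NetworkPlan, Placement, build_plan
from .reports import cost_by_tier, tier_increment_counts
from .validation import validate_model


@dataclass(frozen=True)
class Move:
    condition_id: str
    level: str
    new_tier_id: str


@dataclass(frozen=True)
class PlacementChange:
    diagnostic_id: str
    old: Placement
    new: Placement


@dataclass(frozen=True)
class ScenarioDiff:
    """Placements that changed between two plans over the same diagnostics,
    plus per-tier deltas in newly-available counts and capital cost."""

    changes: tuple[PlacementChange, ...]
    tier_count_delta: dict[str, int]
    tier_cost_delta: dict[str, tuple[float, float]]  # (delta low, delta high) USD

    @property
    def empty(self) -> bool:
        return not self.changes

    def changed_diagnostics(self) -> set[str]:
        return {c.diagnostic_id for c in self.changes}


def reassign_care(
    m: ModelInstance, condition_id: str, level: str, new_tier_id: str
) -> ModelInstance:
    """Return a copy of ``m`` with one condition-level's care tier replaced."""
    if new_tier_id not in {t.id for t in m.tiers}:
        raise KeyError(f"unknown tier {new_tier_id!r}")
    keys = {(a.condition_id, a.level) for a in m.care_assignments}
    if (condition_id, level) not in keys:
        raise KeyError(f"no care assignment for condition-level ({condition_id!r}, {level!r})")
    new_assignments = tuple(
        CareAssignment(condition_id=condition_id, level=a.level, tier_id=new_tier_id)
        if (a.condition_id, a.level) == (condition_id, level)
        else a
        for a in m.care_assignments
    )
    return m.model_copy(update={"care_assignments": new_assignments})


def apply_scenario(m: ModelInstance, moves: Iterable[Move]) -> ModelInstance:
    """Apply moves in order, revalidating the instance after each step."""
    current = m
    for i, mv in enumerate(moves):
        current = reassign_care(current, mv.condition_id, mv.level, mv.new_tier_id)
        violations = validate_model(current)
        if violations:
            msgs = "; ".join(str(v) for v in violations)
            raise ValueError(f"scenario step {i + 1} produced an invalid model: {msgs}")
    return current


def diff_plans(a: NetworkPlan, b: NetworkPlan) -> ScenarioDiff:
    """Symmetric placement difference between two plans.

    Both plans must cover the same diagnostic set; a diagnostic appears
    in the diff iff any placement field (desired, feasible, performing,
    mode, origins, justification, chosen format) differs.
    """
    old = {p.diagnostic_id: p for p in a.placements}
    new = {p.diagnostic_id: p for p in b.placements}
    if set(old) != set(new):
        only_a = sorted(set(old) - set(new))
        only_b = sorted(set(new) - set(old))
        raise ValueError(
            f"plans cover different diagnostics (only in first: {only_a}; only in second: {only_b})"
        )
    changes = tuple(
        PlacementChange(d, old[d], new[d]) for d in sorted(old) if old[d] != new[d]
    )

    inc_a = tier_increment_counts(a).by_tier()
    inc_b = tier_increment_counts(b).by_tier()
    cost_a = cost_by_tier(a)
    cost_b = cost_by_tier(b)
    tiers = sorted(set(inc_a) | set(inc_b))
    count_delta = {t: inc_b.get(t, 0) - inc_a.get(t, 0) for t in tiers}
    cost_delta = {}
    for t in tiers:
        ca = cost_a.get(t)
        cb = cost_b.get(t)
        low_a, high_a = (ca.low, ca.high) if ca else (0.0, 0.0)
        low_b, high_b = (cb.low, cb.high) if cb else (0.0, 0.0)
        cost_delta[t] = (low_b - low_a, high_b - high_a)
    return ScenarioDiff(changes=changes, tier_count_delta=count_delta, tier_cost_delta=cost_delta)


def run_scenario(m: ModelInstance, moves: Iterable[Move]) -> tuple[ModelInstance, ScenarioDiff]:
    """Convenience: apply moves and diff the induced plans."""
    moved = apply_scenario(m, moves)
    return moved, diff_plans(build_plan(m), build_plan(moved))


def load_moves(path: Union[str, Path]) -> list[Move]:
    """Read a scenario file (JSON or YAML list of moves)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, list):
        raise ValueError(f"{path}: scenario file must be a list of moves")
    moves = []
    for i, item in enumerate(data):
        if not isinstance(item, dict) or not {"condition", "level", "new_tier"} <= set(item):
            raise ValueError(f"{path}: move {i + 1} must have keys condition, level, new_tier")
        moves.append(Move(str(item["condition"]), str(item["level"]), str(item["new_tier"])))
    return moves


def diff_table(d: ScenarioDiff) -> pd.DataFrame:
    rows = [
        {
            "diagnostic": c.diagnostic_id,
            "old_performing_tier": c.old.performing_tier_id,
            "new_performing_tier": c.new.performing_tier_id,
            "old_mode": c.old.mode,
            "new_mode": c.new.mode,
            "old_desired_tier": c.old.desired_tier_id,
            "new_desired_tier": c.new.desired_tier_id,
        }
        for c in d.changes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "diagnostic", "old_performing_tier", "new_performing_tier",
            "old_mode", "new_mode", "old_desired_tier", "new_desired_tier",
        ],
    )


def diff_markdown(d: ScenarioDiff) -> str:
    lines = ["# Scenario diff", ""]
    if d.empty:
        lines.append("No placements changed.")
        lines.append("")
        return "\n".join(lines)
    lines.append(f"{len(d.changes)} placement(s) changed.")
    lines.append("")
    for c in d.changes:
        lines.append(
            f"- {c.diagnostic_id}: {c.old.performing_tier_id}/{c.old.mode}"
            f" -> {c.new.performing_tier_id}/{c.new.mode}"
        )
    lines.append("")
    lines.append("## Per-tier deltas")
    lines.append("")
    for t in sorted(d.tier_count_delta):
        dl, dh = d.tier_cost_delta[t]
        lines.append(
            f"- {t}: {d.tier_count_delta[t]:+d} diagnostics, "
            f"capital cost delta [{dl:+,.0f}, {dh:+,.0f}] USD"
        )
    lines.append("")
    return "\n".join(lines)
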