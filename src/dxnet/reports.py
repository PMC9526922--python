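"""Summary outputs derived from a network plan.

Covers the quantities a planner needs when turning a plan into policy:
how many new diagnostics each tier takes on (tier increments), which
laboratory tests travel as specimens and to where (send-out summary),
the discipline/modality mix, which equipment each tier must newly buy
and what that costs (interval arithmetic over per-item USD ranges), how
diagnostic demand is distributed over conditions, and how demand
accumulates as conditions are added to the covered set (coverage curve).

Counting conventions: a diagnostic is counted once, at its performing
tier, regardless of how many formats realize it; equipment available at
a lower tier is never re-counted at a higher one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Iterable, Optional, Union

import pandas as pd

from .model import CostInterval, EquipmentItem, ModelIndex, ModelInstance
from .placement import NetworkPlan


# ---------------------------------------------------------------------------
# tier increments & send-outs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TierIncrement:
    tier_id: str
    new_diagnostics: int          # performing tier = this tier
    incoming_sendouts: int        # of those, performed on transported specimens


@dataclass(frozen=True)
class TierIncrementReport:
    increments: tuple[TierIncrement, ...]   # ascending tier rank
    total: int

    def by_tier(self) -> dict[str, int]:
        return {i.tier_id: i.new_diagnostics for i in self.increments}


def tier_increment_counts(p: NetworkPlan) -> TierIncrementReport:
    """Diagnostics newly available at each tier (counted once, at their
    performing tier; send-outs included there, flagged)."""
    ix = ModelIndex(p.model)
    new = {t.id: 0 for t in p.model.tiers}
    sent = {t.id: 0 for t in p.model.tiers}
    for pl in p.placements:
        new[pl.performing_tier_id] += 1
        if pl.mode == "send_out":
            sent[pl.performing_tier_id] += 1
    incs = tuple(
        TierIncrement(t.id, new[t.id], sent[t.id]) for t in ix.tiers_ascending()
    )
    return TierIncrementReport(increments=incs, total=len(p.placements))


@dataclass(frozen=True)
class SendoutSummary:
    #: unique send-out diagnostics performed at each tier (a diagnostic
    #: counts once here even if specimens arrive from several lower tiers)
    to_tier: dict[str, int]
    #: (origin tier, performing tier) -> diagnostics routed along that leg
    by_route: dict[tuple[str, str], int]


def sendout_summary(p: NetworkPlan) -> SendoutSummary:
    to_tier: dict[str, int] = {}
    by_route: dict[tuple[str, str], int] = {}
    for pl in p.placements:
        if pl.mode != "send_out":
            continue
        to_tier[pl.performing_tier_id] = to_tier.get(pl.performing_tier_id, 0) + 1
        for origin in pl.origin_tier_ids:
            key = (origin, pl.performing_tier_id)
            by_route[key] = by_route.get(key, 0) + 1
    return SendoutSummary(to_tier=to_tier, by_route=by_route)


def category_counts(p: NetworkPlan) -> tuple[dict[str, int], dict[str, int]]:
    """(by discipline, by modality); both sum to the diagnostic total."""
    ix = ModelIndex(p.model)
    by_disc: dict[str, int] = {}
    by_mod: dict[str, int] = {}
    for pl in p.placements:
        d = ix.diagnostic_by_id[pl.diagnostic_id]
        by_disc[d.discipline] = by_disc.get(d.discipline, 0) + 1
        by_mod[d.modality] = by_mod.get(d.modality, 0) + 1
    return by_disc, by_mod


# ---------------------------------------------------------------------------
# condition-centric views
# ---------------------------------------------------------------------------

def condition_diagnostics(
    m: Union[ModelInstance, ModelIndex], condition_id: str
) -> set[str]:
    """Diagnostics a single condition calls for, in isolation: every
    diagnostic indicated for any of its levels, directly or through a
    medicine assigned to one of its levels."""
    ix = m if isinstance(m, ModelIndex) else ModelIndex(m)
    wanted: set[str] = set()
    medicines: set[str] = set()
    for ma in ix.model.medicine_assignments:
        if ma.condition_id == condition_id:
            medicines.add(ma.medicine_id)
    for ind in ix.model.indications:
        if ind.targets_condition and ind.condition_id == condition_id:
            wanted.add(ind.diagnostic_id)
        elif ind.targets_medicine and ind.medicine_id in medicines:
            wanted.add(ind.diagnostic_id)
    return wanted


def per_condition_counts(m: ModelInstance) -> dict[str, int]:
    ix = ModelIndex(m)
    return {c.id: len(condition_diagnostics(ix, c.id)) for c in m.conditions}


@dataclass(frozen=True)
class CoverageCurve:
    """Cumulative unique-diagnostic counts as conditions are added greedily
    (largest isolated diagnostic set first, ties broken by name)."""

    condition_ids: tuple[str, ...]
    cumulative: tuple[int, ...]
    marginal: tuple[int, ...]
    #: median over all marginals, the first condition's full count included
    median_marginal_including_first: float
    #: median over marginals after the first condition (None for 1 condition)
    median_marginal_excluding_first: Optional[float]


def cumulative_coverage(m: ModelInstance) -> CoverageCurve:
    """Greedy coverage curve; input condition order never matters because
    ordering is recomputed from the per-condition counts."""
    ix = ModelIndex(m)
    if not m.conditions:
        raise ValueError("cumulative_coverage requires at least one condition")
    sets = {c.id: condition_diagnostics(ix, c.id) for c in m.conditions}
    name = {c.id: c.name for c in m.conditions}
    order = sorted(sets, key=lambda cid: (-len(sets[cid]), name[cid], cid))
    seen: set[str] = set()
    cumulative: list[int] = []
    marginal: list[int] = []
    for cid in order:
        before = len(seen)
        seen |= sets[cid]
        cumulative.append(len(seen))
        marginal.append(len(seen) - before)
    incl = float(median(marginal))
    excl = float(median(marginal[1:])) if len(marginal) > 1 else None
    return CoverageCurve(
        condition_ids=tuple(order),
        cumulative=tuple(cumulative),
        marginal=tuple(marginal),
        median_marginal_including_first=incl,
        median_marginal_excluding_first=excl,
    )


def medicine_only_ids(m: ModelInstance) -> set[str]:
    """Diagnostics whose every indication targets a medicine (and that
    have at least one indication)."""
    has_condition: set[str] = set()
    has_any: set[str] = set()
    for ind in m.indications:
        has_any.add(ind.diagnostic_id)
        if ind.targets_condition:
            has_condition.add(ind.diagnostic_id)
    return has_any - has_condition


def medicine_only_count(m: ModelInstance) -> int:
    return len(medicine_only_ids(m))


# ---------------------------------------------------------------------------
# equipment & capital cost
# ---------------------------------------------------------------------------

def equipment_by_tier(p: NetworkPlan) -> dict[str, set[str]]:
    """Equipment newly required at each tier: the union of the chosen
    formats' equipment at that tier, minus anything a lower tier already
    requires (equipment, like diagnostics, is available upward)."""
    ix = ModelIndex(p.model)
    fmt = ix.format_by_id
    out: dict[str, set[str]] = {}
    already: set[str] = set()
    for t in ix.tiers_ascending():
        here: set[str] = set()
        for pl in p.placements:
            if pl.performing_tier_id == t.id:
                here.update(fmt[pl.chosen_format_id].equipment_ids)
        out[t.id] = here - already
        already |= here
    return out


def equipment_rollup(p: NetworkPlan, tier_id: str) -> set[str]:
    return equipment_by_tier(p)[tier_id]


def cost_of_equipment(
    items: Iterable[Union[str, EquipmentItem]], m: Optional[ModelInstance] = None
) -> CostInterval:
    """Interval sum of equipment capital costs (one instrument of each type)."""
    total = CostInterval.zero()
    ix = ModelIndex(m) if m is not None else None
    for item in sorted(items, key=lambda x: x if isinstance(x, str) else x.id):
        if isinstance(item, str):
            if ix is None:
                raise ValueError("equipment ids require the model instance for prices")
            item = ix.equipment_by_id[item]
        total = total + item.cost
    return total


def cost_by_tier(p: NetworkPlan) -> dict[str, CostInterval]:
    """Capital-cost interval of each tier's newly required equipment."""
    rollup = equipment_by_tier(p)
    return {tid: cost_of_equipment(ids, p.model) for tid, ids in rollup.items()}


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def plan_table(p: NetworkPlan) -> pd.DataFrame:
    """Flat one-row-per-placement table, ordered by performing tier rank,
    then discipline, then diagnostic name."""
    ix = ModelIndex(p.model)
    rows = []
    for pl in p.placements:
        d = ix.diagnostic_by_id[pl.diagnostic_id]
        rows.append(
            {
                "diagnostic": d.id,
                "name": d.name,
                "discipline": d.discipline,
                "modality": d.modality,
                "desired_tier": pl.desired_tier_id,
                "feasible_tier": pl.feasible_tier_id,
                "performing_tier": pl.performing_tier_id,
                "mode": pl.mode,
                "origin_tiers": ";".join(pl.origin_tier_ids),
                "chosen_format": pl.chosen_format_id,
                "justification": ";".join(
                    (f"{j.medicine_id}->" if j.medicine_id else "")
                    + f"{j.condition_id}:{j.level}[{j.indication_class}]"
                    for j in pl.justification
                ),
            }
        )
    rows.sort(
        key=lambda r: (
            ix.rank(r["performing_tier"]),
            r["discipline"],
            r["name"],
            r["diagnostic"],
        )
    )
    return pd.DataFrame(
        rows,
        columns=[
            "diagnostic", "name", "discipline", "modality", "desired_tier",
            "feasible_tier", "performing_tier", "mode", "origin_tiers",
            "chosen_format", "justification",
        ],
    )


def _equipment_table(p: NetworkPlan) -> pd.DataFrame:
    ix = ModelIndex(p.model)
    rollup = equipment_by_tier(p)
    rows = []
    for t in ix.tiers_ascending():
        for eq_id in sorted(rollup[t.id]):
            e = ix.equipment_by_id[eq_id]
            rows.append(
                {
                    "tier": t.id,
                    "equipment": e.id,
                    "name": e.name,
                    "cost_low_usd": e.cost.low,
                    "cost_high_usd": e.cost.high,
                    "workforce_note": e.workforce_note,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["tier", "equipment", "name", "cost_low_usd", "cost_high_usd", "workforce_note"],
    )


def _cost_table(p: NetworkPlan) -> pd.DataFrame:
    ix = ModelIndex(p.model)
    costs = cost_by_tier(p)
    top_rank = max((t.rank for t in p.model.tiers), default=0)
    rows = []
    for t in ix.tiers_ascending():
        c = costs[t.id]
        note = "not validated" if t.rank == top_rank else ""
        rows.append(
            {"tier": t.id, "cost_low_usd": c.low, "cost_high_usd": c.high, "note": note}
        )
    return pd.DataFrame(rows, columns=["tier", "cost_low_usd", "cost_high_usd", "note"])


def _markdown_report(p: NetworkPlan) -> str:
    ix = ModelIndex(p.model)
    table = plan_table(p)
    inc = tier_increment_counts(p)
    so = sendout_summary(p)
    costs = _cost_table(p)
    lines = ["# Diagnostic network plan", ""]
    lines.append(f"Total unique diagnostics: {inc.total}")
    lines.append("")
    for t in ix.tiers_ascending():
        sub = table[table["performing_tier"] == t.id]
        lines.append(f"## {ix.tier_by_id[t.id].name} tier ({len(sub)} new diagnostics)")
        lines.append("")
        for _, r in sub.iterrows():
            marker = ""
            if r["mode"] == "send_out":
                marker = f" *(send-out from {r['origin_tiers'] or '-'})*"
            elif r["mode"] == "referral":
                marker = f" *(referral from {r['origin_tiers'] or '-'})*"
            lines.append(f"- {r['name']} [{r['discipline']}]{marker}")
        lines.append("")
    lines.append("## Send-outs by receiving tier")
    lines.append("")
    for tid in sorted(so.to_tier, key=ix.rank):
        lines.append(f"- to {ix.tier_by_id[tid].name}: {so.to_tier[tid]} laboratory tests")
    lines.append("")
    lines.append("## Capital cost by tier (USD, one instrument of each type)")
    lines.append("")
    for _, r in costs.iterrows():
        note = f" — {r['note']}" if r["note"] else ""
        lines.append(
            f"- {ix.tier_by_id[r['tier']].name}: "
            f"[{r['cost_low_usd']:,.0f}, {r['cost_high_usd']:,.0f}]{note}"
        )
    lines.append("")
    return "\n".join(lines)


def export_report(
    p: NetworkPlan, out_dir: Union[str, Path], formats: Iterable[str] = ("csv", "json", "markdown")
) -> list[Path]:
    """Write the report bundle; repeated exports are byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    formats = {("markdown" if f in ("md", "markdown") else f) for f in formats}
    unknown = formats - {"csv", "json", "markdown"}
    if unknown:
        raise ValueError(f"unknown report format(s): {sorted(unknown)}")
    if "csv" in formats:
        for name, df in (
            ("placements", plan_table(p)),
            ("equipment", _equipment_table(p)),
            ("costs", _cost_table(p)),
        ):
            path = out / f"{name}.csv"
            df.to_csv(path, index=False, encoding="utf-8")
            written.append(path)
    if "json" in formats:
        inc = tier_increment_counts(p)
        so = sendout_summary(p)
        by_disc, by_mod = category_counts(p)
        bundle = {
            "total_diagnostics": inc.total,
            "tier_increments": {i.tier_id: i.new_diagnostics for i in inc.increments},
            "incoming_sendouts": {i.tier_id: i.incoming_sendouts for i in inc.increments},
            "sendouts_to_tier": dict(sorted(so.to_tier.items())),
            "sendout_routes": {f"{a}->{b}": n for (a, b), n in sorted(so.by_route.items())},
            "by_discipline": dict(sorted(by_disc.items())),
            "by_modality": dict(sorted(by_mod.items())),
            "cost_by_tier": {
                tid: [c.low, c.high] for tid, c in sorted(cost_by_tier(p).items())
            },
            "placements": plan_table(p).to_dict(orient="records"),
        }
        path = out / "report.json"
        path.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        written.append(path)
    if "markdown" in formats:
        path = out / "report.md"
        path.write_text(_markdown_report(p), encoding="utf-8")
        written.append(path)
    return written
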