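"""Report derivations: conservation, coverage, costs, rollups, exports."""

import pandas as pd
import pytest

from dxnet import (
    ModelInstance,
    build_plan,
    category_counts,
    condition_diagnostics,
    cost_by_tier,
    cost_of_equipment,
    cumulative_coverage,
    equipment_by_tier,
    export_report,
    medicine_only_count,
    medicine_only_ids,
    per_condition_counts,
    plan_table,
    sendout_summary,
    tier_increment_counts,
)

from _helpers import brute_condition_diagnostics, build_instance
from conftest import small_instance


@pytest.mark.parametrize("seed", range(6))
def test_tier_increments_and_categories_conserve_totals(seed):
    m = small_instance(seed=seed)
    plan = build_plan(m)
    inc = tier_increment_counts(plan)
    assert sum(i.new_diagnostics for i in inc.increments) == inc.total == len(m.diagnostics)
    by_disc, by_mod = category_counts(plan)
    assert sum(by_disc.values()) == sum(by_mod.values()) == inc.total


def test_empty_plan_reports_zero_everywhere():
    m = build_instance()
    plan = build_plan(m)
    inc = tier_increment_counts(plan)
    assert inc.total == 0 and all(i.new_diagnostics == 0 for i in inc.increments)
    assert sendout_summary(plan).to_tier == {}


@pytest.mark.parametrize("seed", range(6))
def test_sendout_summary_counts_only_laboratory_sendouts(seed):
    m = small_instance(seed=seed)
    plan = build_plan(m)
    so = sendout_summary(plan)
    diags = {d.id: d for d in m.diagnostics}
    expected = {}
    for p in plan.placements:
        if p.mode == "send_out":
            assert diags[p.diagnostic_id].modality == "laboratory"
            expected[p.performing_tier_id] = expected.get(p.performing_tier_id, 0) + 1
    assert so.to_tier == expected
    # each route leg pairs a listed origin with the performing tier
    for (origin, performing), n in so.by_route.items():
        assert n >= 1 and origin != performing


@pytest.mark.parametrize("seed", range(6))
def test_per_condition_counts_match_brute_force_union(seed):
    m = small_instance(seed=seed)
    counts = per_condition_counts(m)
    for c in m.conditions:
        assert counts[c.id] == len(brute_condition_diagnostics(m, c.id))
        assert condition_diagnostics(m, c.id) == brute_condition_diagnostics(m, c.id)


def test_condition_with_no_diagnostics_counts_zero():
    m = build_instance(
        conditions=("lonely",),
        care=[("lonely", lvl, "primary") for lvl in ("triage", "uncomplicated", "complicated")],
    )
    assert per_condition_counts(m) == {"lonely": 0}


@pytest.mark.parametrize("seed", range(6))
def test_coverage_curve_matches_sequential_union_oracle(seed):
    m = small_instance(seed=seed)
    curve = cumulative_coverage(m)
    sets = {c.id: brute_condition_diagnostics(m, c.id) for c in m.conditions}
    # ordering: descending isolated count, ties by display name
    counts = [len(sets[c]) for c in curve.condition_ids]
    assert counts == sorted(counts, reverse=True)
    seen = set()
    for cid, cum, marg in zip(curve.condition_ids, curve.cumulative, curve.marginal):
        before = len(seen)
        seen |= sets[cid]
        assert cum == len(seen) and marg == len(seen) - before
    assert curve.cumulative[-1] == len(set().union(*sets.values()))
    assert all(a <= b for a, b in zip(curve.cumulative, curve.cumulative[1:]))


def test_coverage_curve_is_input_order_invariant():
    m = small_instance(seed=4)
    shuffled = ModelInstance(**{**m.model_dump(), "conditions": tuple(reversed(m.model_dump()["conditions"]))})
    assert cumulative_coverage(m) == cumulative_coverage(shuffled)


def test_single_condition_curve():
    m = build_instance(
        conditions=("only",),
        care=[("only", lvl, "primary") for lvl in ("triage", "uncomplicated", "complicated")],
        diagnostics=[dict(id="d", name="D", discipline="chemistry", modality="laboratory")],
        indications=[dict(diagnostic_id="d", condition_id="only", level="triage", indication_class="diagnosis")],
        formats=[dict(id="f", diagnostic_id="d", name="rdt", min_tier_id="primary")],
    )
    curve = cumulative_coverage(m)
    assert curve.cumulative == (1,) and curve.marginal == (1,)
    assert curve.median_marginal_including_first == 1.0
    assert curve.median_marginal_excluding_first is None


def test_medicine_only_counts(ghana):
    assert medicine_only_ids(ghana) == {"g6pd", "egfr_mutation", "drug_levels"}
    assert medicine_only_count(ghana) == 3


def test_mixed_indication_diagnostic_is_not_medicine_only(ghana):
    # liver function panel has both condition- and medicine-targeted indications
    assert "liver_function" not in medicine_only_ids(ghana)


def test_medicine_indication_free_instance_has_zero_medicine_only():
    m = small_instance(seed=2, p_medicine_indication=0.0)
    assert medicine_only_count(m) == 0


@pytest.mark.parametrize("seed", range(6))
def test_equipment_rollups_partition_required_equipment(seed):
    m = small_instance(seed=seed)
    plan = build_plan(m)
    rollup = equipment_by_tier(plan)
    tiers = list(rollup)
    for i, a in enumerate(tiers):
        for b in tiers[i + 1:]:
            assert rollup[a].isdisjoint(rollup[b])
    fmts = {f.id: f for f in m.formats}
    required = set()
    for p in plan.placements:
        required |= set(fmts[p.chosen_format_id].equipment_ids)
    assert set().union(*rollup.values()) == required


def test_cost_interval_sum_is_additive_over_disjoint_sets(ghana, ghana_plan):
    rollup = equipment_by_tier(ghana_plan)
    a, b = rollup["primary"], rollup["secondary"]
    combined = cost_of_equipment(a | b, ghana)
    split = cost_of_equipment(a, ghana) + cost_of_equipment(b, ghana)
    assert (combined.low, combined.high) == (split.low, split.high)
    empty = cost_of_equipment(set(), ghana)
    assert (empty.low, empty.high) == (0.0, 0.0)


def test_plan_table_is_one_row_per_placement_and_parseable(ghana_plan, tmp_path):
    df = plan_table(ghana_plan)
    assert len(df) == len(ghana_plan.placements)
    path = tmp_path / "placements.csv"
    df.to_csv(path, index=False)
    back = pd.read_csv(path, dtype=str, keep_default_na=False)
    assert list(back.columns) == list(df.columns) and len(back) == len(df)


def test_export_is_deterministic_and_structured(ghana_plan, tmp_path):
    export_report(ghana_plan, tmp_path / "a")
    export_report(ghana_plan, tmp_path / "b")
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
    md = (tmp_path / "a" / "report.md").read_text()
    for section in ("Primary tier", "Secondary tier", "Tertiary tier"):
        assert section in md
    costs = pd.read_csv(tmp_path / "a" / "costs.csv", keep_default_na=False)
    assert costs.loc[costs["tier"] == "tertiary", "note"].item() == "not validated"
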