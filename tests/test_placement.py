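"""Placement engine: desired/feasible/performing tiers, modes, properties."""

import pytest

from dxnet import (
    CareAssignment,
    Condition,
    ConditionLevel,
    DiagnosticIndication,
    PlacementError,
    build_plan,
    desired_tier,
    feasible_tier,
    place_diagnostic,
)

from _helpers import (
    THREE_TIERS,
    build_instance,
    brute_desired_rank,
    brute_feasible_rank,
    brute_performing_rank,
)
from conftest import small_instance


def _simple(care, indications, formats, diagnostics=None, **kw):
    diagnostics = diagnostics or [
        dict(id="d", name="D", discipline="chemistry", modality="laboratory")
    ]
    return build_instance(
        conditions=("dm", "pna"),
        care=care,
        diagnostics=diagnostics,
        indications=indications,
        formats=formats,
        **kw,
    )


_BASE_CARE = [
    ("dm", "triage", "primary"), ("dm", "uncomplicated", "secondary"), ("dm", "complicated", "tertiary"),
    ("pna", "triage", "primary"), ("pna", "uncomplicated", "secondary"), ("pna", "complicated", "tertiary"),
]


def test_desired_tier_is_minimum_over_indicated_care_tiers():
    m = _simple(
        _BASE_CARE,
        indications=[
            dict(diagnostic_id="d", condition_id="dm", level="uncomplicated", indication_class="monitoring"),
            dict(diagnostic_id="d", condition_id="dm", level="triage", indication_class="diagnosis"),
        ],
        formats=[dict(id="f", diagnostic_id="d", name="rdt", min_tier_id="primary")],
    )
    tier, just = desired_tier("d", m)
    assert tier.id == "primary"
    assert [(j.condition_id, j.level, j.indication_class) for j in just] == [
        ("dm", "triage", "diagnosis")
    ]


def test_medicine_only_indication_inherits_care_tier_of_medicine():
    m = _simple(
        _BASE_CARE,
        indications=[dict(diagnostic_id="d", medicine_id="ceph", indication_class="toxicity")],
        formats=[dict(id="f", diagnostic_id="d", name="analyzer", min_tier_id="primary")],
        medicines=("ceph",),
        medicine_assignments=[dict(medicine_id="ceph", condition_id="pna", level="complicated")],
    )
    tier, just = desired_tier("d", m)
    assert tier.id == "tertiary"
    assert just[0].medicine_id == "ceph" and just[0].level == "complicated"


def test_feasible_tier_is_minimum_over_formats():
    m = _simple(
        _BASE_CARE,
        indications=[dict(diagnostic_id="d", condition_id="dm", level="triage", indication_class="diagnosis")],
        formats=[
            dict(id="f1", diagnostic_id="d", name="rdt", min_tier_id="primary"),
            dict(id="f2", diagnostic_id="d", name="automated immunoassay", min_tier_id="secondary"),
        ],
    )
    assert feasible_tier("d", m).id == "primary"


def test_single_format_singleton_min():
    m = _simple(
        _BASE_CARE,
        indications=[dict(diagnostic_id="d", condition_id="dm", level="triage", indication_class="diagnosis")],
        formats=[dict(id="f", diagnostic_id="d", name="hplc", min_tier_id="tertiary")],
    )
    assert feasible_tier("d", m).id == "tertiary"


def test_constrained_laboratory_test_becomes_send_out():
    m = _simple(
        _BASE_CARE,
        indications=[dict(diagnostic_id="d", condition_id="dm", level="triage", indication_class="diagnosis")],
        formats=[dict(id="f", diagnostic_id="d", name="analyzer", min_tier_id="secondary")],
    )
    p = place_diagnostic("d", m)
    assert (p.desired_tier_id, p.performing_tier_id) == ("primary", "secondary")
    assert p.mode == "send_out" and p.origin_tier_ids == ("primary",)


def test_constrained_imaging_becomes_referral_never_send_out():
    m = _simple(
        _BASE_CARE,
        diagnostics=[dict(id="d", name="XR", discipline="radiology", modality="imaging")],
        indications=[dict(diagnostic_id="d", condition_id="pna", level="triage", indication_class="diagnosis")],
        formats=[dict(id="f", diagnostic_id="d", name="fixed unit", min_tier_id="secondary")],
    )
    p = place_diagnostic("d", m)
    assert p.mode == "referral" and p.origin_tier_ids == ("primary",)


def test_sendout_ineligible_laboratory_test_becomes_referral():
    m = _simple(
        _BASE_CARE,
        diagnostics=[
            dict(id="d", name="D", discipline="chemistry", modality="laboratory", sendout_eligible=False)
        ],
        indications=[dict(diagnostic_id="d", condition_id="dm", level="triage", indication_class="diagnosis")],
        formats=[dict(id="f", diagnostic_id="d", name="analyzer", min_tier_id="tertiary")],
    )
    p = place_diagnostic("d", m)
    assert p.mode == "referral" and p.origin_tier_ids == ("primary", "secondary")


def test_unconstrained_placement_is_on_site_with_no_origins():
    m = _simple(
        _BASE_CARE,
        indications=[dict(diagnostic_id="d", condition_id="dm", level="triage", indication_class="diagnosis")],
        formats=[dict(id="f", diagnostic_id="d", name="rdt", min_tier_id="primary")],
    )
    p = place_diagnostic("d", m)
    assert p.mode == "on_site" and p.origin_tier_ids == ()


def test_unindicated_and_unrealizable_diagnostics_raise():
    m = _simple(_BASE_CARE, indications=[], formats=[])
    with pytest.raises(PlacementError, match="unindicated"):
        desired_tier("d", m)
    with pytest.raises(PlacementError, match="unrealizable"):
        feasible_tier("d", m)


def test_unanchored_medicine_raises():
    m = _simple(
        _BASE_CARE,
        indications=[dict(diagnostic_id="d", medicine_id="ceph", indication_class="toxicity")],
        formats=[dict(id="f", diagnostic_id="d", name="x", min_tier_id="primary")],
        medicines=("ceph",),
    )
    with pytest.raises(PlacementError, match="unanchored medicine"):
        desired_tier("d", m)


# ---------------------------------------------------------------------------
# properties on random instances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(12))
def test_tiers_match_brute_force_enumeration(seed):
    m = small_instance(seed=seed)
    plan = build_plan(m)
    rank = {t.id: t.rank for t in m.tiers}
    for p in plan.placements:
        assert rank[p.desired_tier_id] == brute_desired_rank(m, p.diagnostic_id)
        assert rank[p.feasible_tier_id] == brute_feasible_rank(m, p.diagnostic_id)
        assert rank[p.performing_tier_id] == brute_performing_rank(m, p.diagnostic_id)


@pytest.mark.parametrize("seed", range(8))
def test_mode_partition_and_origin_span(seed):
    m = small_instance(seed=seed)
    ix = {d.id: d for d in m.diagnostics}
    rank = {t.id: t.rank for t in m.tiers}
    for p in build_plan(m).placements:
        d = ix[p.diagnostic_id]
        if p.mode == "on_site":
            assert p.performing_tier_id == p.desired_tier_id and p.origin_tier_ids == ()
        elif p.mode == "send_out":
            assert d.modality == "laboratory" and d.sendout_eligible
        else:
            assert d.modality == "imaging" or not d.sendout_eligible
        assert [rank[t] for t in p.origin_tier_ids] == list(
            range(rank[p.desired_tier_id], rank[p.performing_tier_id])
        )


def test_lowering_a_format_floor_never_raises_performing_tiers():
    m = small_instance(seed=21)
    rank = {t.id: t.rank for t in m.tiers}
    before = {p.diagnostic_id: rank[p.performing_tier_id] for p in build_plan(m).placements}
    target = next(f for f in m.formats if rank[f.min_tier_id] > 1)
    lowered = target.model_copy(update={"min_tier_id": m.tiers[0].id})
    m2 = m.model_copy(
        update={"formats": tuple(lowered if f.id == target.id else f for f in m.formats)}
    )
    after = {p.diagnostic_id: rank[p.performing_tier_id] for p in build_plan(m2).placements}
    assert all(after[d] <= before[d] for d in before)


def test_lowering_a_care_tier_never_raises_desired_tiers():
    m = small_instance(seed=22)
    rank = {t.id: t.rank for t in m.tiers}
    before = {p.diagnostic_id: rank[p.desired_tier_id] for p in build_plan(m).placements}
    target = next(a for a in m.care_assignments if rank[a.tier_id] > 1)
    lowered = CareAssignment(
        condition_id=target.condition_id, level=target.level, tier_id=m.tiers[0].id
    )
    m2 = m.model_copy(
        update={
            "care_assignments": tuple(
                lowered if (a.condition_id, a.level) == (target.condition_id, target.level) else a
                for a in m.care_assignments
            )
        }
    )
    after = {p.diagnostic_id: rank[p.desired_tier_id] for p in build_plan(m2).placements}
    assert all(after[d] <= before[d] for d in before)


def test_adding_a_condition_never_raises_existing_desired_tiers():
    m = small_instance(seed=23)
    rank = {t.id: t.rank for t in m.tiers}
    before = {p.diagnostic_id: rank[p.desired_tier_id] for p in build_plan(m).placements}
    new_cond = Condition(id="zz_new", name="New condition")
    levels = tuple(ConditionLevel(condition_id="zz_new", level=l) for l in ("triage", "uncomplicated", "complicated"))
    care = tuple(
        CareAssignment(condition_id="zz_new", level=l, tier_id=m.tiers[0].id)
        for l in ("triage", "uncomplicated", "complicated")
    )
    extra_inds = tuple(
        DiagnosticIndication(
            diagnostic_id=d.id, condition_id="zz_new", level="uncomplicated", indication_class="comorbidity"
        )
        for d in m.diagnostics[:5]
    )
    m2 = m.model_copy(
        update={
            "conditions": m.conditions + (new_cond,),
            "condition_levels": m.condition_levels + levels,
            "care_assignments": m.care_assignments + care,
            "indications": m.indications + extra_inds,
        }
    )
    after = {p.diagnostic_id: rank[p.desired_tier_id] for p in build_plan(m2).placements}
    assert set(after) == set(before)  # no placement removed
    assert all(after[d] <= before[d] for d in before)


def test_build_plan_emits_exactly_one_placement_per_diagnostic(ghana_plan, ghana):
    assert sorted(p.diagnostic_id for p in ghana_plan.placements) == sorted(
        d.id for d in ghana.diagnostics
    )


def test_chosen_format_is_operable_and_deterministic():
    m = small_instance(seed=9)
    fmts = {f.id: f for f in m.formats}
    rank = {t.id: t.rank for t in m.tiers}
    plan1, plan2 = build_plan(m), build_plan(m)
    assert plan1.placements == plan2.placements
    for p in plan1.placements:
        assert fmts[p.chosen_format_id].diagnostic_id == p.diagnostic_id
        assert rank[fmts[p.chosen_format_id].min_tier_id] <= rank[p.performing_tier_id]
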