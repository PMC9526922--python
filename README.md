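# dxnet — tier-specific essential-diagnostics network planning

National health systems deliver care in tiers (Primary health centers,
Secondary district hospitals, Tertiary referral hospitals), but guidance on
*which tier* each essential diagnostic — laboratory test or imaging
examination — belongs to is scarce. `dxnet` implements a relational
planning model for exactly that question, aimed at ministries of health,
national essential-diagnostics-list (NEDL) committees, and diagnostic-network
researchers.

## The model

The model links burden-of-disease conditions, each split into three care
levels — triage (T), management of the uncomplicated condition (U), and
management with complications (C) — to the tier where that care is
delivered, plus the medicines treating each condition-level, the
diagnostics indicated for condition-levels or medicines, and the concrete
formats (rapid test, automated analyzer, …) each diagnostic can be run in,
with each format's infrastructure-determined minimum tier.

For a diagnostic *d* with indicated condition-levels (expanded through its
indicated medicines' assignments) and formats F(d):

- **desired tier** `t_des(d) = min { careTier(c,ℓ) : (c,ℓ) indicated for d }` —
  the lowest tier where patient management depends on the result;
- **feasible tier** `t_fea(d) = min { minTier(f) : f ∈ F(d) }` — the
  infrastructure floor;
- **performing tier** `t_per(d) = max(t_des, t_fea)` by tier rank.

If `t_per = t_des` the diagnostic is delivered **on-site**. If
infrastructure forces it upward, a laboratory test travels as a specimen
(**send-out**) from every tier in `[t_des, t_per)`, while imaging (or a
send-out-ineligible test) means **patient referral**. Reports then derive
tier increments, send-out routes, discipline mixes, per-tier equipment
rollups with interval capital costs (USD, one instrument of each type),
per-condition diagnostic sets, and a greedy cumulative-coverage curve; a
scenario engine moves condition-levels between tiers and diffs the induced
plans.

## Worked example

```python
from dxnet import (build_plan, cost_by_tier, ghana_fixture,
                   sendout_summary, tier_increment_counts)

model = ghana_fixture()            # bundled 3-tier exemplar (19 conditions)
plan = build_plan(model)

inc = tier_increment_counts(plan)
print(inc.by_tier(), "total", inc.total)
print(sendout_summary(plan).to_tier)
print({t: (c.low, c.high) for t, c in cost_by_tier(plan).items()})
```

prints

```
{'primary': 11, 'secondary': 19, 'tertiary': 15} total 45
{'secondary': 8, 'tertiary': 1}
{'primary': (8330.0, 8330.0), 'secondary': (571000.0, 777000.0), 'tertiary': (1810000.0, 4550000.0)}
```

Reading: of the exemplar's 45 diagnostics, 11 are performed at Primary, 19
at Secondary (8 of them as specimen send-outs arriving from Primary, e.g.
HbA1c and complete blood count) and 15 at Tertiary (one, HIV viral load,
as a send-out from Secondary). Equipping Primary costs $8,330 exactly
($2,330 of laboratory equipment plus a $6,000 point-of-care ultrasound);
Secondary needs $571,000–$777,000 ($296k–$377k of laboratory analyzers plus
$275k–$400k for an ultrasound and an X-ray machine); the Tertiary interval
is reported but not validated. The same pipeline runs on any model loaded
with `load_model()` from a CSV directory or JSON bundle, or generated with
`generate_synthetic()`.

The same workflow from a shell:

```bash
dxnet generate --ghana -o ghana/      # emit the exemplar as a CSV bundle
dxnet validate ghana/                 # referential-integrity report, exit 0
dxnet report ghana/ -o out/ --format md,csv,json
dxnet scenario ghana/ --moves moves.yaml -o out/scenario
```

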