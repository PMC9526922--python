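# Methods

## Model and assumptions

`dxnet` treats a national diagnostic network as a relational constraint
problem. The entities and rules are:

- **Tiers** are a totally ordered set (rank 1 = lowest). Tier comparisons
  are rank comparisons; nothing is hard-coded to three tiers, though the
  bundled exemplar and the defaults use Primary/Secondary/Tertiary.
- **Conditions** are split into exactly three care levels — triage,
  uncomplicated management, complicated management — and each
  condition-level is assigned to exactly one care tier. Triage means
  identifying suspected cases for referral, so its care tier is usually
  the lowest.
- **Diagnostics** are identified by analyte or examination, not by
  format: HIV serology by rapid test and by automated immunoassay is one
  diagnostic with two formats. Each format carries the minimum tier its
  equipment, facilities and personnel allow, plus references to equipment
  items with `[low, high]` USD capital-cost intervals.
- **Indications** justify a diagnostic either at a condition-level
  (diagnosis, monitoring, co-morbidity) or at a medicine (toxicity,
  dose adjustment, companion). Medicine-targeted indications inherit the
  care tiers of every condition-level the medicine is assigned to treat —
  the only reading consistent with "available at the lowest tier where
  patients might receive management dependent on the result", since that
  is where the medicine is prescribed.

Placement: desired tier = minimum care tier over the expanded indication
set; feasible tier = minimum format tier; performing tier = the
rank-maximum of the two. A diagnostic performed at tier *t* is assumed
available to all higher tiers (no duplicate placements). When
infrastructure forces a test above its desired tier, laboratory tests
default to specimen transport ("send-out") and imaging to patient
referral; `sendout_eligible` is a per-diagnostic input override (default
true for laboratory, always false for imaging), not a computed
turnaround-time property.

## Counting and reporting conventions

- Tier increments count each diagnostic once, at its performing tier;
  send-outs are counted at the tier that runs the specimen and flagged,
  not double-counted at their origin tiers. Increments therefore sum to
  the unique-diagnostic total.
- A send-out diagnostic counts once per performing tier in the
  "sent to tier X" summary even when specimens arrive from several lower
  tiers; per-leg route counts are reported separately.
- Equipment rollups are cumulative-minus-lower: a tier's set is the
  equipment of the chosen formats performed there minus anything a lower
  tier already requires, so rollups partition the equipment set and
  interval costs add without double counting.
- Capital cost of a tier is the interval sum (componentwise) over its
  rollup, assuming one instrument of each type. The highest tier's cost
  row is labelled "not validated" in exports: apex-tier capital needs are
  dominated by advanced instruments whose prices this model does not
  attempt to validate.
- Per-condition diagnostic sets are computed in isolation of other
  conditions and include medicine-mediated diagnostics (a toxicity test
  for a medicine counts toward every condition the medicine treats).
- The coverage curve orders conditions by descending isolated count
  (ties by display name, then id) and reports the median marginal under
  both conventions — including the first condition's full count as a
  marginal, and excluding it — because a half-integer median of integer
  marginals depends on that choice. Both values are exposed, labelled.

## Tunable parameters

| Parameter | Units | Default | Why |
| --- | --- | --- | --- |
| tier set | ordered ranks | 3 tiers | generalized health-center / district / referral structure |
| `sendout_eligible` | boolean per diagnostic | true (laboratory) | specimen transport is the default integrated-network assumption |
| format tie-break | — | min tier, then equipment midpoint, then name | determinism where the data are silent |
| equipment cost | USD interval | per item | price uncertainty propagates as interval arithmetic |

Format choice at the performing tier is a reporting decision only (it
feeds equipment rollups); it never changes the performing tier itself.

## The bundled exemplar

`ghana_fixture()` encodes a condensed three-tier West-African exemplar:
19 priority conditions (the projected top-burden set plus antenatal
care), care-tier logic (triage at Primary except acute coronary
syndrome at Secondary; uncomplicated management at Secondary except
cancers at Tertiary and antenatal care/malaria at Primary; complicated
management at Tertiary), 45 representative diagnostics across all 11
disciplines, 10 medicines, and a 30-item equipment catalogue. The
published tier capital figures are encoded exactly: Primary laboratory
$2,330 + $6,000 point-of-care ultrasound, Secondary analyzers
$296,000–$377,000 + imaging $275,000–$400,000. Per-item price splits
inside a tier are illustrative allocations chosen to sum to those tier
totals; only the tier sums are meaningful. Tertiary item prices are
rough placeholders and flagged "not validated". The fixture is a
condensed subset of a full national catalogue (≈111 diagnostics), so
national headline counts are out of its reach by design; it exists to
exercise every placement branch (on-site, send-out, referral), every
discipline, and the exact cost arithmetic.

## Synthetic generator

`generate_synthetic(SyntheticSpec(...))` emulates the relational shape
at study scale: 3 tiers, 20 conditions × 3 levels with care tiers
non-decreasing from triage to complicated, 111 diagnostics (~12%
imaging, matching the exemplar's 13/111 imaging share), 40 medicines,
1–3 formats per diagnostic with minimum tiers uniform over the tier
range, 1–3 indications per diagnostic with a 15% chance of targeting a
medicine, 5% of laboratory tests send-out-ineligible, and equipment
price intervals drawn in $100–$500,000. All draws come from one
`numpy` generator seeded by `spec.seed`, so instances are reproducible;
every instance passes `validate_model` by construction.

What it does **not** emulate: real co-occurrence structure (shared
diagnostics between related conditions), realistic discipline
proportions, volume/population-density effects, or correlated format
economics. Passing property tests therefore demonstrate the engine's
logical correctness (oracle equivalence, conservation, monotonicity,
invertibility), not country-level realism of any generated plan.

## Numerical and degenerate-input choices

- Costs are exact interval sums of the input numbers; no rounding is
  applied anywhere, and degenerate intervals (low = high) are allowed.
- Validation is total and returns violations as data; placement raises
  typed errors (`unindicated diagnostic`, `unrealizable diagnostic`,
  `unanchored medicine`) which `build_plan` aggregates into one report.
- An empty-but-typed instance (no diagnostics) yields an empty plan and
  all-zero reports rather than an error.
- Serialization uses one CSV dialect (UTF-8, comma, header row, empty
  string = null, `;` for multi-valued cells) and canonical row ordering,
  making write→load the identity and repeated writes byte-identical.
- Indications tagged as determining the level of a condition are a
  data-entry concern: the schema keeps the transcribed target as-is
  rather than silently rewriting complicated-level targets to
  uncomplicated.

## Problem sizes in the test suite

Property checks run on compact instances chosen to cover the state
space quickly: oracle equivalence on 200 random instances of 5–50
diagnostics, conservation on 25 instances, monotonicity on 500 random
downward perturbations across 20 instances, scenario
locality/invertibility on 15 instances. The full suite runs in a few
seconds on one CPU.

## Known limitations

- No recurrent/operating-cost, test-volume, or turnaround-time
  modelling; capital cost only, excluding service contracts and duties.
- No optimization or search over scenarios — the scenario engine
  evaluates user-specified moves, it does not propose them.
- Diagnostic nomenclature mapping to external lists (EDL/NEDL naming)
  is out of scope; identity is carried by caller-supplied slugs.
- The bundled exemplar's condition–diagnostic catalogue is condensed;
  its aggregate counts describe the fixture, not a full national
  essential-diagnostics list.
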