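# Methods

## Model

The package implements a deterministic demand-and-price projection for
dental care of Australians aged 65+. It is an *explanatory* (accounting)
model, not a statistical fit: every output is an arithmetic consequence
of its inputs, and there is no uncertainty quantification by design —
the population inputs are censuses, not samples.

Three inputs drive the projection:

1. **Population strata.** Counts of persons 65+ per aggregation cell
   (geographic unit × jurisdiction × IRSD decile × remoteness class).
   Strata are generic label cells rather than census polygons: the
   arithmetic only consumes counts per label combination, so the GIS
   join that produces real inputs is out of scope and replaced by label
   columns. Decile 1 is always the most disadvantaged 10% of the
   population. Unknown remoteness is the explicit label `Unclassified`,
   and a missing decile is stored as NA (excluded from decile groupings
   only), so partial tables — e.g. jurisdiction totals without
   small-area joins — validate and aggregate cleanly instead of being
   rejected.
2. **Service mix.** A single national visit rate (2.58 annual visits per
   person 65+, from the 2013 national dental telephone interview survey
   of dentate adults) and the mean number of services per visit in each
   of nine clinical areas (2003–04 wave of the dentists'
   practice-activity study). The rate was measured on dentate
   respondents but is applied to the whole 65+ count, reproducing the
   published model; a `dentate_fraction` multiplier (default 1.0) is
   exposed for sensitivity analysis. No heterogeneity of the rate by
   decile or remoteness is modelled — none is published.
3. **Fees.** AUD per visit in each service area (below).

Cost of a cell is `visits × fee × λ` with `λ` a flat scenario multiplier.
The only shipped scenario is the government veterans' schedule at
`λ = 0.79` (prices ≈ 21% below private general-practice fees); a flat
factor is the only faithful encoding, since no per-item schedule
comparison is published.

## Fee derivation and its ambiguity

A category fee is the average of its high-frequency schedule items:
`total = Σ mean_fee × frequency_weight`, divided by a denominator `D`.
The published diagnostic example (items 011, 012, 013 at weight 1 and
the per-exposure bitewing 022 at weight 2) totals 206.65 AUD and prints
an average of 51.66 = 206.65/4, i.e. `D` = number of *line entries*.
That is the package default (`per_line_entry`).

However, the published downstream cost table implies an effective
diagnostic fee of ≈ 68.5 AUD/visit, not 51.66. Dividing the same total
by the three *single-billed* items (treating the per-exposure radiograph
as an add-on that inflates the episode total but is not a standalone
service) gives 206.65/3 = 68.88 — much closer. Both readings are
selectable (`denominator_rule="per_distinct_item"` for the second); the
default reproduces the printed fee table, and the reference schedule
(next section) sidesteps the ambiguity by calibrating the diagnostic fee
from the cost table directly.

Fees are stored to cent precision; episode totals are unrounded.
Calibration (`fee = cost / visits`) is exact division and round-trips to
machine precision.

## Reference inputs and reconstruction

Only fragments of the original inputs were printed, so
`agecost.baseline` reconstructs the rest deterministically and flags it:

- **Populations.** WA's 65+ count (342,652) was printed directly. ACT,
  NT and Tas are recovered from their printed annual visit totals
  (126,466; 40,862; 251,958) divided by 2.58 and rounded. NSW, Vic, Qld
  and SA are recovered from their published prosthodontics cost divided
  by the published implied prosthodontics fee (1083 AUD/visit), the
  prosthodontics per-visit mean (0.257) and the visit rate. These
  reconstructions inherit the rounding of the published figures
  (≲ 0.1% for the large columns); the run manifest flags them.
- **Fees.** Prosthodontics (1083) and periodontics (203) use the
  published implied per-visit costs. The other seven categories are
  calibrated from the NSW column of the published cost table (largest
  column, least relative rounding error): e.g. diagnostic 68.49,
  restorative 215.10, crown & bridge 1222.64 AUD/visit. All carry
  `provenance="calibrated"`. The diagnostic fee can instead be derived
  from the printed schedule items (51.66) via
  `reference_fee_schedule(diagnostic_from_items=True)`; the two differ
  by ≈ 25%, an inconsistency internal to the published derivations, and
  the calibrated value is the default because it reproduces the
  published cost table.

With these inputs the pipeline reproduces the published jurisdiction ×
area cost table to within its printed rounding: national total ≈ 6,387M
AUD (published 6,385M), prosthodontics row ≈ 2,613M (published 2,612M),
replacement + restorative ≈ 5,020M (published 5,020M).

## Rounding policy

All internal arithmetic is unrounded; rounding is a formatting concern.
Two deliberate exceptions:

- The published two-step worked table decomposes the *rounded* annual
  visit count (884,042 × 0.671 = 593,192.182, not 884,042.16 × 0.671).
  `split_by_service(..., round_totals=True)` reproduces this; the
  pipeline default keeps totals unrounded so that unit-level computation
  followed by aggregation equals direct aggregate-level computation to
  < 1e-9 relative. Rounding to whole visits changes national cost cells
  by < 1 AUD per stratum — invisible at report precision.
- Report cells in the `millions` style round to the nearest million,
  except positive values below 1M, which keep one decimal (`$0.4`), and
  exact zero (`$0`). Row/column totals are computed from unrounded cells
  *before* formatting: the published grand total differs from the sum of
  its rounded cells, so rounded-cell arithmetic cannot be the internal
  representation.

## Synthetic small-area generator

`generate_population` emulates the structure of real small-area census
inputs without reproducing any real geography:

- unit total residents uniform on [200, 800] (the census small-area size
  band);
- 65+ count = `round(total × a)` with `a ~ Normal(0.15, 0.05)` truncated
  to [0, 1]. The mean matches the national 65+ share; no within-area age
  structure is published, so any bounded unimodal draw serves and both
  moments are configurable;
- jurisdiction and remoteness drawn from weight vectors defaulting to
  the approximate national 65+ distribution and a mostly-metropolitan
  remoteness profile;
- deciles assigned by greedy population-share fill over a reproducibly
  shuffled unit order (the shuffle stands in for the disadvantage
  score): each decile ends within one unit's population of 10%. Real
  disadvantage indices partition on total residents; the generator
  partitions on the 65+ counts the model consumes, so the 10% property
  holds exactly for the modelled population and can be verified from the
  generated table alone.

Everything is driven by one integer seed through a single `numpy`
generator; identical specs produce byte-identical tables.

What the generator does *not* emulate: spatial autocorrelation,
correlation between disadvantage and age structure or remoteness,
jurisdiction-specific remoteness profiles, and real settlement patterns.
Passing tests on synthetic data therefore demonstrate the pipeline's
arithmetic correctness, conservation and reproducibility — not the
realism of any specific dollar figure for Australia; those are anchored
separately by the published worked examples.

## Numerical and design choices

- Integer population arithmetic throughout the population module; group
  sums are exact, and conservation tests assert equality, not closeness.
- Visit and cost cells are float64; stratum-vs-aggregate equivalence is
  asserted at < 1e-9 relative (floating summation order is the only
  source of discrepancy).
- Zero-population groups in per-person views are reported as NaN with an
  `undefined` flag, never as zero.
- Stratum input order never affects any aggregate.
- Problem sizes: property checks run on 10,000 synthetic units (the
  scale at which decile shares are specified to converge within 0.5%);
  worked-example checks run on single strata. The full suite completes
  in a few seconds.

## Known limitations

- One national visit rate and one national fee per category: no state,
  decile or remoteness variation in either (the fee surveys document
  state variation that this model deliberately averages away).
- The 2003–04 service mix is the most recent age-resolved mix published;
  actual service patterns have likely shifted toward tooth retention
  since.
- Point estimates only; no demographic projection over time; no
  modelling of insurance coverage, public waiting lists, or subgroups
  (Indigenous and institutionalised older people) with documented poorer
  oral health.
- Orthodontics is excluded for lack of utilisation data, not because its
  cost is zero.
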