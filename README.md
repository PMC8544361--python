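# agecost

Deterministic projection of dental-service utilisation and expenditure for
the Australian population aged 65 and over, resolved by jurisdiction
(state/territory), socioeconomic disadvantage decile (IRSD, decile 1 =
most disadvantaged) and remoteness class.

The package is aimed at health-services researchers and oral-health
planners who need a transparent, reproducible cost basis for geriatric
dental care: what would it cost, at private general-practice fees, for
every older Australian to receive the services this cohort currently
uses?

## The model

For each population stratum *s* (a geographic/demographic cell with 65+
count `pop(s)`) and each of nine clinical service areas *k* (diagnostic,
preventive, periodontics, oral surgery, endodontics, restorative, crown &
bridge, prosthodontics, general; orthodontics excluded — no utilisation
data exist for this cohort):

```
visits(s)    = pop(s) × r           r = 2.58 annual visits/person (65+)
visits(s,k)  = visits(s) × m(k)     m(k) = mean services of area k per visit
cost(s,k)    = visits(s,k) × f(k) × λ
```

where `f(k)` is the per-visit fee of area *k* in AUD and `λ` a scenario
multiplier (1.0 baseline; 0.79 prices the model at the government
veterans' schedule, ~21% below private fees). The per-visit means `m(k)`
are services per visit, not shares: they sum to 2.241.

Fees come from one of three routes, each flagged by provenance:
derived from high-frequency schedule items (`Σ fee·weight / D`, with two
selectable denominator rules), supplied directly, or *calibrated*
(back-derived as published cost ÷ projected visits, used for categories
whose survey items were never published). All aggregation uses unrounded
values; rounding to millions happens only at report time.

Real census, disadvantage-index and fee-survey inputs are closed or
download-heavy, so the package ships a synthetic small-area generator
(units of 200–800 residents, configurable aged fraction, deciles holding
10% of population each) that makes every stage testable end to end.

## Worked example

```python
import pandas as pd
from agecost import PopulationTable, project_service_visits, compute_costs, format_report
from agecost.baseline import reference_service_mix, reference_fee_schedule

wa = PopulationTable(pd.DataFrame({
    "unit_id": ["WA"], "jurisdiction": ["WA"], "decile": [pd.NA],
    "remoteness": ["Unclassified"], "pop_65plus": [342_652],
}))
mix = reference_service_mix()                    # r = 2.58, 2003-04 mix
vt = project_service_visits(wa, mix, round_totals=True)
print(vt.data.set_index("area")["visits"].round(3))
```

```
area
Diagnostic        593192.182
Restorative       566670.922
Preventive        303226.406
Prosthodontics    227198.794
CrownBridge        85752.074
Endodontics        84868.032
OralSurgery        80447.822
General            25637.218
Periodontics       14144.672
```

342,652 persons × 2.58 visits = 884,042 annual visits, decomposed by the
per-visit service means: prosthodontics alone accounts for 227,199 of
WA's annual dental visits by older people.

```python
ct = compute_costs(vt, reference_fee_schedule())
print(format_report(ct, "millions")[["WA"]])
```

```
area
Diagnostic         $41
Restorative       $122
Preventive         $29
Prosthodontics    $246
CrownBridge       $105
Endodontics        $21
OralSurgery        $22
General            $14
Periodontics        $3
```

At the calibrated fees (prosthodontics 1083 AUD/visit, periodontics
203 AUD/visit) WA's older cohort would require $246M/year for
prosthodontics but only $3M for periodontics — replacement dentistry
dominates the bill everywhere.

The same pipeline is scriptable from the shell:

```sh
agecost synth --n-units 1000 --seed 7 --out pop.csv
agecost run --population pop.csv --by jurisdiction,decile --out results/
agecost calibrate --cost 246000000 --visits 227198.794   # -> 1082.75
agecost reproduce --out baseline/                        # reference tables
```

## Layout

- `agecost.population` — strata, validation, grouped totals
- `agecost.services` — visit projection and service-area decomposition
- `agecost.fees` — item averaging, implied-fee calibration, schedule I/O
- `agecost.costs` — cost cells, aggregation, per-person views, reports
- `agecost.synthetic` — synthetic small-area census generator
- `agecost.baseline` — bundled reference inputs (printed or reconstructed)
- `agecost.pipeline` / `agecost.cli` — end-to-end runs and the `agecost` command

See `docs/methods.md` for modelling assumptions, parameter provenance and
known limitations.
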