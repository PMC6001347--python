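# genaccount

A generational-accounting model of the lifetime **net fiscal contribution
(NFC)** of an individual conceived through publicly funded assisted
reproduction (IVF or artificial insemination), calibrated to 2006 Spain.

The model sums the taxes an average individual pays to the state and the
transfers they receive, per single year of age from birth to life
expectancy (78), projects the real base-year flows under GDP growth and
inflation, discounts them, subtracts the up-front expected treatment cost,
and reports the NFC, the break-even age at which the state's cumulative
position turns positive, and the return on investment per euro spent —
under full funding of all treatment cycles or a capped (three-cycle)
policy, in the base case and under eight one-way macro sensitivity
scenarios.

## Layout

| module | contents |
| --- | --- |
| `genaccount.profiles` | `AgeProfile` data model, transfer/tax profile sets, imputation operations (group-mean expansion, per-capita imputation, participation weighting, component sums) |
| `genaccount.lifecycle` | `MacroParams`, growth/discount factors, present value, `npv`, break-even age |
| `genaccount.art_costs` | geometric treatment-cycle economics: expected cycles, cost per pregnancy, capped-funding expected cost, live-birth-adjusted expected NFC, ROI |
| `genaccount.scenarios` | scenario specs, unemployment re-weighting, one-way deterministic sensitivity runs, tornado tables |
| `genaccount.synthetic` | synthetic age-profile generator with the documented structure (schooling-age education, six U-shaped healthcare bands, late-life pensions, working-age labour taxes, consumption taxes from fixed starting ages) and two-scalar calibration to the published discounted lifetime totals |
| `genaccount.io` / `genaccount.cli` | profile CSV contract, table rendering, pipeline, `genaccount` command line |

Because the underlying per-age Spanish statistics are unpublished, the
synthetic generator reproduces their *structure* and the two published
discounted totals (taxes €370,482; transfers €275,972), not the true euro
levels; break-even ages and scenario euro values are therefore
shape-dependent (the shipped default shape keeps all scenario break-even
ages inside the published 29–41 envelope).

## CLI

```sh
# calibrated synthetic profiles as CSV (columns: age,component,kind,value)
genaccount --seed 1 synth --out profiles.csv \
    --calibrate-taxes 370482 --calibrate-transfers 275972

# full pipeline from a YAML config (base table, sensitivity, tornado,
# cumulative curve, log)
genaccount run --config cfg.yaml --format csv

# built-in eight-scenario sensitivity set
genaccount --seed 1 sensitivity --set table4 --technique ivf --policy capped:3
```

Minimal `cfg.yaml`:

```yaml
macro: {discount_rate: 0.035, gdp_growth: 0.0408, inflation: 0.035}
techniques: [IVF, AI]
policies: [unlimited, "capped:3"]
profiles:
  synthetic: {seed: 1}
output_dir: out
```

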