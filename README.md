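# popmortgen

Build single-year population mortality (**PopMort**) files from abridged
life tables, and validate them end-to-end with a built-in Ederer II
relative-survival estimator on simulated cohorts.

Abridged life tables (e.g. SRS-style publications) report the probability
of dying, `nqx`, per age group. Relative-survival software instead needs a
long table of mortality **rate** and annual survival **probability** per
calendar year × sex × single year of age (0–100). `popmortgen` performs the
conversion:

1. **Invert nqx to a central rate** with separation factors
   (`rate = nqx / (n − f·nqx)`, with `f = 1/2` for the 0–4 group and
   `n/2` — i.e. 5/2 — for the other closed groups).
2. **Convert to annual survival probability** via `prob = exp(−rate)`.
3. **Expand to single ages**: every age in a group carries that group's
   rate/prob; ages beyond the last closed group (up to 100) reuse the last
   closed group's values.
4. **Map periods to calendar years**: a life-table period is anchored at
   its midyear (2015–2019 → 2017); each requested calendar year uses the
   nearest midyear, carrying the latest table forward and the earliest
   backward.

## Modules

| module | purpose |
|---|---|
| `popmortgen.life_table` | parse/validate abridged life tables, merge split infant rows, separation factors |
| `popmortgen.popmort_engine` | rate/probability conversions, single-age expansion, year assignment, table assembly |
| `popmortgen.popmort_io` | CSV read/write with configurable headers (defaults `_year, sex, _age, rate, prob`) |
| `popmortgen.synthetic_fixtures` | Gompertz–Makeham life tables and piecewise-constant-hazard cohort simulation |
| `popmortgen.relative_survival` | actuarial observed survival, Ederer II expected survival, relative survival + CIs, age-standardisation |
| `popmortgen.cli` | `popmortgen build / simulate / rs` |

## CLI

Build a PopMort file from a config:

```sh
popmortgen build --config build.yaml
```

```yaml
# build.yaml
start_year: 2009
end_year: 2024
output: popmort.csv
sources:
  - path: life_table_2016_2020.csv
    schema:
      age_column: age_group
      nqx_columns: {1: nqx_male, 2: nqx_female}
      period: [2016, 2020]
```

Sex codes are fixed: **1 = male, 2 = female**. Life-table sources may be
wide (one nqx column per sex) or long (one nqx column plus a sex column);
age-group labels `0-4`, `5–9`, `85+` and bare starts are accepted, and
split infant rows (`0` / `1-4`) are merged automatically.

Generate synthetic fixtures and run relative survival:

```sh
popmortgen simulate --seed 1 --cohort-out cohort.csv --popmort-out popmort.csv
popmortgen rs cohort.csv popmort.csv --horizon 5
```

`rs` prints per-interval observed, Ederer II expected, and relative
survival with 95% confidence limits (log(−log) transform, Greenwood
variance).

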